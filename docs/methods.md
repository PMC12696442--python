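# Methods

## Scaffold model

A scaffold design is the solid region of a nodal TPMS field over a
printable domain. The three fields (Gyroid, Schwarz Diamond, Schoen I-WP)
are 2π-periodic trigonometric implicit functions; Gyroid and Diamond are
odd under point inversion (`f(−p) = −f(p)`) while I-WP is even, properties
the test suite uses as exact symmetry oracles. Physical coordinates map to
the dimensionless equation coordinates through one cubic unit cell of edge
L via `2π/L` per axis.

Two solidification conventions are offered. The default, **skeletal**,
takes the solid as `{f ≥ t}` (one labyrinth of the surface); **sheet** mode
takes `{|f| ≤ t}` (a thickened shell, t ≥ 0). Skeletal is the default
because single-labyrinth walls are what an extrusion printer fabricates
most directly; the chosen mode is recorded in every output manifest. With
the skeletal sign convention, raising t removes material, so porosity is a
nondecreasing function of t (nonincreasing for sheet), which makes
threshold calibration a one-dimensional monotone root-finding problem.

**Porosity means void volume fraction**: a target of 0.2 leaves 80 % of
the domain solid. Voxels are classified by their centre point with no
partial-volume weighting, deliberately matching the binarized-image
semantics of the downstream slice morphometry — a voxel model sliced along
its own grid reproduces the 3-D void count exactly.

## Parameters and defaults

| Parameter | Default | Why |
| --------- | ------- | --- |
| Domain | Ø8 mm × 3 mm cylinder | the compression-specimen geometry of the physical scaffolds |
| Target porosity | 0.20 | the stated design porosity of the study |
| Unit-cell edge L | 2.5 mm | chosen so the cylinder spans ≳3 periods laterally and pore openings come out sub-millimetre, the order observed in printed scaffolds; fully configurable |
| Voxel pitch | 40 µm | resolves the 2.5 mm cell with ~62 voxels/period, fast enough for interactive calibration; 13.69 µm is available to mirror the reconstruction scale of the reference scanner |
| Bisection tolerance | 10⁻³ on φ | well below the ±0.5-point acceptance band; 60 iterations max |
| Connectivity | 8-connected | the particle-analysis convention of ImageJ |
| Minimum pore size | 4 px | small enough to keep real pores, large enough to drop single-pixel speckle |

The unit-cell size is a genuinely open design choice: the source study does
not report its cell size (nor whether all geometries shared one), so
absolute ECD values cannot be reproduced — only compared at matched L and
φ. The comparison report therefore states the computed ordering without
asserting the published one as ground truth; in practice both agree
(Gyroid > Diamond > I-WP at L = 2.5 mm, φ = 0.2).

## Calibration

`calibrate_threshold` samples the field once at voxel centres, brackets t
by the sampled extrema, and bisects on the voxel-counted porosity until
|φ − target| ≤ tolerance. With ~2.4 M domain voxels the attainable φ
granularity (~4×10⁻⁷) is far finer than the tolerance, so bisection always
terminates (9–12 iterations in practice). Targets outside the achievable
bracket raise a dedicated error reporting that bracket; exhausting the
iteration budget raises a convergence error carrying the last bracket. An
independent Monte-Carlo integrator (uniform points in the domain, explicit
seed, default 0) serves as the oracle for voxel-counted volume fractions in
the tests.

## Meshing

Marching cubes runs on the thresholded field min-combined with a signed
distance to the domain wall (positive inside, in mm; the dimensionless
field is rescaled by L/2π so the two are commensurate). The min-combination
makes the isosurface close itself at the cylinder wall and end faces in one
pass, avoiding fragile post-hoc hole filling. The grid is padded by one
ghost layer continuing the wall-distance ramp (edge value minus one pitch,
clamped negative), which lands the boundary cap on the true wall instead of
biasing it half a voxel inward. Meshes are checked watertight (every edge
shared by exactly two faces) and oriented outward (signed volume > 0,
computed by the divergence theorem); mesh volume agrees with the
voxel-counted solid volume to ≲0.5 % at 40 µm pitch, with 2 % asserted at
pitch ≤ L/64. Binary STL is the default dialect; units are mm, unlabeled in
STL per convention and recorded in the run manifest.

## Synthetic slice stacks

`render_slices` emulates reconstructed micro-CT output as stacks of binary
axial images at pixel size = slice spacing = voxel pitch. Rendering is
three-valued — solid, in-domain pore, outside-domain background — with the
background carried as a per-slice domain mask and collapsed only after ROI
application, so exterior background can never inflate porosity.
`degrade` stresses the morphometry with reconstruction-like smoothing
(per-slice Gaussian blur of the binary image, then re-thresholding at 0.5);
σ = 0 is the identity and porosity drift stays ≤ 0.02 at σ ≤ 1 px.

What the simulator does **not** model: polychromatic beam physics (beam
hardening, ring artifacts — scanner-side corrections in practice), printer
shrinkage and extrusion-width error, segmentation-threshold uncertainty of
real grey-level reconstructions, and partial-volume grey levels. Passing
tests therefore demonstrate the correctness of the measurement chain on
ideal binarized data, not the fidelity of any physical print: the 2–5
percentage-point porosity deviations seen in fabricated scaffolds originate
in printing, not in this measurement pipeline.

Phantoms (circular channels, single pore, checkerboard) provide analytic
ground truth for porosity and per-pore ECD; truth porosity uses the
analytic pore area over the pixel-counted region area, consistent with
what an ideal measurement of the rasterized image returns.

## Morphometry

Per slice, porosity = pore pixels / total ROI pixels. The alternative
reading of "pore area over scaffold area" (pore/solid) is rejected because
it can exceed 1 and is inconsistent with reported porosities in the 18–23 %
range; the ambiguity is noted here once. Pores are connected components of
the pore phase inside the ROI (8-connectivity default), filtered by the
minimum-size threshold; ECD = 2·√(A/π) with A in µm². Components touching
the ROI/domain boundary are flagged and **included** by default — at 20 %
porosity with large openings, excluding them would discard most of the pore
area — with an exclusion flag provided. SD is the sample SD (n−1), reported
as NaN for n < 2; a stack with no pores yields n = 0 with NaN ECD rather
than an error.

## Numerical and engineering choices

* Arrays are ordered (z, y, x) so axial slices are contiguous; the nodal
  expressions factor into single-axis trig terms and are assembled by
  broadcasting 1-D arrays, keeping a 2.4 M-voxel calibration under a
  second.
* Grids beyond a configurable voxel budget (default 6×10⁸) are rejected
  with a suggestion to coarsen the pitch.
* Degenerate inputs: empty domain masks, empty solids at meshing, empty
  pore phases, and non-watertight meshes each raise (or sentinel) as
  documented on the respective function.
* Determinism: calibration, rendering, degradation and meshing are
  deterministic for fixed inputs; only the Monte-Carlo oracle consumes a
  seed. Re-running any stage from its manifest reproduces outputs.
* Test problem sizes: the suite calibrates the full Ø8 × 3 mm cylinder at
  39.06 µm (= L/64) pitch for the porosity/mesh/consistency checks and uses
  a single 64³ unit-cell box for symmetry, monotonicity and Monte-Carlo
  agreement; the ECD-ordering check runs the cylinder at 40 µm and 20 µm
  pitch to demonstrate grid convergence of the ranking.

## Known limitations

* Graded or hybrid TPMS, non-cubic cells, and lattice distortions are out
  of scope, as are mechanical property prediction and slicing to G-code.
* ECD is a 2-D proxy for pore-opening size; no 3-D pore-network extraction
  or sphere-fitting pore size is attempted.
* DICOM output of real scanners is emulated as TIFF + JSON sidecar; a
  DICOM reader can be hooked into `read_stack` if needed.
* No significance testing across geometries: the in-silico pipeline has no
  physical replicates to test.
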