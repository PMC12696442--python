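# tpmscaffold

Digital design and morphometric analysis of triply-periodic-minimal-surface
(TPMS) tissue-engineering scaffolds.

TPMS scaffolds — smooth, fully interconnected porous architectures built
from the Gyroid, Schwarz Diamond, and Schoen I-WP surfaces — are a standard
platform in bone and cartilage tissue engineering. This package covers the
in-silico half of that workflow, for scaffold designers and micro-CT
analysts:

1. **Design**: evaluate the nodal (trigonometric implicit) equation of a
   geometry over a printable domain, and calibrate the level-set threshold
   by bisection so the realized void fraction matches a target porosity.
2. **Export**: extract a watertight, domain-capped triangle mesh by
   marching cubes and write print-ready binary or ASCII STL.
3. **Quantify**: render the voxel model into binarized axial slice stacks
   (emulating reconstructed micro-CT output), then measure ROI-restricted
   porosity and per-pore **Equivalent Circular Diameter**
   (ECD = 2·√(A/π)) via connected-component labeling with a minimum-size
   noise filter, aggregated as mean ± SD.

## Model

Each geometry is the solid region `{f(x, y, z) ≥ t}` ("skeletal" solid;
a `sheet` mode `{|f| ≤ t}` is also available) of a 2π-periodic nodal field:

| Geometry | f(x, y, z) |
| -------- | ---------- |
| Gyroid   | cos x sin y + sin x cos z + cos y sin z |
| Diamond  | sin x sin y sin z + sin x cos y cos z + cos x sin y cos z + cos x cos y sin z |
| I-WP     | 2(cos x cos y + cos x cos z + cos y cos z) − (cos 2x + cos 2y + cos 2z) |

Dimensionless coordinates map to physical millimetres through a cubic unit
cell of edge L: `x = 2π·X/L`. Porosity φ is the **void** volume fraction of
the domain; the map t ↦ φ(t) is monotone, so bisection pins t to any target
porosity to a tolerance of 10⁻³.

## Worked example

Run the full staged pipeline (design → STL → slices → morphometry →
comparison) for all three geometries on the default Ø8 mm × 3 mm cylinder
at 20 % target porosity, 2.5 mm unit cell, 40 µm voxel pitch:

```sh
tpmscaffold pipeline --out pipe
```

which prints:

```
Geometry comparison (ranked by mean ECD, largest first)

  1. gyroid: porosity 0.2009 +/- 0.0080, ECD 1014.5 +/- 400.5 um (n=811 pores)
  2. diamond: porosity 0.2010 +/- 0.0254, ECD 852.7 +/- 363.8 um (n=1123 pores)
  3. iwp: porosity 0.2004 +/- 0.1387, ECD 689.3 +/- 696.9 um (n=1002 pores)
```

Every geometry realizes the 20 % design porosity to within 0.1 percentage
points, and at matched cell size and porosity the Gyroid presents the
largest mean pore opening, followed by Diamond and I-WP. Per-geometry
outputs land in `pipe/<geometry>/`: the print-ready STL
(`gyroid_0.2_2.5mm.stl`), the voxel model, a run-manifest JSON with every
resolved parameter, the binarized TIFF slice stack with its metadata
sidecar, and `pores.csv` / `slices.csv` / `summary.csv`.

Individual stages are available as `tpmscaffold generate`, `slices`, and
`analyze`; see `--help` for options (config-file support, sheet mode,
degradation of the slices by Gaussian blur + re-thresholding, ROI choices,
minimum pore size).

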