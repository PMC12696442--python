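"""Implicit TPMS scaffold design.

Triply periodic minimal surfaces (TPMS) are approximated by the zero sets of
trigonometric "nodal" functions that are 2*pi-periodic along each axis.  A
solid scaffold is obtained by thresholding such a field over a printable
domain (a cylinder or box), and the threshold is calibrated by bisection so
that the realized void fraction (porosity) matches a design target.

Conventions
-----------
* Porosity means the VOID volume fraction of the domain: a target of 0.2
  leaves 80 % of the domain solid.
* Skeletal solid = ``{f >= t}``, so raising the threshold ``t`` carves away
  more material and porosity is nondecreasing in ``t``.  Sheet solid =
  ``{|f| <= t}`` (a thickened shell around the surface), where porosity is
  nonincreasing in ``t``.
* Dimensionless equation coordinates map to physical millimetres through one
  cubic unit cell of edge ``L``: ``x_dimensionless = 2*pi * X_mm / L``.
* Voxels are classified by their centre point, matching the binarized-image
  semantics of the downstream slice morphometry.

Arrays are ordered ``(z, y, x)`` so that axial slices are contiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import AchievableRangeError, ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

GEOMETRIES = ("gyroid", "diamond", "iwp")

SKELETAL = "skeletal"
SHEET = "sheet"
MODES = (SKELETAL, SHEET)

#: Refuse to allocate grids beyond this many voxels (configurable per call).
DEFAULT_VOXEL_BUDGET = 600_000_000


# ---------------------------------------------------------------------------
# Nodal fields
# ---------------------------------------------------------------------------

def _gyroid(x, y, z):
    return np.cos(x) * np.sin(y) + np.sin(x) * np.cos(z) + np.cos(y) * np.sin(z)


def _diamond(x, y, z):
    sx, cx = np.sin(x), np.cos(x)
    sy, cy = np.sin(y), np.cos(y)
    sz, cz = np.sin(z), np.cos(z)
    return sx * sy * sz + sx * cy * cz + cx * sy * cz + cx * cy * sz


def _iwp(x, y, z):
    cx, cy, cz = np.cos(x), np.cos(y), np.cos(z)
    return 2.0 * (cx * cy + cx * cz + cy * cz) - (
        np.cos(2 * x) + np.cos(2 * y) + np.cos(2 * z)
    )


_FIELDS: dict[str, Callable] = {"gyroid": _gyroid, "diamond": _diamond, "iwp": _iwp}


@dataclass(frozen=True)
class NodalField:
    """A named TPMS implicit function over dimensionless periodic coordinates."""

    geometry_id: str

    def __post_init__(self):
        if self.geometry_id not in _FIELDS:
            raise ValidationError(
                f"unknown geometry {self.geometry_id!r}; choose one of "
                f"{', '.join(GEOMETRIES)}"
            )

    def __call__(self, x, y, z):
        return _FIELDS[self.geometry_id](np.asarray(x), np.asarray(y), np.asarray(z))


def nodal_value(geometry_id: str, point) -> float | np.ndarray:
    """Evaluate the nodal equation of a geometry at a dimensionless point.

    ``point`` is a length-3 sequence ``(x, y, z)``; components may be arrays
    (broadcast together).  Values are finite for finite input.
    """
    f = NodalField(geometry_id)
    x, y, z = point
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValidationError("point components must be finite")
    return f(x, y, z)


# ---------------------------------------------------------------------------
# Design parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """One cubic TPMS period of physical edge length ``edge_length`` (mm)."""

    edge_length: float = 2.5

    def __post_init__(self):
        if not self.edge_length > 0:
            raise ValidationError("unit-cell edge length must be > 0")

    @property
    def scale(self) -> float:
        """Radians of dimensionless coordinate per physical mm (2*pi/L)."""
        return 2.0 * np.pi / self.edge_length


@dataclass(frozen=True)
class DomainSpec:
    """Printable domain: a cylinder (diameter, height) or box (lx, ly, lz), mm.

    ``voxel_pitch`` is the isotropic sampling step in micrometres.  The pitch
    must resolve the smallest domain dimension with at least 10 voxels.
    """

    shape: str = "cylinder"
    dimensions: tuple = (8.0, 3.0)
    voxel_pitch: float = 40.0  # um

    def __post_init__(self):
        if self.shape not in ("cylinder", "box"):
            raise ValidationError(f"unknown domain shape {self.shape!r}; use cylinder or box")
        n_expected = 2 if self.shape == "cylinder" else 3
        if len(self.dimensions) != n_expected:
            raise ValidationError(
                f"{self.shape} domain needs {n_expected} dimensions, got {len(self.dimensions)}"
            )
        if any(d <= 0 for d in self.dimensions) or self.voxel_pitch <= 0:
            raise ValidationError("domain dimensions and voxel pitch must be > 0")
        if self.pitch_mm > min(self.dimensions) / 10.0:
            raise ValidationError(
                "voxel pitch must be at most 1/10 of the smallest domain dimension"
            )

    @property
    def pitch_mm(self) -> float:
        return self.voxel_pitch / 1000.0

    @property
    def extent_mm(self) -> tuple:
        """Bounding-box edge lengths (x, y, z) in mm."""
        if self.shape == "cylinder":
            d, h = self.dimensions
            return (d, d, h)
        return tuple(self.dimensions)

    def grid_shape(self) -> tuple:
        """Number of voxels (nz, ny, nx)."""
        ex, ey, ez = self.extent_mm
        h = self.pitch_mm
        n = lambda e: max(2, int(np.ceil(e / h - 1e-9)))
        return (n(ez), n(ey), n(ex))

    def axes_mm(self):
        """1-D physical voxel-centre coordinates ``(xs, ys, zs)`` in mm.

        x and y are centred on the domain axis; z starts at the bottom face.
        """
        nz, ny, nx = self.grid_shape()
        h = self.pitch_mm
        centred = lambda n: (np.arange(n) - (n - 1) / 2.0) * h
        xs, ys = centred(nx), centred(ny)
        zs = (np.arange(nz) + 0.5) * h
        return xs, ys, zs

    def domain_mask(self) -> np.ndarray:
        """Boolean ``(nz, ny, nx)`` array: voxel centre inside the domain."""
        nz, ny, nx = self.grid_shape()
        if self.shape == "box":
            return np.ones((nz, ny, nx), dtype=bool)
        d, _h = self.dimensions
        xs, ys, _ = self.axes_mm()
        disc = (xs[None, :] ** 2 + ys[:, None] ** 2) <= (d / 2.0) ** 2
        return np.broadcast_to(disc[None, :, :], (nz, ny, nx)).copy()

    def origin_mm(self) -> tuple:
        """Physical coordinate (x, y, z) of voxel (0, 0, 0) centre."""
        xs, ys, zs = self.axes_mm()
        return (float(xs[0]), float(ys[0]), float(zs[0]))


@dataclass(frozen=True)
class LevelSetSpec:
    """Solidification rule: skeletal ``{f >= t}`` or sheet ``{|f| <= t}``."""

    mode: str = SKELETAL
    threshold: float = 0.0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown level-set mode {self.mode!r}; use skeletal or sheet")
        if self.mode == SHEET and self.threshold < 0:
            raise ValidationError("sheet mode requires threshold >= 0")


@dataclass
class VoxelModel:
    """Binary solid/void occupancy on a uniform grid with physical pitch.

    ``occupancy`` and ``domain_mask`` are boolean ``(nz, ny, nx)`` arrays;
    solid voxels never lie outside the domain mask.
    """

    occupancy: np.ndarray
    domain_mask: np.ndarray
    pitch_um: float
    origin_mm: tuple
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.occupancy.shape != self.domain_mask.shape:
            raise ValidationError("occupancy and domain mask shapes differ")
        if np.any(self.occupancy & ~self.domain_mask):
            raise ValidationError("solid voxels found outside the domain mask")


# ---------------------------------------------------------------------------
# Field sampling and solidification
# ---------------------------------------------------------------------------

def field_on_grid(
    geometry_id: str,
    unit_cell: UnitCell,
    domain: DomainSpec,
    voxel_budget: int = DEFAULT_VOXEL_BUDGET,
):
    """Sample the nodal field at voxel centres of the domain grid.

    Returns ``(scalar_grid, domain_mask)`` with arrays ordered (z, y, x).
    Physical coordinates are converted to dimensionless ones via 2*pi/L.
    The nodal expressions factor into single-axis trigonometric terms, so the
    grid is assembled by broadcasting 1-D arrays (no meshgrid allocation).
    """
    f = NodalField(geometry_id)
    nz, ny, nx = domain.grid_shape()
    n_vox = nz * ny * nx
    if n_vox > voxel_budget:
        raise ValidationError(
            f"grid of {n_vox} voxels exceeds the budget of {voxel_budget}; "
            f"coarsen the pitch (currently {domain.voxel_pitch} um) or raise the budget"
        )
    xs, ys, zs = (a * unit_cell.scale for a in domain.axes_mm())
    grid = f(xs[None, None, :], ys[None, :, None], zs[:, None, None])
    return grid, domain.domain_mask()


def solidify(scalar_grid: np.ndarray, level_set: LevelSetSpec, domain_mask: np.ndarray,
             pitch_um: float, origin_mm: tuple = (0.0, 0.0, 0.0), meta: dict | None = None
             ) -> VoxelModel:
    """Threshold a sampled field into a binary solid, clipped to the domain."""
    if level_set.mode == SKELETAL:
        occ = scalar_grid >= level_set.threshold
    else:
        occ = np.abs(scalar_grid) <= level_set.threshold
    occ &= domain_mask
    m = dict(meta or {})
    m.setdefault("mode", level_set.mode)
    m.setdefault("threshold", level_set.threshold)
    return VoxelModel(occ, domain_mask, pitch_um, origin_mm, m)


def void_fraction(model: VoxelModel) -> float:
    """Porosity of the model: 1 - solid voxels / domain voxels."""
    n_dom = int(model.domain_mask.sum())
    if n_dom == 0:
        raise ValidationError("degenerate domain: mask contains no voxels")
    return 1.0 - int(model.occupancy.sum()) / n_dom


def _void_fraction_at(values: np.ndarray, t: float, mode: str) -> float:
    """Void fraction of in-domain field values thresholded at ``t``."""
    if mode == SKELETAL:
        solid = np.count_nonzero(values >= t)
    else:
        solid = np.count_nonzero(np.abs(values) <= t)
    return 1.0 - solid / values.size


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    geometry_id: str
    mode: str
    threshold: float
    realized_void_fraction: float
    target_void_fraction: float
    iterations: int


def calibrate_threshold(
    geometry_id: str,
    unit_cell: UnitCell,
    domain: DomainSpec,
    mode: str = SKELETAL,
    target_void_fraction: float = 0.2,
    tolerance: float = 1e-3,
    max_iterations: int = 60,
    _field_and_mask=None,
) -> CalibrationResult:
    """Bisect the level-set threshold until porosity matches the target.

    The map ``t -> porosity(t)`` is monotone (nondecreasing for skeletal,
    nonincreasing for sheet), so plain bisection converges; the initial
    bracket comes from the sampled field extrema.  Deterministic for fixed
    inputs.  Raises :class:`AchievableRangeError` if the target lies outside
    the porosities realizable at this resolution, and
    :class:`ConvergenceError` (with the last bracket) if ``max_iterations``
    are exhausted before ``|realized - target| <= tolerance``.
    """
    if not 0.0 < target_void_fraction < 1.0:
        raise ValidationError("target void fraction must lie strictly in (0, 1)")
    if tolerance <= 0:
        raise ValidationError("tolerance must be > 0")
    if mode not in MODES:
        raise ValidationError(f"unknown level-set mode {mode!r}")

    if _field_and_mask is None:
        grid, mask = field_on_grid(geometry_id, unit_cell, domain)
    else:
        grid, mask = _field_and_mask
    values = grid[mask]
    if values.size == 0:
        raise ValidationError("degenerate domain: mask contains no voxels")

    eps = 1e-9
    if mode == SKELETAL:
        t_lo, t_hi = float(values.min()) - eps, float(values.max()) + eps
    else:
        t_lo, t_hi = 0.0, float(np.abs(values).max()) + eps

    phi_lo = _void_fraction_at(values, t_lo, mode)
    phi_hi = _void_fraction_at(values, t_hi, mode)
    phi_min, phi_max = sorted((phi_lo, phi_hi))
    if not (phi_min - tolerance <= target_void_fraction <= phi_max + tolerance):
        raise AchievableRangeError(target_void_fraction, phi_min, phi_max)

    increasing = mode == SKELETAL  # porosity vs threshold
    for it in range(1, max_iterations + 1):
        t_mid = 0.5 * (t_lo + t_hi)
        phi = _void_fraction_at(values, t_mid, mode)
        logger.debug(
            "calibrate %s it=%d bracket=[%.6g, %.6g] t=%.6g phi=%.6f",
            geometry_id, it, t_lo, t_hi, t_mid, phi,
        )
        if abs(phi - target_void_fraction) <= tolerance:
            return CalibrationResult(
                geometry_id, mode, t_mid, phi, target_void_fraction, it
            )
        if (phi < target_void_fraction) == increasing:
            t_lo = t_mid
        else:
            t_hi = t_mid
    raise ConvergenceError(
        f"calibration did not converge in {max_iterations} iterations; "
        f"last bracket [{t_lo:.6g}, {t_hi:.6g}]",
        bracket=(t_lo, t_hi),
    )


def build_scaffold(
    geometry_id: str,
    unit_cell: UnitCell | None = None,
    domain: DomainSpec | None = None,
    mode: str = SKELETAL,
    target_void_fraction: float = 0.2,
    tolerance: float = 1e-3,
    max_iterations: int = 60,
):
    """Calibrate and voxelize one scaffold design.

    Returns ``(model, calibration, scalar_grid)``; the grid is returned so the
    surface-extraction step can reuse it without resampling.
    """
    unit_cell = unit_cell or UnitCell()
    domain = domain or DomainSpec()
    grid, mask = field_on_grid(geometry_id, unit_cell, domain)
    cal = calibrate_threshold(
        geometry_id, unit_cell, domain, mode, target_void_fraction,
        tolerance, max_iterations, _field_and_mask=(grid, mask),
    )
    model = solidify(
        grid, LevelSetSpec(mode, cal.threshold), mask,
        pitch_um=domain.voxel_pitch, origin_mm=domain.origin_mm(),
        meta={
            "geometry": geometry_id,
            "unit_cell_mm": unit_cell.edge_length,
            "domain_shape": domain.shape,
            "domain_dimensions_mm": tuple(domain.dimensions),
            "target_void_fraction": target_void_fraction,
            "realized_void_fraction": cal.realized_void_fraction,
        },
    )
    return model, cal, grid


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def monte_carlo_solid_fraction(
    geometry_id: str,
    unit_cell: UnitCell,
    domain: DomainSpec,
    threshold: float = 0.0,
    mode: str = SKELETAL,
    n_points: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Estimate the solid volume fraction by uniform-point integration.

    Independent of the voxel grid: points are drawn uniformly inside the
    domain (rejection sampling for cylinders) and the nodal field evaluated
    directly.  Standard error ~ 0.5/sqrt(n).
    """
    rng = np.random.default_rng(seed)
    ex, ey, ez = domain.extent_mm
    pts = rng.random((n_points, 3)) * np.array([ex, ey, ez])
    pts[:, 0] -= ex / 2.0
    pts[:, 1] -= ey / 2.0
    if domain.shape == "cylinder":
        r2 = (domain.dimensions[0] / 2.0) ** 2
        inside = pts[:, 0] ** 2 + pts[:, 1] ** 2 <= r2
        pts = pts[inside]
    s = unit_cell.scale
    vals = NodalField(geometry_id)(pts[:, 0] * s, pts[:, 1] * s, pts[:, 2] * s)
    if mode == SKELETAL:
        return float(np.mean(vals >= threshold))
    return float(np.mean(np.abs(vals) <= threshold))
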