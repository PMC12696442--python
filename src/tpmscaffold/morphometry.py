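"""Slice morphometry: ROI porosity, per-pore ECD, and aggregation.

Mirrors a standard particle-analysis workflow on binarized cross sections:
a fixed region of interest (ROI) is applied to every slice, porosity is the
pore-pixel fraction of the ROI cross-section, and individual pores are
connected components of the pore phase whose size exceeds a minimum-size
noise threshold.  Pore-opening size is summarized by the equivalent circular
diameter, ECD = 2*sqrt(A/pi), the diameter of the circle with the same area.

Pixels outside the printable domain (carried by the slice stack's domain
mask) are never counted as pore: the pore phase is void *inside* the ROI and
domain.  The standard deviation is the sample SD (n-1 denominator), reported
as NaN when fewer than two observations exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from .errors import ValidationError
from .imaging import SliceStack

DEFAULT_CONNECTIVITY = 8  # particle-analysis convention
DEFAULT_MIN_SIZE_PX = 4


def ecd_from_area(area: float) -> float:
    """Equivalent circular diameter of a region of the given area."""
    return 2.0 * np.sqrt(area / np.pi)


# ---------------------------------------------------------------------------
# ROI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROISpec:
    """Region of interest applied identically to every slice.

    ``full`` selects the whole image; ``circle`` takes ``center`` (x, y) and
    ``radius``; ``rectangle`` takes ``bounds`` (x0, y0, x1, y1), half-open.
    Coordinates are in pixels.
    """

    shape: str = "full"
    center: tuple | None = None
    radius: float | None = None
    bounds: tuple | None = None

    def __post_init__(self):
        if self.shape not in ("full", "circle", "rectangle"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "circle" and (self.center is None or not self.radius or self.radius <= 0):
            raise ValidationError("circular ROI needs a center and a positive radius")
        if self.shape == "rectangle":
            if self.bounds is None or len(self.bounds) != 4:
                raise ValidationError("rectangular ROI needs bounds (x0, y0, x1, y1)")
            x0, y0, x1, y1 = self.bounds
            if x1 <= x0 or y1 <= y0:
                raise ValidationError("rectangular ROI bounds are empty")

    def mask(self, image_shape: tuple) -> np.ndarray:
        """Boolean pixel mask for an image of shape (h, w)."""
        h, w = image_shape
        if self.shape == "full":
            return np.ones((h, w), dtype=bool)
        if self.shape == "circle":
            cx, cy = self.center
            if cx - self.radius < -0.5 or cy - self.radius < -0.5 \
                    or cx + self.radius > w - 0.5 or cy + self.radius > h - 0.5:
                raise ValidationError("circular ROI extends beyond the image bounds")
            yy, xx = np.ogrid[:h, :w]
            return (xx - cx) ** 2 + (yy - cy) ** 2 <= self.radius**2
        x0, y0, x1, y1 = (int(round(v)) for v in self.bounds)
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise ValidationError("rectangular ROI extends beyond the image bounds")
        m = np.zeros((h, w), dtype=bool)
        m[y0:y1, x0:x1] = True
        return m


def _region_mask(binary_slice: np.ndarray, roi: ROISpec, domain_mask=None) -> np.ndarray:
    region = roi.mask(binary_slice.shape)
    if domain_mask is not None:
        region &= domain_mask.astype(bool)
    if not region.any():
        raise ValidationError("ROI is empty (no pixels inside ROI and domain)")
    return region


# ---------------------------------------------------------------------------
# Per-slice measurements
# ---------------------------------------------------------------------------

def slice_porosity(binary_slice, roi: ROISpec, domain_mask=None) -> float:
    """Pore-pixel fraction of the ROI cross-section of one binary slice.

    "Scaffold area" is the whole ROI cross-section, so the result is always
    in [0, 1]; solid = 1, pore = 0 within the domain.
    """
    binary_slice = np.asarray(binary_slice)
    region = _region_mask(binary_slice, roi, domain_mask)
    pore = region & (binary_slice == 0)
    return float(pore.sum()) / float(region.sum())


@dataclass(frozen=True)
class PoreRecord:
    """One connected pore region in one slice."""

    slice_index: int
    label_id: int
    area_um2: float
    ecd_um: float
    centroid_px: tuple  # (x, y)
    touches_roi_boundary: bool


def label_pores(
    binary_slice,
    roi: ROISpec,
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    pixel_size_um: float = 1.0,
    domain_mask=None,
    slice_index: int = 0,
) -> list[PoreRecord]:
    """Connected pore components inside the ROI, noise-filtered by size.

    Components smaller than ``min_size_px`` pixels are discarded (minimum
    size threshold); components whose pixels lie on the ROI/domain boundary
    are flagged.  ECD is computed from the pixel area times pixel_size^2.
    """
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    if min_size_px < 1:
        raise ValidationError("min_size_px must be >= 1")
    binary_slice = np.asarray(binary_slice)
    region = _region_mask(binary_slice, roi, domain_mask)
    pore = region & (binary_slice == 0)
    labels = measure.label(pore, connectivity=1 if connectivity == 4 else 2)
    # ring of region pixels adjacent to the outside of the region (or image edge)
    ring = region & ~ndimage.binary_erosion(region, structure=np.ones((3, 3)), border_value=0)
    boundary_ids = set(np.unique(labels[ring])) - {0}
    records = []
    for rp in measure.regionprops(labels):
        if rp.area < min_size_px:
            continue
        area_um2 = float(rp.area) * pixel_size_um**2
        cy, cx = rp.centroid
        records.append(
            PoreRecord(
                slice_index=slice_index,
                label_id=int(rp.label),
                area_um2=area_um2,
                ecd_um=ecd_from_area(area_um2),
                centroid_px=(float(cx), float(cy)),
                touches_roi_boundary=rp.label in boundary_ids,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _mean_sd(values: np.ndarray) -> tuple:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else float("nan")
    return mean, sd


@dataclass
class PoreStats:
    """Per-slice porosities, pooled pore records, and their aggregates."""

    label: str
    pixel_size_um: float
    slice_porosities: list
    pores: list  # PoreRecord
    mean_porosity: float
    sd_porosity: float
    mean_ecd_um: float
    sd_ecd_um: float
    n_pores: int
    params: dict = field(default_factory=dict)

    def pores_frame(self) -> pd.DataFrame:
        cols = ["slice_index", "label_id", "area_um2", "ecd_um",
                "centroid_x_px", "centroid_y_px", "touches_roi_boundary"]
        rows = [
            (p.slice_index, p.label_id, p.area_um2, p.ecd_um,
             p.centroid_px[0], p.centroid_px[1], p.touches_roi_boundary)
            for p in self.pores
        ]
        return pd.DataFrame(rows, columns=cols)

    def slices_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"slice_index": range(len(self.slice_porosities)),
             "porosity": self.slice_porosities}
        )

    def summary_row(self) -> dict:
        return {
            "label": self.label,
            "mean_porosity": self.mean_porosity,
            "sd_porosity": self.sd_porosity,
            "mean_ecd_um": self.mean_ecd_um,
            "sd_ecd_um": self.sd_ecd_um,
            "n_pores": self.n_pores,
            "pixel_size_um": self.pixel_size_um,
        }


def aggregate(
    stack: SliceStack,
    roi: ROISpec = ROISpec(),
    connectivity: int = DEFAULT_CONNECTIVITY,
    min_size_px: int = DEFAULT_MIN_SIZE_PX,
    include_boundary_pores: bool = True,
    label: str = "scaffold",
) -> PoreStats:
    """Measure every slice of a stack and aggregate.

    Porosity mean/SD is over slices; ECD mean/SD is over pooled pores
    (boundary-touching pores included unless disabled).  A stack whose pore
    phase vanishes after filtering yields ``n_pores = 0`` with NaN ECD
    aggregates rather than an error.
    """
    if stack.n_slices == 0:
        raise ValidationError("empty stack")
    porosities = []
    pores: list[PoreRecord] = []
    for i in range(stack.n_slices):
        dom = None if stack.domain_mask is None else stack.domain_mask[i]
        porosities.append(slice_porosity(stack.slices[i], roi, dom))
        pores.extend(
            label_pores(
                stack.slices[i], roi, connectivity, min_size_px,
                stack.pixel_size, dom, slice_index=i,
            )
        )
    measured = [p for p in pores if include_boundary_pores or not p.touches_roi_boundary]
    mean_p, sd_p = _mean_sd(porosities)
    mean_e, sd_e = _mean_sd([p.ecd_um for p in measured])
    return PoreStats(
        label=label,
        pixel_size_um=stack.pixel_size,
        slice_porosities=porosities,
        pores=pores,
        mean_porosity=mean_p,
        sd_porosity=sd_p,
        mean_ecd_um=mean_e,
        sd_ecd_um=sd_e,
        n_pores=len(measured),
        params={
            "connectivity": connectivity,
            "min_size_px": min_size_px,
            "include_boundary_pores": include_boundary_pores,
            "roi": roi.shape,
        },
    )


def save_stats(stats: PoreStats, out_dir) -> dict:
    """Write pores.csv, slices.csv and summary.csv for one analysis."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pores": out / "pores.csv",
        "slices": out / "slices.csv",
        "summary": out / "summary.csv",
    }
    stats.pores_frame().to_csv(paths["pores"], index=False)
    stats.slices_frame().to_csv(paths["slices"], index=False)
    pd.DataFrame([stats.summary_row()]).to_csv(paths["summary"], index=False)
    return paths


# ---------------------------------------------------------------------------
# Cross-geometry comparison
# ---------------------------------------------------------------------------

def compare_geometries(stats_list: list) -> tuple:
    """Rank geometries by mean ECD and tabulate porosity and pore size.

    Returns ``(DataFrame, text)``.  Requires at least two stats objects with
    pores, all measured at one pixel size (otherwise units are not
    comparable).  Exact ECD ties are flagged.
    """
    usable = [s for s in stats_list if s.n_pores > 0]
    if len(usable) < 2:
        raise ValidationError("need at least two analyses with pores to compare")
    sizes = {s.pixel_size_um for s in usable}
    if len(sizes) > 1:
        raise ValidationError(f"mismatched pixel sizes {sorted(sizes)}; units not comparable")
    rows = [s.summary_row() for s in usable]
    df = pd.DataFrame(rows).sort_values("mean_ecd_um", ascending=False, kind="stable")
    df["rank_by_ecd"] = range(1, len(df) + 1)
    ecds = df["mean_ecd_um"].to_numpy()
    df["ecd_tie"] = [bool(np.any(np.delete(ecds, i) == e)) for i, e in enumerate(ecds)]
    df = df.reset_index(drop=True)
    lines = ["Geometry comparison (ranked by mean ECD, largest first)", ""]
    for _, r in df.iterrows():
        tie = " (tie)" if r["ecd_tie"] else ""
        lines.append(
            f"  {r['rank_by_ecd']}. {r['label']}: porosity "
            f"{r['mean_porosity']:.4f} +/- {r['sd_porosity']:.4f}, "
            f"ECD {r['mean_ecd_um']:.1f} +/- {r['sd_ecd_um']:.1f} um "
            f"(n={int(r['n_pores'])} pores){tie}"
        )
    return df, "\n".join(lines)
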