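"""In-silico micro-CT: binarized slice stacks, phantoms, and stack I/O.

Reconstructed micro-CT output is emulated as a stack of binary axial images
on a uniform isotropic voxel grid.  The renderer keeps three-valued
semantics — solid, in-domain pore, outside-domain background — by carrying a
per-slice domain mask alongside the binary solid image; collapsing to binary
happens only after the region of interest is applied downstream, so exterior
background can never inflate porosity.

Stacks round-trip losslessly as multi-page TIFF plus a JSON metadata sidecar
(pixel size, slice spacing, slice axis).  DICOM readers can be hooked in at
:func:`read_stack` if needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import MetadataError, ValidationError
from .tpms import VoxelModel

_AXIS_TO_DIM = {"z": 0, "y": 1, "x": 2}

_SIDECAR_KEYS = ("pixel_size_um", "slice_spacing_um", "axis")


@dataclass
class SliceStack:
    """Ordered binary 2-D images plus physical pixel geometry.

    ``slices`` is ``(n, h, w)`` with 1 = solid, 0 = pore/background.
    ``domain_mask`` (same shape, optional) marks pixels inside the printable
    domain; where absent the whole image is treated as in-domain.
    ``truth`` optionally records analytic ground truth for phantom stacks.
    """

    slices: np.ndarray
    pixel_size: float  # um
    slice_spacing: float  # um
    axis: str = "z"
    domain_mask: np.ndarray | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.uint8)
        if self.slices.ndim != 3:
            raise ValidationError("slice stack must be a (n, h, w) array")
        if self.pixel_size <= 0 or self.slice_spacing <= 0:
            raise ValidationError("pixel size and slice spacing must be > 0")
        if self.axis not in _AXIS_TO_DIM:
            raise ValidationError("axis must be one of x, y, z")
        if self.domain_mask is not None:
            self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
            if self.domain_mask.shape != self.slices.shape:
                raise ValidationError("domain mask shape must match the slices")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def render_slices(model: VoxelModel, axis: str = "z") -> SliceStack:
    """Slice a voxel model into binary images perpendicular to ``axis``.

    One slice per voxel layer; pixel size and slice spacing both equal the
    voxel pitch.  Voxels outside the domain mask are rendered as background
    (0) and flagged in the stack's domain mask so they are excluded from any
    porosity denominator downstream.
    """
    if axis not in _AXIS_TO_DIM:
        raise ValidationError("axis must be one of x, y, z")
    # occupancy is (z, y, x); move the slicing axis first
    perm = {"z": (0, 1, 2), "y": (1, 0, 2), "x": (2, 0, 1)}[axis]
    occ = np.transpose(model.occupancy, perm)
    dom = np.transpose(model.domain_mask, perm)
    return SliceStack(
        slices=occ.astype(np.uint8),
        pixel_size=model.pitch_um,
        slice_spacing=model.pitch_um,
        axis=axis,
        domain_mask=dom.copy(),
    )


def degrade(
    stack: SliceStack,
    blur_sigma_px: float,
    rebinarize_threshold: float = 0.5,
    seed: int = 0,
) -> SliceStack:
    """Emulate reconstruction smoothing: per-slice Gaussian blur + re-threshold.

    ``blur_sigma_px`` is the Gaussian sigma in pixels; 0 returns the stack
    unchanged.  The result is deterministic for a fixed seed (the seed is
    reserved for future stochastic degradations such as detector noise).
    """
    if blur_sigma_px < 0:
        raise ValidationError("blur sigma must be >= 0")
    if not 0.0 < rebinarize_threshold < 1.0:
        raise ValidationError("rebinarization threshold must lie in (0, 1)")
    del seed  # deterministic pipeline; kept for interface stability
    if blur_sigma_px == 0:
        out = stack.slices.copy()
    else:
        blurred = ndimage.gaussian_filter(
            stack.slices.astype(float), sigma=(0, blur_sigma_px, blur_sigma_px)
        )
        out = (blurred >= rebinarize_threshold).astype(np.uint8)
    return SliceStack(
        out, stack.pixel_size, stack.slice_spacing, stack.axis,
        None if stack.domain_mask is None else stack.domain_mask.copy(),
        dict(stack.truth),
    )


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Analytic ground-truth fixture for the morphometry pipeline.

    ``circular_channels``: ``n_features`` circular through-pores of diameter
    ``feature_diameter_um`` on a square grid with centre spacing
    ``spacing_um``, optionally cut into a disc domain of ``disc_diameter_um``.
    ``single_pore``: one centred circular pore.  ``checkerboard``: alternating
    solid/pore squares of ``checker_px`` pixels.
    """

    kind: str
    image_shape: tuple = (1000, 1000)
    pixel_size_um: float = 10.0
    n_slices: int = 1
    feature_diameter_um: float = 500.0
    n_features: int = 1
    spacing_um: float | None = None
    disc_diameter_um: float | None = None
    checker_px: int = 8

    def __post_init__(self):
        if self.kind not in ("circular_channels", "single_pore", "checkerboard"):
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.pixel_size_um <= 0 or self.n_slices < 1 or self.checker_px < 1:
            raise ValidationError("phantom parameters must be positive")
        if self.feature_diameter_um <= 0 or self.n_features < 1:
            raise ValidationError("phantom parameters must be positive")


def _disc(shape, cy, cx, radius_px):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def make_phantom(spec: PhantomSpec) -> SliceStack:
    """Construct a binary stack with exactly known pore geometry.

    The returned stack's ``truth`` dict holds the analytic porosity and the
    per-pore equivalent circular diameters (um).  Overlapping or out-of-image
    features raise :class:`ValidationError`.
    """
    h, w = spec.image_shape
    px = spec.pixel_size_um
    if spec.kind == "checkerboard":
        yy, xx = np.indices((h, w))
        solid = (((yy // spec.checker_px) + (xx // spec.checker_px)) % 2).astype(np.uint8)
        stack = np.repeat(solid[None], spec.n_slices, axis=0)
        return SliceStack(stack, px, px, "z", truth={"porosity": 0.5, "ecd_um": []})

    r_px = spec.feature_diameter_um / 2.0 / px
    cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
    if spec.kind == "single_pore":
        centres = [(cy0, cx0)]
    else:
        n_side = int(np.ceil(np.sqrt(spec.n_features)))
        pitch = (spec.spacing_um or 2.5 * spec.feature_diameter_um) / px
        if pitch < 2 * r_px + 1:
            raise ValidationError("channel spacing makes features overlap")
        offsets = (np.arange(n_side) - (n_side - 1) / 2.0) * pitch
        centres = [
            (cy0 + oy, cx0 + ox) for oy in offsets for ox in offsets
        ][: spec.n_features]

    domain = None
    if spec.disc_diameter_um is not None:
        dr = spec.disc_diameter_um / 2.0 / px
        if dr > min(h, w) / 2.0:
            raise ValidationError("disc domain does not fit in the image")
        domain = _disc((h, w), cy0, cx0, dr)

    solid = np.ones((h, w), dtype=np.uint8) if domain is None else domain.astype(np.uint8)
    for cy, cx in centres:
        if cy - r_px < 0 or cx - r_px < 0 or cy + r_px > h - 1 or cx + r_px > w - 1:
            raise ValidationError("phantom feature does not fit inside the image")
        pore = _disc((h, w), cy, cx, r_px)
        if domain is not None and np.any(pore & ~domain):
            raise ValidationError("phantom feature extends outside the disc domain")
        solid[pore] = 0

    region_area = float(h * w) if domain is None else float(domain.sum())
    pore_area_px = np.pi * r_px**2 * len(centres)
    truth = {
        "porosity": pore_area_px / region_area,
        "ecd_um": [spec.feature_diameter_um] * len(centres),
        "n_pores_per_slice": len(centres),
    }
    stack = np.repeat(solid[None], spec.n_slices, axis=0)
    dom3 = None if domain is None else np.repeat(domain[None], spec.n_slices, axis=0)
    return SliceStack(stack, px, px, "z", domain_mask=dom3, truth=truth)


# ---------------------------------------------------------------------------
# Stack I/O: multi-page TIFF + JSON sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _mask_path(path: Path) -> Path:
    return path.with_suffix(".domain" + path.suffix)


def write_stack(stack: SliceStack, path) -> None:
    """Write slices as multi-page TIFF with a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.slices, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "slice_spacing_um": stack.slice_spacing,
        "axis": stack.axis,
        "n_slices": stack.n_slices,
        "has_domain_mask": stack.domain_mask is not None,
    }
    if stack.truth:
        meta["truth"] = stack.truth
    if stack.domain_mask is not None:
        tifffile.imwrite(
            _mask_path(path), stack.domain_mask.astype(np.uint8),
            photometric="minisblack",
        )
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_stack(path) -> SliceStack:
    """Read a stack written by :func:`write_stack` (lossless round trip)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(
            f"metadata sidecar {sidecar.name} not found; required keys: "
            + ", ".join(_SIDECAR_KEYS)
        )
    meta = json.loads(sidecar.read_text())
    missing = [k for k in _SIDECAR_KEYS if k not in meta]
    if missing:
        raise MetadataError("sidecar missing required keys: " + ", ".join(missing))
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    mask = None
    if meta.get("has_domain_mask") and _mask_path(path).exists():
        mask = tifffile.imread(_mask_path(path)).astype(bool)
        if mask.ndim == 2:
            mask = mask[None]
    return SliceStack(
        data, meta["pixel_size_um"], meta["slice_spacing_um"], meta["axis"],
        domain_mask=mask, truth=meta.get("truth", {}),
    )
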