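"""Surface extraction and print-ready STL export.

The calibrated implicit solid is turned into a watertight triangle mesh by
marching cubes.  Capping at the domain boundary is done *inside* the scalar
field: the field is min-combined with a signed distance to the domain wall
(positive inside), so the isosurface closes itself at the cylinder wall and
end faces in a single pass instead of relying on post-hoc hole filling.

STL is written in the binary dialect by default (80-byte header, uint32
triangle count, 50 bytes per triangle); coordinates are millimetres, which
STL leaves unlabeled by convention.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .errors import MeshError, ValidationError
from .tpms import DomainSpec, UnitCell

_BINARY_HEADER = b"tpmscaffold binary STL" + b" " * 58  # 80 bytes

_TRI_DTYPE = np.dtype(
    [
        ("normal", "<f4", (3,)),
        ("v0", "<f4", (3,)),
        ("v1", "<f4", (3,)),
        ("v2", "<f4", (3,)),
        ("attr", "<u2"),
    ]
)


@dataclass
class TriangleMesh:
    """Indexed triangle mesh in physical millimetres.

    ``vertices`` is ``(n, 3)`` float, ``faces`` ``(m, 3)`` int with
    consistent outward orientation (signed volume > 0 for a valid solid).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self) -> np.ndarray:
        """Unit outward normals per face (zero for degenerate triangles)."""
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            n = np.where(norm > 0, n / norm, 0.0)
        return n

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.count_nonzero(counts != 2))

    def is_watertight(self) -> bool:
        return self.n_faces > 0 and self.open_edge_count() == 0


def mesh_volume(mesh: TriangleMesh) -> float:
    """Signed enclosed volume (mm^3) via summed tetrahedron contributions.

    Positive for outward orientation.  Requires a watertight mesh; otherwise
    raises :class:`MeshError` naming the open-edge count.
    """
    open_edges = mesh.open_edge_count()
    if open_edges:
        raise MeshError(f"mesh is not watertight: {open_edges} open edge(s)")
    v = mesh.vertices
    f = mesh.faces
    # V = sum det(v0, v1, v2) / 6 over faces (divergence theorem)
    return float(np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]])).sum() / 6.0)


# ---------------------------------------------------------------------------
# Domain signed distance and surface extraction
# ---------------------------------------------------------------------------

def _domain_signed_distance(domain: DomainSpec) -> np.ndarray:
    """Signed distance (mm, positive inside) to the domain wall at voxel centres."""
    xs, ys, zs = domain.axes_mm()
    if domain.shape == "cylinder":
        d, h = domain.dimensions
        r = np.sqrt(xs[None, None, :] ** 2 + ys[None, :, None] ** 2)
        radial = (d / 2.0) - r
        axial = np.minimum(zs, h - zs)[:, None, None]
        return np.minimum(radial, axial)
    lx, ly, lz = domain.dimensions
    dx = np.minimum(xs + lx / 2.0, lx / 2.0 - xs)[None, None, :]
    dy = np.minimum(ys + ly / 2.0, ly / 2.0 - ys)[None, :, None]
    dz = np.minimum(zs, lz - zs)[:, None, None]
    out = np.minimum(np.minimum(dx, dy), dz)
    return np.broadcast_to(out, domain.grid_shape()).copy()


def extract_surface(
    shifted_field: np.ndarray,
    domain: DomainSpec,
    unit_cell: UnitCell | None = None,
) -> TriangleMesh:
    """Marching-cubes isosurface of the solid ``{shifted_field >= 0}``, capped.

    The caller subtracts the calibrated threshold beforehand so the isolevel
    is 0.  ``unit_cell`` (if given) rescales the dimensionless nodal field to
    approximate millimetre units (gradient ~ 2*pi/L), so the min-combination
    with the domain distance stays well conditioned; for fields already in
    physical units leave it as None.  Vertices come out in physical mm.
    """
    shifted_field = np.asarray(shifted_field, dtype=float)
    if shifted_field.ndim != 3 or min(shifted_field.shape) < 2:
        raise ValidationError("scalar grid must be 3-D with at least 2 voxels per axis")
    if shifted_field.shape != domain.grid_shape():
        raise ValidationError(
            f"grid shape {shifted_field.shape} does not match domain grid "
            f"{domain.grid_shape()}"
        )
    if unit_cell is not None:
        field_mm = shifted_field / unit_cell.scale
    else:
        field_mm = shifted_field
    capped = np.minimum(field_mm, _domain_signed_distance(domain))
    if not np.any(capped > 0):
        raise MeshError("no surface at this threshold: solid region is empty")

    h = domain.pitch_mm
    # one pad layer closes caps at the grid border; the ghost value continues
    # the wall-distance ramp (one pitch less than the edge value) so the cap
    # lands on the true wall, clamped negative so no spurious surface appears
    padded = np.pad(capped, 1, mode="edge")
    tiny = -1e-9 * max(1.0, float(np.abs(capped).max()))
    for axis in range(3):
        for sl in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = sl
            layer = padded[tuple(idx)]
            layer -= h
            np.minimum(layer, tiny, out=layer)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.0, spacing=(h, h, h))
    ox, oy, oz = domain.origin_mm()
    # marching cubes indexes (z, y, x); shift by the pad layer and map to physical
    xyz = np.empty_like(verts)
    xyz[:, 0] = verts[:, 2] - h + ox
    xyz[:, 1] = verts[:, 1] - h + oy
    xyz[:, 2] = verts[:, 0] - h + oz
    mesh = TriangleMesh(xyz, faces)
    if mesh_volume(mesh) < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def write_stl(mesh: TriangleMesh, path, format: str = "binary") -> None:
    """Write a mesh as binary (default) or ASCII STL."""
    if format not in ("binary", "ascii"):
        raise ValidationError(f"unknown STL format {format!r}; use binary or ascii")
    if mesh.n_faces > 0xFFFFFFFF:
        raise ValidationError("triangle count exceeds the uint32 limit of binary STL")
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    normals = mesh.face_normals()
    if format == "binary":
        rec = np.zeros(mesh.n_faces, dtype=_TRI_DTYPE)
        rec["normal"] = normals
        rec["v0"], rec["v1"], rec["v2"] = tri[:, 0], tri[:, 1], tri[:, 2]
        with open(path, "wb") as fh:
            fh.write(_BINARY_HEADER)
            fh.write(struct.pack("<I", mesh.n_faces))
            fh.write(rec.tobytes())
        return
    with open(path, "w") as fh:
        fh.write("solid tpmscaffold\n")
        for n, t in zip(normals, tri):
            fh.write(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}\n")
            fh.write("    outer loop\n")
            for v in t:
                fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
            fh.write("    endloop\n")
            fh.write("  endfacet\n")
        fh.write("endsolid tpmscaffold\n")


def _weld(tri_vertices: np.ndarray) -> TriangleMesh:
    """Rebuild an indexed mesh from per-triangle vertices.

    Identical coordinates are merged; vertex order follows first appearance,
    so a write->read round trip of an already-welded mesh reproduces the
    original arrays when coordinates are float32-exact.
    """
    flat = tri_vertices.reshape(-1, 3)
    _, first_idx, inverse = np.unique(
        flat.view([("", flat.dtype)] * 3).ravel(), return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    verts = flat[np.sort(first_idx)]
    faces = rank[inverse].reshape(-1, 3)
    return TriangleMesh(verts, faces)


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file back into an indexed mesh."""
    with open(path, "rb") as fh:
        head = fh.read(80)
        rest = fh.read()
    is_ascii = head.lstrip().startswith(b"solid") and b"facet" in (head + rest[:4096])
    if not is_ascii:
        if len(rest) < 4:
            raise MeshError("truncated binary STL file")
        (count,) = struct.unpack_from("<I", rest, 0)
        body = rest[4 : 4 + count * _TRI_DTYPE.itemsize]
        if len(body) != count * _TRI_DTYPE.itemsize:
            raise MeshError("binary STL body shorter than its declared triangle count")
        rec = np.frombuffer(body, dtype=_TRI_DTYPE)
        tri = np.stack([rec["v0"], rec["v1"], rec["v2"]], axis=1).astype(float)
        return _weld(tri)
    text = (head + rest).decode("ascii", errors="replace")
    coords = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) == 4 and parts[0] == "vertex":
            coords.append([float(p) for p in parts[1:]])
    if len(coords) % 3 != 0:
        raise MeshError("ASCII STL vertex count is not a multiple of 3")
    tri = np.asarray(coords, dtype=np.float32).reshape(-1, 3, 3).astype(float)
    return _weld(tri)


def stl_filename(geometry_id: str, porosity: float, cell_mm: float) -> str:
    """Canonical file name ``{geometry}_{porosity}_{cell}mm.stl``."""
    return f"{geometry_id}_{porosity:g}_{cell_mm:g}mm.stl"
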