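"""Triangulated cortical surface meshes: data model, I/O, synthesis, geometry.

Distances are 3-D Euclidean throughout the package; coordinates are in mm
and vertex indices are 0-based.  File formats (FreeSurfer binary triangle
surface, FreeSurfer "curv" overlays, GIFTI) keep their native conventions
at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh",
    "read_surface",
    "write_surface",
    "read_overlay",
    "write_overlay",
    "make_icosphere",
    "mean_nearest_vertex_distance",
    "vertex_areas",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """A triangulated surface: ``vertices`` (n, 3) float mm, ``faces`` (m, 3) int.

    Invariants are checked at construction: at least one vertex, finite
    coordinates, face indices in range, no degenerate face (repeated index).
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 1:
            raise ValueError("vertices must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(v)):
            raise ValueError("vertex coordinates must be finite")
        if f.size:
            if f.min() < 0 or f.max() >= v.shape[0]:
                raise ValueError("face indices out of range")
            degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            if degen.any():
                raise ValueError(f"degenerate face(s) with repeated vertex index: {np.where(degen)[0][:5]}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


def _gifti_surface(path: str) -> SurfaceMesh:
    import nibabel as nib
    from nibabel.nifti1 import intent_codes

    img = nib.load(path)
    coords = faces = None
    for arr in img.darrays:
        if arr.intent == intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = arr.data
        elif arr.intent == intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = arr.data
    if coords is None or faces is None:
        raise ValueError(f"{path}: GIFTI file lacks a pointset/triangle darray pair")
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int))


def read_surface(path: str | os.PathLike, format: str | None = None) -> SurfaceMesh:
    """Read a surface from FreeSurfer binary triangle format or GIFTI.

    ``format`` is "freesurfer-surf" or "gifti"; if None it is inferred from
    the extension (``.gii`` -> GIFTI, else FreeSurfer). Vertex order is
    preserved exactly as stored.
    """
    import nibabel as nib

    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "gifti" if path.endswith(".gii") else "freesurfer-surf"
    if format not in ("gifti", "freesurfer-surf"):
        raise ValueError(f"unknown surface format: {format!r}")
    try:
        if format == "gifti":
            return _gifti_surface(path)
        coords, faces = nib.freesurfer.read_geometry(path)
        return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int))
    except Exception as exc:  # nibabel raises a zoo of errors on corrupt files
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc


def write_surface(mesh: SurfaceMesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``mesh`` in FreeSurfer binary triangle format or GIFTI."""
    import nibabel as nib

    path = os.fspath(path)
    if format is None:
        format = "gifti" if path.endswith(".gii") else "freesurfer-surf"
    if format == "gifti":
        from nibabel.gifti import GiftiDataArray, GiftiImage

        img = GiftiImage(darrays=[
            GiftiDataArray(mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, path)
    elif format == "freesurfer-surf":
        nib.freesurfer.write_geometry(path, mesh.vertices, mesh.faces)
    else:
        raise ValueError(f"unknown surface format: {format!r}")


def write_overlay(values: np.ndarray, path: str | os.PathLike, mesh: SurfaceMesh | None = None,
                  format: str | None = None) -> None:
    """Write a per-vertex scalar overlay (FreeSurfer curv or GIFTI functional array).

    If ``mesh`` is given, the overlay length must match its vertex count.
    Round-trip precision is float32.
    """
    import nibabel as nib

    values = np.asarray(values, dtype=np.float32).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("overlay values must be finite")
    if mesh is not None and values.size != mesh.n_vertices:
        raise ValueError(f"overlay length {values.size} != vertex count {mesh.n_vertices}")
    path = os.fspath(path)
    if format is None:
        format = "gifti" if path.endswith(".gii") else "freesurfer-curv"
    if format == "gifti":
        from nibabel.gifti import GiftiDataArray, GiftiImage

        img = GiftiImage(darrays=[GiftiDataArray(values, intent="NIFTI_INTENT_NONE")])
        nib.save(img, path)
    elif format == "freesurfer-curv":
        nib.freesurfer.write_morph_data(path, values)
    else:
        raise ValueError(f"unknown overlay format: {format!r}")


def read_overlay(path: str | os.PathLike, format: str | None = None) -> np.ndarray:
    """Read a per-vertex scalar overlay written by :func:`write_overlay`."""
    import nibabel as nib

    path = os.fspath(path)
    if format is None:
        format = "gifti" if path.endswith(".gii") else "freesurfer-curv"
    if format not in ("gifti", "freesurfer-curv"):
        raise ValueError(f"unknown overlay format: {format!r}")
    try:
        if format == "gifti":
            img = nib.load(path)
            return np.asarray(img.darrays[0].data, dtype=np.float64)
        return np.asarray(nib.freesurfer.read_morph_data(path), dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc


# -- synthetic geometry -------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
    [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
    [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
], dtype=float)
_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
], dtype=int)


def make_icosphere(subdivisions: int = 3, radius: float = 100.0) -> SurfaceMesh:
    """Geodesic sphere from recursive icosahedron subdivision.

    ``subdivisions`` n gives 10*4**n + 2 vertices; every vertex lies at
    ``radius`` from the origin.  A synthetic stand-in for a (quasi-uniform)
    cortical sphere, used by simulations and tests.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be non-negative")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 refused (mesh would exceed 655k vertices)")
    verts = [tuple(v) for v in _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0])]
    faces = [tuple(f) for f in _ICO_FACES]
    for _ in range(subdivisions):
        midpoint: dict[tuple[int, int], int] = {}

        def mid(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in midpoint:
                p = np.add(verts[a], verts[b]) / 2.0
                p /= np.linalg.norm(p)
                midpoint[key] = len(verts)
                verts.append(tuple(p))
            return midpoint[key]

        faces = [t for f in faces for t in (
            (f[0], mid(f[0], f[1]), mid(f[0], f[2])),
            (f[1], mid(f[1], f[2]), mid(f[0], f[1])),
            (f[2], mid(f[0], f[2]), mid(f[1], f[2])),
            (mid(f[0], f[1]), mid(f[1], f[2]), mid(f[0], f[2])),
        )]
    v = np.asarray(verts, float)
    v *= radius / np.linalg.norm(v, axis=1, keepdims=True)
    return SurfaceMesh(v, np.asarray(faces, int))


def mean_nearest_vertex_distance(mesh: SurfaceMesh) -> float:
    """Mean over vertices of the Euclidean distance to the closest other vertex.

    Uses a k-d tree; exact (not approximate) nearest neighbours.
    """
    if mesh.n_vertices < 2:
        raise ValueError("need at least 2 vertices")
    tree = cKDTree(mesh.vertices)
    d, _ = tree.query(mesh.vertices, k=2)
    return float(d[:, 1].mean())


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Area (mm^2) of each triangle."""
    v = mesh.vertices
    f = mesh.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area (mm^2): one third of the summed incident triangle areas.

    Sums to the total mesh area exactly; supports mm^2 cluster sizes.
    """
    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    fa = face_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fa / 3.0)
    return out
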