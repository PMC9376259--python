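"""Double-radius dividing: downsampling a cortical surface to "labels".

A label is a small contiguous patch of vertices that becomes the basic
analysis unit.  The dividing sweep walks the vertices in ascending index
order.  An unpainted vertex becomes a seed: unpainted vertices closer than
``r`` (including the seed itself) are painted green and grouped into the
seed's label; unpainted vertices at distance in [r, R) are painted yellow.
Painted vertices (green or yellow) are never seeds, so seed pairs end up
at least R apart and, with R = 2r, the green balls cannot overlap.  After
the sweep every yellow (or otherwise unassigned) vertex joins the label
whose green-member centroid is nearest, ties broken toward the lowest
label id.  All comparisons are strict ("less than") and all distances are
3-D Euclidean.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import SurfaceMesh, vertex_areas

__all__ = [
    "Parcellation",
    "double_radius_divide",
    "label_centers",
    "downsample_series",
    "mean_nearest_label_distance",
    "build_adjacency",
    "label_areas",
    "write_annot",
    "read_annot",
    "write_assignment_tsv",
    "read_assignment_tsv",
    "surface_report",
]


@dataclass
class Parcellation:
    """Vertex-to-label partition produced by :func:`double_radius_divide`.

    ``assignment`` maps each vertex to a label id in 0..n_labels-1; every
    label is non-empty.  ``seeds`` holds each label's seed vertex index and
    ``centers`` the final centroid (mean of member-vertex coordinates, mm).
    ``r``/``R`` record the radii the sweep was run with.
    """

    assignment: np.ndarray
    seeds: np.ndarray
    centers: np.ndarray
    r: float
    R: float
    green: np.ndarray = field(default=None, repr=False)  # bool: painted green in the sweep

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.int64)
        L = int(a.max()) + 1 if a.size else 0
        if a.size == 0:
            raise ValueError("empty assignment")
        counts = np.bincount(a, minlength=L)
        if a.min() < 0 or (counts == 0).any():
            raise ValueError("labels must be consecutive 0..L-1 and non-empty")
        self.assignment = a

    @property
    def n_vertices(self) -> int:
        return self.assignment.size

    @property
    def n_labels(self) -> int:
        return self.seeds.size

    def members(self, label: int) -> np.ndarray:
        return np.where(self.assignment == label)[0]


def double_radius_divide(mesh: SurfaceMesh, r: float = 0.9, R: float | None = None) -> Parcellation:
    """Partition ``mesh`` vertices into labels with the double-radius sweep.

    Parameters
    ----------
    r : inner grouping radius in mm (default 0.9).
    R : exclusion ("double") radius in mm; defaults to 2*r.  Seeds end up
        pairwise >= R apart, which prevents overlap of neighbouring labels.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    R = 2.0 * r if R is None else float(R)
    if R < r:
        raise ValueError("R must be >= r")
    xyz = mesh.vertices
    n = mesh.n_vertices
    tree = cKDTree(xyz)

    UNPAINTED, GREEN, YELLOW = 0, 1, 2
    paint = np.zeros(n, dtype=np.int8)
    assignment = np.full(n, -1, dtype=np.int64)
    seeds: list[int] = []

    for v in range(n):
        if paint[v] != UNPAINTED:
            continue
        label = len(seeds)
        seeds.append(v)
        ball = tree.query_ball_point(xyz[v], R)
        ball = np.asarray(ball, dtype=np.int64)
        ball = ball[paint[ball] == UNPAINTED]
        d = np.linalg.norm(xyz[ball] - xyz[v], axis=1)
        inner = ball[d < r]          # strict: "less than a 0.9-mm radius"
        outer = ball[(d >= r) & (d < R)]
        paint[inner] = GREEN
        assignment[inner] = label
        paint[outer] = YELLOW

    green = assignment >= 0
    # centroids of green members only (the sweep-time "center positions")
    L = len(seeds)
    green_centers = np.zeros((L, 3))
    counts = np.bincount(assignment[green], minlength=L).astype(float)
    for k in range(3):
        green_centers[:, k] = np.bincount(assignment[green], weights=xyz[green, k],
                                          minlength=L) / counts

    leftover = np.where(~green)[0]
    if leftover.size:
        # nearest green centroid; exact distance ties go to the lowest label id
        ctree = cKDTree(green_centers)
        dmin, nearest = ctree.query(xyz[leftover])
        tied = ctree.query_ball_point(xyz[leftover], dmin * (1 + 1e-12) + 1e-300)
        assignment[leftover] = [min(c) if len(c) > 1 else nearest[i]
                                for i, c in enumerate(tied)]

    final_centers = np.zeros((L, 3))
    counts = np.bincount(assignment, minlength=L).astype(float)
    for k in range(3):
        final_centers[:, k] = np.bincount(assignment, weights=xyz[:, k], minlength=L) / counts

    return Parcellation(assignment=assignment, seeds=np.asarray(seeds, dtype=np.int64),
                        centers=final_centers, r=r, R=R, green=green)


def label_centers(parc: Parcellation, mesh: SurfaceMesh, membership: str = "final") -> np.ndarray:
    """(L, 3) label centroids: mean member-vertex coordinates.

    ``membership="green-only"`` uses only vertices painted green during the
    sweep (the centers the yellow-assignment step saw); ``"final"`` uses
    all members after yellow assignment.
    """
    if membership not in ("final", "green-only"):
        raise ValueError("membership must be 'final' or 'green-only'")
    mask = np.ones(parc.n_vertices, bool) if membership == "final" else parc.green
    L = parc.n_labels
    counts = np.bincount(parc.assignment[mask], minlength=L).astype(float)
    if (counts == 0).any():
        raise ValueError("a label has no members under the requested membership")
    out = np.zeros((L, 3))
    for k in range(3):
        out[:, k] = np.bincount(parc.assignment[mask], weights=mesh.vertices[mask, k],
                                minlength=L) / counts
    return out


def downsample_series(series: np.ndarray, parc: Parcellation) -> np.ndarray:
    """Average a (n_vertices, n_frames) series into label space.

    Returns (n_labels, n_frames): unweighted mean of member-vertex BOLD
    values per frame.
    """
    series = np.asarray(series, float)
    if series.shape[0] != parc.n_vertices:
        raise ValueError(f"series has {series.shape[0]} vertices, parcellation {parc.n_vertices}")
    L = parc.n_labels
    counts = np.bincount(parc.assignment, minlength=L).astype(float)
    out = np.zeros((L, series.shape[1]))
    for t in range(series.shape[1]):
        out[:, t] = np.bincount(parc.assignment, weights=series[:, t], minlength=L)
    return out / counts[:, None]


def mean_nearest_label_distance(parc: Parcellation) -> float:
    """Mean over labels of the center-to-center distance to the nearest other label."""
    if parc.n_labels < 2:
        raise ValueError("need at least 2 labels")
    tree = cKDTree(parc.centers)
    d, _ = tree.query(parc.centers, k=2)
    return float(d[:, 1].mean())


def build_adjacency(parc: Parcellation, mesh: SurfaceMesh, threshold: float = 1.1):
    """Boolean (L, L) adjacency: labels are adjacent iff their closest
    vertex-vertex distance is strictly below ``threshold`` mm.

    Irreflexive and symmetric.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    L = parc.n_labels
    adj = np.zeros((L, L), dtype=bool)
    tree = cKDTree(mesh.vertices)
    pairs = tree.query_pairs(threshold, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(mesh.vertices[pairs[:, 0]] - mesh.vertices[pairs[:, 1]], axis=1)
        pairs = pairs[d < threshold]  # query_pairs is <=; the criterion is strict
        a, b = parc.assignment[pairs[:, 0]], parc.assignment[pairs[:, 1]]
        keep = a != b
        adj[a[keep], b[keep]] = True
        adj[b[keep], a[keep]] = True
    return adj


def label_areas(parc: Parcellation, mesh: SurfaceMesh) -> np.ndarray:
    """Per-label surface area in mm^2 (sum of member vertex areas)."""
    va = vertex_areas(mesh)
    return np.bincount(parc.assignment, weights=va, minlength=parc.n_labels)


# -- persistence --------------------------------------------------------------

def write_annot(parc: Parcellation, path: str | os.PathLike) -> None:
    """Export as a FreeSurfer .annot with a generated colour table."""
    import nibabel as nib

    L = parc.n_labels
    rng = np.random.default_rng(0)  # colours are cosmetic; fixed for determinism
    ctab = np.zeros((L, 5), dtype=np.int64)
    ctab[:, :3] = rng.integers(0, 256, size=(L, 3))
    # ensure unique annotation values (b + 256 g + 65536 r)
    while len({tuple(row[:3]) for row in ctab}) < L:
        ctab[:, :3] = rng.integers(0, 256, size=(L, 3))
    names = [f"label_{i:06d}".encode() for i in range(L)]
    nib.freesurfer.write_annot(os.fspath(path), parc.assignment.astype(np.int32), ctab, names)


def read_annot(path: str | os.PathLike) -> np.ndarray:
    """Read back the vertex->label assignment from a .annot file."""
    import nibabel as nib

    labels, _, _ = nib.freesurfer.read_annot(os.fspath(path))
    return np.asarray(labels, dtype=np.int64)


def write_assignment_tsv(parc: Parcellation, path: str | os.PathLike) -> None:
    """Language-neutral TSV dialect: columns vertex_index, label_id."""
    import pandas as pd

    pd.DataFrame({"vertex_index": np.arange(parc.n_vertices),
                  "label_id": parc.assignment}).to_csv(path, sep="\t", index=False)


def read_assignment_tsv(path: str | os.PathLike) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out = np.full(len(df), -1, dtype=np.int64)
    out[df["vertex_index"].to_numpy()] = df["label_id"].to_numpy()
    return out


def surface_report(mesh: SurfaceMesh, r: float = 0.9, R: float | None = None,
                   searchlight_radius: float = 10.0) -> dict:
    """Summary statistics of a surface and its double-radius parcellation.

    Returns vertex count, mean nearest-vertex distance, label count, mean
    nearest-label center distance, and the searchlight member-count range —
    the quantities used to characterise a template surface.  Note the
    statistics depend on which geometry (white/pial/inflated) the mesh
    carries.
    """
    from .decoding import build_searchlights

    from .mesh import mean_nearest_vertex_distance

    parc = double_radius_divide(mesh, r=r, R=R)
    sl = build_searchlights(parc.centers, radius=searchlight_radius)
    sizes = np.array([len(s) for s in sl])
    return {
        "n_vertices": mesh.n_vertices,
        "mean_nearest_vertex_distance_mm": mean_nearest_vertex_distance(mesh),
        "n_labels": parc.n_labels,
        "mean_nearest_label_distance_mm": mean_nearest_label_distance(parc),
        "searchlight_members_min": int(sizes.min()),
        "searchlight_members_max": int(sizes.max()),
        "vertices_per_label": mesh.n_vertices / parc.n_labels,
    }
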