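"""Second-level (random-effects) inference over label maps.

Per-subject statistics (decoding accuracies, amplitudes, correlations,
slopes) are treated as samples from a population: one-sample t-tests
against chance, Benjamini-Hochberg FDR over each frame's labels, and
cluster extraction on the label-adjacency graph with a strict minimum
cluster size.

Degenerate zero-variance cases use conservative conventions: all subjects
exactly at chance gives t=0, p=0.5; zero variance strictly above chance
gives p=0 flagged degenerate; an all-zero slope sample gives p=1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StatMap",
    "Cluster",
    "ClusterSet",
    "ttest_vs_chance",
    "fdr_mask",
    "extract_clusters",
    "significant_map",
    "group_slope_test",
]


@dataclass
class StatMap:
    """Per-label statistics: t, one- or two-sided p, and the effect mean."""

    t: np.ndarray
    p: np.ndarray
    effect: np.ndarray
    degenerate: np.ndarray = None

    def __post_init__(self):
        if self.degenerate is None:
            self.degenerate = np.zeros_like(np.asarray(self.p), dtype=bool)


@dataclass
class Cluster:
    members: np.ndarray      # label ids
    size: int                # member count ("cluster size (label)")
    area_mm2: float          # sum of member label areas
    peak: int                # member with max |t|


@dataclass
class ClusterSet:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def member_mask(self, n_labels: int) -> np.ndarray:
        mask = np.zeros(n_labels, dtype=bool)
        for c in self.clusters:
            mask[c.members] = True
        return mask

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([
            {"cluster": i, "size_labels": c.size, "size_mm2": c.area_mm2,
             "peak_label": c.peak, "n_members": len(c.members)}
            for i, c in enumerate(self.clusters)
        ])


def _onesample_t(values: np.ndarray, popmean: float, alternative: str):
    """One-sample t along axis 0 with explicit zero-variance conventions."""
    values = np.asarray(values, float)
    n = values.shape[0]
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - popmean) / (sd / np.sqrt(n))
    df = n - 1
    if alternative == "greater":
        p = stats.t.sf(t, df)
    elif alternative == "two-sided":
        p = 2 * stats.t.sf(np.abs(t), df)
    else:
        raise ValueError(alternative)
    # zero variance: at popmean -> t=0, p=0.5 (1.0 two-sided); off popmean -> p=0
    at = degenerate & (mean == popmean)
    off = degenerate & (mean != popmean)
    t = np.where(at, 0.0, t)
    p = np.where(at, 0.5 if alternative == "greater" else 1.0, p)
    if alternative == "greater":
        p = np.where(off & (mean > popmean), 0.0, p)
        p = np.where(off & (mean < popmean), 1.0, p)
        t = np.where(off & (mean > popmean), np.inf, t)
        t = np.where(off & (mean < popmean), -np.inf, t)
    else:
        p = np.where(off, 0.0, p)
        with np.errstate(invalid="ignore"):
            t = np.where(off, np.sign(mean - popmean) * np.inf, t)
    return t, p, mean, degenerate


def ttest_vs_chance(maps: np.ndarray, chance: float, tail: str = "greater") -> StatMap:
    """One-sample t across subjects (axis 0) of accuracies against chance.

    ``maps`` is (subjects, labels) or (subjects, labels, frames); the test
    is unilateral (mean > chance) by default.
    """
    maps = np.asarray(maps, float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    t, p, mean, degen = _onesample_t(maps, chance, tail)
    return StatMap(t=t, p=p, effect=mean, degenerate=degen)


def fdr_mask(p: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``.

    The family is exactly the supplied array (typically one frame's labels).
    """
    p = np.asarray(p, float).ravel()
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.where(below)[0])
        mask[order[: k + 1]] = True
    return mask


def extract_clusters(mask: np.ndarray, adjacency: np.ndarray, stat: StatMap | None = None,
                     areas: np.ndarray | None = None) -> ClusterSet:
    """Group masked labels into connected clusters on the adjacency graph.

    Equivalent to the recursive flood-fill: a masked label and every masked
    label reachable through adjacent masked labels form one cluster.
    Returns member ids, size in labels, area in mm^2 and the peak (max |t|)
    label per cluster.
    """
    mask = np.asarray(mask, bool)
    idx = np.where(mask)[0]
    cs = ClusterSet()
    if idx.size == 0:
        return cs
    sub = np.asarray(adjacency, bool)[np.ix_(idx, idx)]
    n_comp, comp = connected_components(csr_matrix(sub), directed=False)
    tvals = None if stat is None else np.abs(np.nan_to_num(np.asarray(stat.t, float)))
    for c in range(n_comp):
        members = idx[comp == c]
        area = float(np.sum(areas[members])) if areas is not None else float("nan")
        peak = int(members[np.argmax(tvals[members])]) if tvals is not None else int(members[0])
        cs.clusters.append(Cluster(members=members, size=members.size, area_mm2=area, peak=peak))
    return cs


def significant_map(stat: StatMap, adjacency: np.ndarray, p_thresh: float = 1e-4,
                    fdr_q: float | None = 0.01, min_cluster_labels: int = 10,
                    areas: np.ndarray | None = None) -> ClusterSet:
    """Thresholded cluster map for one frame.

    The survival mask is ``p < p_thresh`` AND (when ``fdr_q`` is given)
    BH-FDR rejection at ``fdr_q`` over this frame's labels; only clusters
    with strictly more than ``min_cluster_labels`` members are retained.
    """
    p = np.asarray(stat.p, float)
    mask = p < p_thresh
    if fdr_q is not None:
        mask &= fdr_mask(p, fdr_q)
    cs = extract_clusters(mask, adjacency, stat=stat, areas=areas)
    cs.clusters = [c for c in cs.clusters if c.size > min_cluster_labels]
    return cs


def group_slope_test(values: np.ndarray, loads: np.ndarray = None) -> StatMap:
    """Group-level load regression: per-subject OLS slope + one-sample t.

    ``values`` is (subjects, conditions[, labels]); ``loads`` the predictor
    (default 1..n_conditions).  Each subject's value is regressed on load
    by ordinary least squares; the slopes are tested against 0 with a
    two-sided one-sample t across subjects.  The effect is the mean slope.
    """
    values = np.asarray(values, float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if values.shape[1] < 2:
        raise ValueError("need at least 2 load levels")
    loads = np.arange(1, values.shape[1] + 1, dtype=float) if loads is None else np.asarray(loads, float)
    x = loads - loads.mean()
    denom = np.sum(x**2)
    # slope_s = sum_c x_c * v_{s,c,...} / sum x^2  (per subject, vectorised)
    slopes = np.tensordot(values, x, axes=([1], [0])) / denom
    t, p, mean, degen = _onesample_t(slopes, 0.0, "two-sided")
    # all-zero-slope convention: no effect anywhere -> p = 1
    zero = degen & (mean == 0)
    p = np.where(zero, 1.0, p)
    return StatMap(t=t, p=p, effect=mean, degenerate=degen)
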