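"""Seed-based trial-wise functional connectivity and its load regression.

For each ROI (a seed label averaged with its adjacent labels) and each
trial, the Pearson correlation between the ROI's 21-s BOLD curve and every
label's 21-s curve is computed; correlations are averaged within each
memory load (1-4) to give a (subjects, loads, labels) tensor, whose load
regression (p < 0.05, cluster > 10) maps areas whose coupling with the
seed scales with memory load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import N_FRAMES, TrialTable
from .inference import ClusterSet, StatMap, group_slope_test, significant_map

__all__ = [
    "RoiSpec",
    "roi_from_coordinate",
    "roi_curve",
    "trial_connectivity",
    "condition_connectivity",
    "connectivity_load_map",
    "connectivity_to_tsv",
]

LOADS = (1, 2, 3, 4)


@dataclass(frozen=True)
class RoiSpec:
    """A seed region: named seed label, optionally averaged with its adjacent labels."""

    name: str
    seed: int
    include_adjacent: bool = True


def roi_from_coordinate(name: str, xyz, centers: np.ndarray,
                        include_adjacent: bool = True) -> RoiSpec:
    """Snap a coordinate (same space as the label centers, mm) to the nearest label.

    Stereotaxic (e.g. Talairach) coordinates must be transformed into the
    template space by the caller beforehand.
    """
    d = np.linalg.norm(np.asarray(centers, float) - np.asarray(xyz, float), axis=1)
    return RoiSpec(name=name, seed=int(np.argmin(d)), include_adjacent=include_adjacent)


def roi_curve(series: np.ndarray, roi: RoiSpec, adjacency: np.ndarray) -> np.ndarray:
    """ROI time series: unweighted mean over the seed and (optionally) its adjacent labels."""
    if not 0 <= roi.seed < series.shape[0]:
        raise ValueError(f"seed label {roi.seed} outside parcellation")
    members = [roi.seed]
    if roi.include_adjacent:
        members += list(np.where(np.asarray(adjacency, bool)[roi.seed])[0])
    return series[np.asarray(members)].mean(axis=0)


def trial_connectivity(roi_ts: np.ndarray, series: np.ndarray, onset: int,
                       window: int = N_FRAMES) -> np.ndarray:
    """Pearson r between the ROI window and each label's window for one trial.

    Windows are the ``window`` frames starting at the trial onset.  A
    zero-variance window on either side yields NaN (flagged undefined;
    excluded from later averaging).
    """
    if onset < 0 or onset + window > series.shape[1]:
        raise ValueError(f"window [{onset}, {onset + window}) outside run")
    x = roi_ts[onset: onset + window]
    Y = series[:, onset: onset + window]
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xnorm = np.sqrt(np.sum(xc**2))
    ynorm = np.sqrt(np.sum(Yc**2, axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Yc @ xc) / (ynorm * xnorm)
    r[~np.isfinite(r)] = np.nan
    if xnorm == 0:
        r[:] = np.nan
    return np.clip(r, -1.0, 1.0)  # guard float round-off; NaN passes through


def condition_connectivity(series_per_run: dict[int, np.ndarray], trials: TrialTable,
                           roi: RoiSpec, adjacency: np.ndarray,
                           window: int = N_FRAMES) -> np.ndarray:
    """Mean per-trial ROI-label correlation within each memory load, one subject.

    Returns (4, n_labels) for loads 1-4; control trials never contribute.
    Undefined (zero-variance) trial correlations are dropped from the mean;
    a load with no usable trial raises.
    """
    roi_ts = {run: roi_curve(series_per_run[run], roi, adjacency) for run in series_per_run}
    n_labels = next(iter(series_per_run.values())).shape[0]
    out = np.zeros((len(LOADS), n_labels))
    for li, load in enumerate(LOADS):
        sel = np.where(trials.condition == load)[0]
        rs = [trial_connectivity(roi_ts[int(trials.run[i])], series_per_run[int(trials.run[i])],
                                 int(trials.onset[i]), window) for i in sel]
        if not rs:
            raise ValueError(f"no trials of load {load}")
        stacked = np.asarray(rs)
        if np.all(np.isnan(stacked)):
            raise ValueError(f"load {load}: no usable (finite-variance) trials")
        with np.errstate(invalid="ignore"):
            out[li] = np.nanmean(stacked, axis=0)  # labels with no usable trial stay NaN
    return out


def connectivity_load_map(tensor: np.ndarray, adjacency: np.ndarray,
                          p_thresh: float = 0.05, min_cluster_labels: int = 10,
                          areas: np.ndarray | None = None) -> tuple[StatMap, ClusterSet]:
    """Load regression of a (subjects, loads, labels) connectivity tensor.

    Per-subject OLS slope of r on load, one-sample t across subjects, then
    clustering at p < ``p_thresh`` with > ``min_cluster_labels`` labels.
    """
    stat = group_slope_test(tensor)
    cs = significant_map(stat, adjacency, p_thresh=p_thresh, fdr_q=None,
                         min_cluster_labels=min_cluster_labels, areas=areas)
    return stat, cs


def connectivity_to_tsv(tensor: np.ndarray, roi_name: str, path) -> None:
    """Long-format TSV (subject, roi, load, label, r) for a (S, 4, L) tensor."""
    import pandas as pd

    S, nL, L = tensor.shape
    idx = np.indices((S, nL, L)).reshape(3, -1)
    pd.DataFrame({"subject": idx[0], "roi": roi_name, "load": idx[1] + 1,
                  "label": idx[2], "r": tensor.ravel()}).to_csv(path, sep="\t", index=False)
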