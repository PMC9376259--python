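"""HRF-based response-strength analysis.

Condition onset times (21-s boxcars) are convolved with a canonical
double-gamma hemodynamic response function to build GLM regressors; OLS
betas per label feed paired contrasts between adjacent load conditions
(element-wise threshold plus sign-flip cluster-wise calibration).
Trial-averaged, control-subtracted, baseline-zeroed 21-s response curves
give an average amplitude per (subject, load, label), which enters the
group load regression (p < 0.05, cluster > 10, no FDR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoding import N_FRAMES, TrialTable
from .inference import ClusterSet, StatMap, extract_clusters, group_slope_test, significant_map

__all__ = [
    "HRFSpec",
    "canonical_hrf",
    "build_design",
    "fit_glm",
    "adjacent_contrasts",
    "response_curves",
    "curve_amplitude",
    "amplitude_load_map",
]


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters (seconds).

    Defaults are the common canonical form: response peak 6 s, undershoot
    peak 16 s, unit dispersions, peak:undershoot ratio 6.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 6.0
    frame_period: float = 1.0

    def __post_init__(self):
        if min(self.peak_delay, self.undershoot_delay, self.peak_dispersion,
               self.undershoot_dispersion, self.ratio, self.frame_period) <= 0:
            raise ValueError("all HRF parameters must be positive")


def canonical_hrf(spec: HRFSpec = HRFSpec(), length: float = 32.0) -> np.ndarray:
    """Double-gamma HRF sampled at the frame period, peak-normalised to 1.

    h(t) = g(t; peak) - g(t; undershoot)/ratio with gamma-pdf lobes; h(0)=0.
    """
    if length < 21:
        raise ValueError("length must cover the 21-s analysis window")
    t = np.arange(0, length, spec.frame_period)
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    h = peak - under / spec.ratio
    return h / h.max()


def build_design(trials: TrialTable, run_lengths: dict[int, int],
                 duration: float = 21.0, hrf: np.ndarray | None = None,
                 conditions=(0, 1, 2, 3, 4)) -> dict[int, np.ndarray]:
    """Per-run GLM design: one HRF-convolved boxcar regressor per condition.

    Each trial contributes a ``duration``-second boxcar at its onset
    (overlapping same-condition boxcars sum); the final column is the
    intercept.  Returns run id -> (frames, n_conditions + 1) matrix.
    """
    hrf = canonical_hrf() if hrf is None else np.asarray(hrf, float)
    dur = int(round(duration))
    designs = {}
    for run, n_frames in run_lengths.items():
        X = np.zeros((n_frames, len(conditions) + 1))
        for j, cond in enumerate(conditions):
            box = np.zeros(n_frames)
            sel = (trials.run == run) & (trials.condition == cond)
            for onset in trials.onset[sel]:
                box[onset: onset + dur] += 1.0
            X[:, j] = np.convolve(box, hrf)[:n_frames]
        X[:, -1] = 1.0
        designs[run] = X
    return designs


def fit_glm(series_per_run: dict[int, np.ndarray], designs: dict[int, np.ndarray]) -> np.ndarray:
    """OLS betas per label, runs concatenated with run-wise intercepts.

    Returns (n_labels, n_conditions): condition betas in a.u. (per-run
    intercepts estimated and discarded).  Raises on rank deficiency,
    naming the collinear columns.
    """
    runs = sorted(designs)
    n_cond = designs[runs[0]].shape[1] - 1
    Y = np.concatenate([series_per_run[r].T for r in runs], axis=0)  # frames x labels
    blocks = []
    for i, r in enumerate(runs):
        X = designs[r]
        inter = np.zeros((X.shape[0], len(runs)))
        inter[:, i] = 1.0
        blocks.append(np.hstack([X[:, :n_cond], inter]))
    Xfull = np.concatenate(blocks, axis=0)
    rank = np.linalg.matrix_rank(Xfull)
    if rank < Xfull.shape[1]:
        # identify offending columns by leave-one-out rank
        bad = [j for j in range(n_cond)
               if np.linalg.matrix_rank(np.delete(Xfull, j, axis=1)) == rank]
        raise ValueError(f"design is rank deficient; collinear condition columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xfull, Y, rcond=None)
    return beta[:n_cond].T


def adjacent_contrasts(betas: np.ndarray, adjacency: np.ndarray,
                       element_p: float = 0.01, cluster_p: float = 0.05,
                       n_permutations: int = 500,
                       rng: np.random.Generator | int | None = 0):
    """Paired t-tests of beta(c+1) - beta(c) with sign-flip cluster control.

    ``betas`` is (subjects, conditions, labels).  For each adjacent pair of
    conditions, subject difference maps are tested against zero (two-sided,
    element threshold ``element_p``); clusters of surviving labels are kept
    when their size exceeds the ``1 - cluster_p`` quantile of the maximum
    cluster size under random sign flips of the subject difference maps.
    Returns a list of (StatMap, ClusterSet) per contrast.
    """
    betas = np.asarray(betas, float)
    if betas.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    from .inference import _onesample_t

    out = []
    for c in range(betas.shape[1] - 1):
        diff = betas[:, c + 1] - betas[:, c]  # subjects x labels
        t, p, mean, degen = _onesample_t(diff, 0.0, "two-sided")
        stat = StatMap(t=t, p=p, effect=mean, degenerate=degen)
        # null distribution of the max cluster size under sign flips
        n_sub = diff.shape[0]
        max_sizes = np.zeros(n_permutations)
        for i in range(n_permutations):
            flip = rng.choice([-1.0, 1.0], size=n_sub)[:, None]
            tp, pp, _, _ = _onesample_t(diff * flip, 0.0, "two-sided")
            cs = extract_clusters(pp < element_p, adjacency)
            max_sizes[i] = max((c_.size for c_ in cs), default=0)
        crit = np.quantile(max_sizes, 1 - cluster_p)
        observed = extract_clusters(p < element_p, adjacency, stat=stat)
        observed.clusters = [cl for cl in observed.clusters if cl.size > crit]
        out.append((stat, observed))
    return out


def response_curves(series_per_run: dict[int, np.ndarray], trials: TrialTable,
                    condition: int, control: int = 0) -> np.ndarray:
    """Control-subtracted, baseline-zeroed mean 21-s response curve per label.

    Averages frames [onset-1, onset+20] over the condition's trials and
    over the control trials, subtracts control from condition, then shifts
    so the pre-onset (baseline) sample is zero.  Returns (n_labels, 21):
    the post-onset samples (seconds 0..20 from stimulus onset).
    """
    def mean_window(cond):
        sel = np.where(trials.condition == cond)[0]
        if sel.size == 0:
            raise ValueError(f"no trials of condition {cond}")
        wins = []
        for i in sel:
            data = series_per_run[int(trials.run[i])]
            o = int(trials.onset[i])
            if o - 1 < 0 or o + N_FRAMES > data.shape[1]:
                raise ValueError(f"trial {i}: window [{o - 1}, {o + N_FRAMES}) outside run")
            wins.append(data[:, o - 1: o + N_FRAMES])
        return np.mean(wins, axis=0)  # labels x 22

    diff = mean_window(condition) - mean_window(control)
    diff = diff - diff[:, :1]  # zero the baseline (onset - 1 s) sample
    return diff[:, 1:]


def curve_amplitude(curve: np.ndarray) -> np.ndarray:
    """Average amplitude of a response curve: arithmetic mean of its 21 samples."""
    curve = np.asarray(curve, float)
    if curve.shape[-1] != N_FRAMES:
        raise ValueError(f"expected {N_FRAMES} samples, got {curve.shape[-1]}")
    return curve.mean(axis=-1)


def amplitude_load_map(amplitudes: np.ndarray, adjacency: np.ndarray,
                       p_thresh: float = 0.05, min_cluster_labels: int = 10,
                       areas: np.ndarray | None = None) -> tuple[StatMap, ClusterSet]:
    """Load regression of response amplitudes: slope test + cluster threshold.

    ``amplitudes`` is (subjects, loads, labels).  Delegates to
    :func:`group_slope_test` and clusters labels with p < ``p_thresh``
    (no FDR) keeping clusters of > ``min_cluster_labels`` labels.
    """
    stat = group_slope_test(amplitudes)
    cs = significant_map(stat, adjacency, p_thresh=p_thresh, fdr_q=None,
                         min_cluster_labels=min_cluster_labels, areas=areas)
    return stat, cs
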