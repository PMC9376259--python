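"""Surface searchlight construction and frame-by-frame cross-validated decoding.

Each label gets a searchlight: the set of labels whose centers lie strictly
within a fixed radius (default 10 mm) of its own center.  For every frame
offset 0..20 s after stimulus onset, the member labels' BOLD values form
one instance per trial; a multiclass SVM (one-vs-one linear learners with
majority-vote decoding, the usual realisation of an error-correcting
output-code model) is trained and tested with leave-one-run-out
cross-validation, and the mean test accuracy is stored at (label, frame).

Two decoding schemes exist:

* ``"task"`` — task vs control (chance 0.5).  Conditions 1-4 collapse into
  one class; because they outnumber control 4:1, each load condition is
  randomly downsampled to a quarter of the control count before training.
* ``"load"`` — memory load 1-4 (chance 0.25).  Control trials are excluded
  and no downsampling is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.svm import SVC

__all__ = [
    "TrialTable",
    "build_searchlights",
    "extract_frame_features",
    "balance_instances",
    "train_classify_cv",
    "searchlight_decode_map",
    "accuracy_maps_to_tsv",
    "N_FRAMES",
    "CHANCE",
]

N_FRAMES = 21  # stimulus onset through end of the delay period, 1-s frames
CHANCE = {"task": 0.5, "load": 0.25}


@dataclass(frozen=True)
class TrialTable:
    """Trial metadata: onset frame index, condition 0-4 (0 = control), run id.

    Onsets are frame indices within each run's own time axis; every trial's
    21-frame analysis window (plus the 1-frame pre-onset baseline) must fit
    inside its run.
    """

    onset: np.ndarray
    condition: np.ndarray
    run: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.onset, dtype=np.int64)
        c = np.asarray(self.condition, dtype=np.int64)
        r = np.asarray(self.run, dtype=np.int64)
        if not (o.size == c.size == r.size) or o.size == 0:
            raise ValueError("onset/condition/run must be equal-length and non-empty")
        if c.min() < 0 or c.max() > 4:
            raise ValueError("conditions must lie in 0..4")
        if o.min() < 1:
            raise ValueError("onsets must leave one pre-onset baseline frame")
        object.__setattr__(self, "onset", o)
        object.__setattr__(self, "condition", c)
        object.__setattr__(self, "run", r)

    @property
    def n_trials(self) -> int:
        return self.onset.size

    @property
    def runs(self) -> np.ndarray:
        return np.unique(self.run)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"onset": self.onset, "condition": self.condition, "run": self.run})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialTable":
        return cls(df["onset"].to_numpy(), df["condition"].to_numpy(), df["run"].to_numpy())


def build_searchlights(centers: np.ndarray, radius: float = 10.0) -> list[np.ndarray]:
    """Per-label member lists: labels whose center is strictly within ``radius``.

    The central label itself (distance 0) is always a member.  Membership is
    symmetric because a single radius is used.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = np.asarray(centers, float)
    tree = cKDTree(centers)
    out = []
    for i, ball in enumerate(tree.query_ball_point(centers, radius)):
        ball = np.asarray(ball, dtype=np.int64)
        d = np.linalg.norm(centers[ball] - centers[i], axis=1)
        out.append(np.sort(ball[d < radius]))  # query_ball_point is <=; spec is strict
    return out


def extract_frame_features(series_per_run: dict[int, np.ndarray], trials: TrialTable,
                           frame_offset: int, scheme: str = "task"):
    """Single-frame instance matrix at ``frame_offset`` seconds after onset.

    Returns ``(X, y, runs)``: X is (n_instances, n_labels) BOLD at frame
    onset+offset, y the class labels (task scheme: 0 control / 1 task; load
    scheme: loads 1-4, control rows dropped), runs the per-instance run ids.
    """
    if not 0 <= frame_offset < N_FRAMES:
        raise IndexError(f"frame_offset {frame_offset} outside 0..{N_FRAMES - 1}")
    if scheme not in CHANCE:
        raise ValueError(f"scheme must be one of {sorted(CHANCE)}")
    rows, ys, rs = [], [], []
    for i in range(trials.n_trials):
        cond = trials.condition[i]
        if scheme == "load" and cond == 0:
            continue
        data = series_per_run[int(trials.run[i])]
        t = int(trials.onset[i]) + frame_offset
        if t >= data.shape[1]:
            raise IndexError(f"trial {i}: frame {t} beyond run length {data.shape[1]}")
        rows.append(data[:, t])
        ys.append(0 if (scheme == "task" and cond == 0) else (1 if scheme == "task" else cond))
        rs.append(trials.run[i])
    return np.asarray(rows, float), np.asarray(ys), np.asarray(rs)


def balance_instances(conditions: np.ndarray, control: int = 0,
                      rng: np.random.Generator | int | None = 0,
                      loads: tuple = (1, 2, 3, 4)) -> np.ndarray:
    """Indices retained to balance task vs control at 4:1 condition ratio.

    All control instances are kept; each load condition keeps
    ``floor(n_control / len(loads))`` randomly chosen instances (fractional
    quarters floored).  Deterministic for a fixed seed.  Raises, naming the
    condition, if a load cannot supply its share.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    conditions = np.asarray(conditions)
    keep = list(np.where(conditions == control)[0])
    per_load = len(keep) // len(loads)
    if per_load == 0:
        raise ValueError(f"fewer than {len(loads)} control instances; cannot balance")
    for cond in loads:
        idx = np.where(conditions == cond)[0]
        if idx.size < per_load:
            raise ValueError(f"condition {cond} has {idx.size} instances, needs {per_load}")
        keep.extend(rng.choice(idx, size=per_load, replace=False))
    return np.sort(np.asarray(keep, dtype=np.int64))


def _zscore_train_apply(train: np.ndarray, test: np.ndarray):
    """Z-score with training-fold statistics only (no test-set leakage)."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def train_classify_cv(X: np.ndarray, y: np.ndarray, runs: np.ndarray, C: float = 1.0) -> float:
    """Leave-one-run-out cross-validated multiclass accuracy.

    Each fold holds one run out for testing and trains on the rest;
    features are z-scored with training-fold statistics; the classifier is
    a linear SVM (C fixed) with one-vs-one majority-vote multiclass
    reduction.  Folds whose training set misses a class are skipped with a
    warning; returns the mean test accuracy over the remaining folds.
    """
    X, y, runs = np.asarray(X, float), np.asarray(y), np.asarray(runs)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    fold_runs = np.unique(runs)
    if fold_runs.size < 3:
        raise ValueError("need at least 3 runs for leave-one-run-out CV")
    accs = []
    for held in fold_runs:
        tr, te = runs != held, runs == held
        if np.unique(y[tr]).size < classes.size:
            warnings.warn(f"fold holding out run {held}: training set misses a class; skipped")
            continue
        Xtr, Xte = _zscore_train_apply(X[tr], X[te])
        clf = SVC(kernel="linear", C=C, decision_function_shape="ovo")
        clf.fit(Xtr, y[tr])
        accs.append(float(np.mean(clf.predict(Xte) == y[te])))
    if not accs:
        raise ValueError("all folds skipped: no fold had every class in training")
    return float(np.mean(accs))


def searchlight_decode_map(series_per_run: dict[int, np.ndarray], trials: TrialTable,
                           searchlights: list[np.ndarray], scheme: str = "task",
                           rng: np.random.Generator | int | None = 0,
                           frames: np.ndarray | None = None) -> np.ndarray:
    """Frame-by-frame searchlight accuracy map for one subject.

    Returns (n_labels, 21) accuracies (unvisited frames NaN when ``frames``
    restricts the sweep).  Under the task scheme the balancing subset is
    drawn once per subject and reused across all labels and frames so the
    map is comparable over the surface.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_labels = len(searchlights)
    frames = np.arange(N_FRAMES) if frames is None else np.asarray(frames, int)
    out = np.full((n_labels, N_FRAMES), np.nan)
    subset = balance_instances(trials.condition, rng=rng) if scheme == "task" else None
    for f in frames:
        X, y, r = extract_frame_features(series_per_run, trials, int(f), scheme=scheme)
        if subset is not None:
            X, y, r = X[subset], y[subset], r[subset]
        for lab in range(n_labels):
            out[lab, f] = train_classify_cv(X[:, searchlights[lab]], y, r)
    return out


def accuracy_maps_to_tsv(maps: np.ndarray, path) -> None:
    """Long-format TSV (subject, label, frame, accuracy) for (S, L, F) maps."""
    S, L, F = maps.shape
    idx = np.indices((S, L, F)).reshape(3, -1)
    pd.DataFrame({"subject": idx[0], "label": idx[1], "frame": idx[2],
                  "accuracy": maps.ravel()}).to_csv(path, sep="\t", index=False)
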