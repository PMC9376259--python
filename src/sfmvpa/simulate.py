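"""Synthetic paradigms and label-space BOLD with injectable effects.

The generator emulates the study conditions the analyses assume: 3 runs of
1-s-frame BOLD, 100 trials (20 per condition 0-4, condition 0 = control)
split 33/33/34 across runs, HRF-shaped responses, and AR(1)+white noise.
Three effects can be injected independently:

* **pattern** — each condition gets a fixed random spatial vector over a
  target region, gated by an HRF-convolved indicator of an active frame
  window and repeated identically on that condition's trials.  A linear
  decoder can exploit it; mean amplitude and coupling cannot.
* **amplitude** — an HRF-convolved 21-s boxcar scaled by slope x load over
  a region: recoverable by the GLM/amplitude load regression.
* **coupling** — a shared latent innovation added during trial windows to
  the seed region (weight 1) and to the target region with weight
  c0 + c1 x load: raises seed-target correlation monotonically in load.

Everything is deterministic under a fixed seed (sub-streams are spawned
per subject/run from the config seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .decoding import N_FRAMES, TrialTable
from .response import HRFSpec, canonical_hrf

__all__ = ["SimulationConfig", "make_paradigm", "simulate_bold", "make_null_dataset",
           "run_lengths"]


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the emulated paradigm: 100 trials (20 per condition
    incl. control) in runs of 33/33/34, 1-s frames, 32-s trial spacing
    (stimulus + 20-s delay + probe/answer), AR(1) noise with phi = 0.3.
    """

    n_labels: int = 0                     # 0 = derive from a parcellation
    n_subjects: int = 10
    trials_per_run: tuple = (33, 33, 34)
    trials_per_condition: int = 20
    n_conditions: int = 5                 # 0 = control, 1-4 = loads
    frame_period: float = 1.0
    trial_spacing: int = 32               # seconds between onsets
    first_onset: int = 2                  # leaves the pre-onset baseline frame
    baseline: float = 100.0
    ar_phi: float = 0.3
    ar_sd: float = 1.0                    # AR(1) innovation sd
    white_sd: float = 0.5
    # pattern effect (decoding); injected only when its region is non-empty
    pattern_region: tuple = ()
    pattern_sd: float = 2.5               # per-condition spatial pattern sd (a.u.)
    pattern_window: tuple = (2, 10)       # active frames [start, stop) after onset
    pattern_conditions: tuple = (0, 1, 2, 3, 4)
    # amplitude effect (response strength); slope is in measured-amplitude
    # units per unit load (the HRF envelope is mean-normalised over 21 s)
    amplitude_region: tuple = ()
    amplitude_slope: float = 0.5
    # coupling effect (connectivity): weight 1 on seed, c0 + c1*load on target
    coupling_seed_region: tuple = ()
    coupling_target_region: tuple = ()
    coupling_c0: float = 0.3
    coupling_c1: float = 0.15
    coupling_latent_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.ar_phi < 1):
            raise ValueError("ar_phi must lie in [0, 1)")
        if min(self.ar_sd, self.white_sd, self.pattern_sd, self.coupling_latent_sd) < 0:
            raise ValueError("noise/effect sds must be non-negative")
        if self.trials_per_condition * self.n_conditions != sum(self.trials_per_run):
            raise ValueError("trials per condition x conditions must equal total run trials")

    def to_dict(self) -> dict:
        return asdict(self)


def run_lengths(config: SimulationConfig) -> dict[int, int]:
    """Frames per run: every trial's 21-frame window plus baseline must fit."""
    return {run: config.first_onset + (n - 1) * config.trial_spacing + N_FRAMES + 1
            for run, n in enumerate(config.trials_per_run)}


def make_paradigm(config: SimulationConfig, rng: np.random.Generator | int | None = None) -> TrialTable:
    """Random trial table: balanced conditions permuted and split across runs.

    Onsets are evenly spaced by ``trial_spacing`` within each run, starting
    at ``first_onset``; the minimum inter-onset gap therefore equals the
    configured spacing, and each 21-frame window (plus the 1-frame
    pre-onset baseline) fits its run.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    conds = np.repeat(np.arange(config.n_conditions), config.trials_per_condition)
    if conds.size != sum(config.trials_per_run):
        raise ValueError("condition counts inconsistent with run sizes")
    conds = rng.permutation(conds)
    onsets, runs = [], []
    i = 0
    for run, n in enumerate(config.trials_per_run):
        span = config.first_onset + (n - 1) * config.trial_spacing + N_FRAMES + 1
        if span > run_lengths(config)[run]:
            raise ValueError(f"run {run} too short for {n} trials")
        onsets.extend(config.first_onset + np.arange(n) * config.trial_spacing)
        runs.extend([run] * n)
        i += n
    return TrialTable(np.asarray(onsets), conds, np.asarray(runs))


def _ar1(rng: np.random.Generator, shape: tuple, phi: float, sd: float) -> np.ndarray:
    """Row-wise AR(1): x_t = phi x_{t-1} + e_t, e ~ N(0, sd^2), stationary start."""
    n_series, n_t = shape
    e = rng.normal(0.0, sd, size=shape)
    x = np.empty(shape)
    x[:, 0] = e[:, 0] / np.sqrt(1 - phi**2) if phi > 0 else e[:, 0]
    for t in range(1, n_t):
        x[:, t] = phi * x[:, t - 1] + e[:, t]
    return x


def simulate_bold(config: SimulationConfig, trials: TrialTable,
                  rng: np.random.Generator | int | None = None) -> dict[int, np.ndarray]:
    """Label-space BOLD for one subject: run id -> (n_labels, frames).

    baseline + AR(1) + white noise + the configured pattern / amplitude /
    coupling effects (see module docstring).  Deterministic under a fixed
    generator.
    """
    if config.n_labels < 1:
        raise ValueError("config.n_labels must be set (>= 1)")
    for region in (config.pattern_region, config.amplitude_region,
                   config.coupling_seed_region, config.coupling_target_region):
        if len(region) and (min(region) < 0 or max(region) >= config.n_labels):
            raise ValueError(f"effect region {region} outside 0..{config.n_labels - 1}")
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    hrf = canonical_hrf(HRFSpec(frame_period=config.frame_period))
    lengths = run_lengths(config)

    # fixed per-condition spatial patterns (drawn once per subject)
    patterns = {}
    if len(config.pattern_region) and config.pattern_sd > 0:
        for cond in config.pattern_conditions:
            patterns[cond] = rng.normal(0.0, config.pattern_sd, size=len(config.pattern_region))
    # HRF-gated envelope of the pattern's active window, within a 21-s trial
    gate = np.zeros(N_FRAMES)
    w0, w1 = config.pattern_window
    gate[w0:w1] = 1.0
    pattern_env = np.convolve(gate, hrf)[:N_FRAMES]
    if pattern_env.max() > 0:
        pattern_env = pattern_env / pattern_env.max()
    # 21-s boxcar envelope, mean-normalised so amplitude_slope is in the
    # units curve_amplitude measures (mean over the 21 window samples)
    box21 = np.convolve(np.ones(N_FRAMES), hrf)[:N_FRAMES]
    box21 = box21 / box21.mean()

    out = {}
    for run, n_frames in lengths.items():
        data = np.full((config.n_labels, n_frames), config.baseline)
        data += _ar1(rng, (config.n_labels, n_frames), config.ar_phi, config.ar_sd)
        if config.white_sd > 0:
            data += rng.normal(0.0, config.white_sd, size=data.shape)
        sel = np.where(trials.run == run)[0]
        for i in sel:
            cond, onset = int(trials.condition[i]), int(trials.onset[i])
            sl = slice(onset, onset + N_FRAMES)
            width = data[:, sl].shape[1]
            if cond in patterns:
                region = np.asarray(config.pattern_region)
                data[region, sl] += np.outer(patterns[cond], pattern_env[:width])
            if len(config.amplitude_region) and config.amplitude_slope != 0 and cond > 0:
                region = np.asarray(config.amplitude_region)
                data[region, sl] += config.amplitude_slope * cond * box21[:width]
            if len(config.coupling_seed_region) and cond > 0 and \
                    (config.coupling_c0 != 0 or config.coupling_c1 != 0):
                latent = rng.normal(0.0, config.coupling_latent_sd, size=width)
                w = config.coupling_c0 + config.coupling_c1 * cond
                data[np.asarray(config.coupling_seed_region), sl] += latent
                if len(config.coupling_target_region):
                    data[np.asarray(config.coupling_target_region), sl] += w * latent
        out[run] = data
    return out


def make_null_dataset(config: SimulationConfig, rng: np.random.Generator | int | None = None):
    """Full subject set with all effects zeroed: (trials, [subject -> run -> series]).

    The calibration input for every false-positive-rate check.
    """
    import dataclasses

    null_cfg = dataclasses.replace(config, pattern_sd=0.0, amplitude_slope=0.0,
                                   coupling_c0=0.0, coupling_c1=0.0)
    rng = np.random.default_rng(config.seed if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng
    trials = make_paradigm(null_cfg, rng)
    subjects = [simulate_bold(null_cfg, trials, rng) for _ in range(config.n_subjects)]
    return trials, subjects
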