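"""HRF shape, design construction, GLM fits, response curves, amplitude regression."""

import numpy as np
import pytest

import sfmvpa as m
from sfmvpa.decoding import TrialTable
from sfmvpa.response import HRFSpec, adjacent_contrasts, build_design, fit_glm
from sfmvpa.simulate import run_lengths


class TestHrf:
    def test_zero_at_onset_and_unit_peak(self):
        h = m.canonical_hrf()
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0)

    def test_peak_between_4_and_7_seconds(self):
        # dense sampling localises the argmax of the double gamma
        spec = HRFSpec(frame_period=0.01)
        h = m.canonical_hrf(spec)
        t_peak = np.argmax(h) * 0.01
        assert 4.0 <= t_peak <= 7.0

    def test_matches_spm_shape(self):
        """Same parameterisation as the classic double gamma (independent oracle).

        The reference offsets its gamma lobes by one sample (loc = dt) and
        samples on a linspace grid, so the comparison aligns the peaks and
        checks the waveform correlation at fine resolution.
        """
        from nilearn.glm.first_level import spm_hrf

        dt = 0.05
        ours = m.canonical_hrf(HRFSpec(frame_period=dt), length=32.0)
        ref = spm_hrf(dt, oversampling=1, time_length=32.0)
        ref = ref / ref.max()
        peak_ours, peak_ref = np.argmax(ours) * dt, np.argmax(ref) * dt
        assert abs(peak_ours - peak_ref) <= 0.2
        shift = np.argmax(ref) - np.argmax(ours)
        aligned = ref[shift: shift + ours.size]
        n = min(ours.size, aligned.size)
        r = np.corrcoef(ours[:n], aligned[:n])[0, 1]
        assert r > 0.999

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            HRFSpec(peak_delay=-1)
        with pytest.raises(ValueError):
            m.canonical_hrf(length=10.0)


@pytest.fixture(scope="module")
def toy_trials():
    # two runs only used for design construction; CV not involved here
    return TrialTable(onset=np.array([5, 60, 5]), condition=np.array([1, 1, 2]),
                      run=np.array([0, 0, 1]))


class TestDesign:
    def test_absent_condition_gives_zero_regressor(self, toy_trials):
        designs = build_design(toy_trials, {0: 120, 1: 60})
        assert np.all(designs[0][:, 3] == 0)  # condition 3 never occurs
        assert np.all(designs[0][:, -1] == 1)  # intercept

    def test_single_trial_equals_shifted_convolution(self, toy_trials):
        hrf = m.canonical_hrf()
        designs = build_design(toy_trials, {0: 120, 1: 60}, hrf=hrf)
        box = np.zeros(60)
        box[5:26] = 1.0
        expected = np.convolve(box, hrf)[:60]
        assert np.allclose(designs[1][:, 2], expected)

    def test_superposition_of_two_trials(self, toy_trials):
        hrf = m.canonical_hrf()
        designs = build_design(toy_trials, {0: 120, 1: 60}, hrf=hrf)
        one = np.zeros(120); one[5:26] = 1
        two = np.zeros(120); two[60:81] = 1
        expected = np.convolve(one + two, hrf)[:120]
        assert np.allclose(designs[0][:, 1], expected)


class TestGlm:
    def test_recovers_exact_scaling(self, toy_trials):
        designs = build_design(toy_trials, {0: 120, 1: 60}, conditions=(1, 2))
        series = {r: np.outer(np.ones(3), 2.0 * d[:, 0]) for r, d in designs.items()}
        betas = fit_glm(series, designs)
        assert np.allclose(betas[:, 0], 2.0, atol=1e-10)

    def test_orthogonal_series_zero_betas(self, toy_trials):
        designs = build_design(toy_trials, {0: 120, 1: 60}, conditions=(1, 2))
        series = {r: np.zeros((2, d.shape[0])) for r, d in designs.items()}
        betas = fit_glm(series, designs)
        assert np.allclose(betas, 0.0)

    def test_matches_normal_equations(self):
        # 3-frame toy system: beta_hat = (X'X)^-1 X'y, computed by hand
        X = np.array([[1.0, 1], [2.0, 1], [4.0, 1]])
        y = np.array([[2.0], [3.0], [6.0]])
        designs = {0: X}
        series = {0: y.T}
        betas = fit_glm(series, designs)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert betas[0, 0] == pytest.approx(ref[0, 0])

    def test_rank_deficiency_named(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)
        X[:, 1] = 2 * np.arange(10)  # collinear with column 0
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="collinear"):
            fit_glm({0: np.zeros((1, 10))}, {0: X})


class TestAdjacentContrasts:
    def _line_adj(self, n):
        adj = np.zeros((n, n), bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        return adj

    def test_identical_betas_all_zero_t(self):
        betas = np.tile(np.arange(12.0), (6, 5, 1))  # same across conditions
        res = adjacent_contrasts(betas, self._line_adj(12), n_permutations=20)
        for stat, cs in res:
            assert np.all(stat.t == 0) and len(cs) == 0

    def test_noise_free_load_differences_degenerate(self):
        loads = np.arange(5.0)
        betas = np.tile(loads[None, :, None], (4, 1, 8))  # beta = load exactly
        res = adjacent_contrasts(betas, self._line_adj(8), n_permutations=20)
        for stat, _ in res:
            assert np.all(stat.degenerate)

    def test_null_cluster_fpr_controlled(self):
        """Gaussian-null betas: family-wise cluster rate <= 0.05 + MC error."""
        rng = np.random.default_rng(12)
        adj = self._line_adj(30)
        fp = 0
        reps = 60
        for i in range(reps):
            betas = rng.normal(size=(8, 2, 30))  # one contrast (2 conditions)
            res = adjacent_contrasts(betas, adj, n_permutations=100, rng=i)
            fp += len(res[0][1]) > 0
        assert fp / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


@pytest.fixture(scope="module")
def sim_setup():
    sim = m.SimulationConfig(n_labels=6, seed=31)
    trials = m.make_paradigm(sim, np.random.default_rng(31))
    return sim, trials


class TestResponseCurves:
    def test_condition_equals_control_gives_zero(self, sim_setup):
        sim, trials = sim_setup
        series = {r: np.full((6, n), 7.0) for r, n in run_lengths(sim).items()}
        curves = m.response_curves(series, trials, condition=2)
        assert curves.shape == (6, 21) and np.allclose(curves, 0.0)

    def test_constant_offset_from_onset(self, sim_setup):
        sim, trials = sim_setup
        series = {r: np.zeros((6, n)) for r, n in run_lengths(sim).items()}
        # condition 1 trials add a constant 3 from onset onwards
        for i in np.where(trials.condition == 1)[0]:
            run, onset = int(trials.run[i]), int(trials.onset[i])
            series[run][:, onset: onset + 21] += 3.0
        curves = m.response_curves(series, trials, condition=1)
        assert np.allclose(curves, 3.0)

    def test_matches_literal_reimplementation(self, sim_setup):
        sim, trials = sim_setup
        rng = np.random.default_rng(5)
        series = {r: rng.normal(size=(6, n)) for r, n in run_lengths(sim).items()}
        curves = m.response_curves(series, trials, condition=3)

        def literal(cond):
            wins = [series[int(trials.run[i])][:, int(trials.onset[i]) - 1: int(trials.onset[i]) + 21]
                    for i in np.where(trials.condition == cond)[0]]
            return np.mean(wins, axis=0)

        diff = literal(3) - literal(0)
        expected = (diff - diff[:, :1])[:, 1:]
        assert np.allclose(curves, expected)

    def test_baseline_invariance_to_constant_shift(self, sim_setup):
        sim, trials = sim_setup
        rng = np.random.default_rng(6)
        series = {r: rng.normal(size=(6, n)) for r, n in run_lengths(sim).items()}
        shifted = {r: s + 123.4 for r, s in series.items()}
        assert np.allclose(m.response_curves(series, trials, 1),
                           m.response_curves(shifted, trials, 1))


class TestAmplitude:
    def test_trivial_values(self):
        assert m.curve_amplitude(np.zeros(21)) == 0.0
        assert m.curve_amplitude(np.full(21, 3.0)) == 3.0
        assert m.curve_amplitude(np.arange(21.0)) == 10.0

    def test_constant_amplitudes_empty_map(self):
        adj = np.zeros((15, 15), bool)
        stat, cs = m.amplitude_load_map(np.full((5, 4, 15), 1.0), adj)
        assert len(cs) == 0 and np.all(stat.p == 1.0)

    def test_null_amplitudes_rarely_cluster(self):
        rng = np.random.default_rng(13)
        n = 102
        adj = np.zeros((n, n), bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        empty = 0
        reps = 100
        for _ in range(reps):
            amps = rng.normal(size=(10, 4, n))
            _, cs = m.amplitude_load_map(amps, adj)
            empty += len(cs) == 0
        assert empty >= 0.95 * reps
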