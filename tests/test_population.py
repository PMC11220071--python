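"""PSTHs, stitching, population geometry, signal variance, variability."""

import numpy as np
import pytest

from trialglm.population import (
    dimensionality_estimate,
    event_psth,
    pca_trajectories,
    population_correlation_matrix,
    signal_variance_decomposition,
    spikecount_cv,
    stitch_trial_psth,
)


class TestEventPSTH:
    def test_single_locked_spike_integrates_to_one(self):
        """One spike exactly at each event: the smoothed PSTH integrates to
        one spike per trial."""
        events = np.array([1.0, 2.0, 3.0, 4.0])
        spikes = [np.array([t]) for t in events]
        centres, rate = event_psth(spikes, events, window=(-0.5, 0.5))
        assert np.trapezoid(rate, centres) == pytest.approx(1.0, rel=1e-3)
        assert centres[np.argmax(rate)] == pytest.approx(0.0, abs=0.011)

    def test_homogeneous_poisson_flat(self, rng):
        """A homogeneous Poisson train has a flat PSTH within 3 SE."""
        r = 30.0
        n_trials = 400
        spikes = [np.sort(rng.uniform(0, 2.0, rng.poisson(2.0 * r))) for _ in range(n_trials)]
        events = np.full(n_trials, 1.0)
        centres, rate = event_psth(spikes, events, window=(-0.8, 0.8))
        # smoothing with sigma=30 ms leaves ~6 effective independent bins
        se = np.sqrt(r / (n_trials * 2 * np.sqrt(np.pi) * 0.03))
        assert np.abs(rate - r).max() < 4 * se

    def test_duplicating_trials_leaves_average_unchanged(self):
        events = np.array([1.0, 2.0])
        spikes = [np.array([1.05]), np.array([2.05])]
        _, a = event_psth(spikes, events, window=(-0.2, 0.2))
        _, b = event_psth(spikes * 3, np.tile(events, 3), window=(-0.2, 0.2))
        assert np.allclose(a, b)

    def test_empty_train_zero_psth(self):
        centres, rate = event_psth([np.empty(0)], np.array([1.0]), window=(-0.2, 0.2))
        assert np.allclose(rate, 0.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            event_psth([np.array([1.0])], np.array([np.nan]), window=(-0.2, 0.2))


class TestStitching:
    def test_expert_alignment_sequence_accepted(self):
        """The C, O, L, R event PSTHs aligned at -0.43, 0, 1.38, 1.96 s
        stitch into one continuous trial PSTH."""
        centres = np.arange(-1.0, 1.0, 0.01)
        segments = [
            (t0, centres, np.full(centres.size, float(i)))
            for i, t0 in enumerate((-0.43, 0.0, 1.38, 1.96))
        ]
        grid, rate = stitch_trial_psth(segments)
        assert grid[0] == pytest.approx(-1.43, abs=1e-9)
        assert grid[-1] == pytest.approx(2.95, abs=1e-9)
        assert np.isfinite(rate).all()

    def test_identical_overlap_returns_segment(self):
        centres = np.arange(0, 1.0, 0.01)
        seg = (0.0, centres, np.sin(centres))
        seg2 = (0.5, centres, np.sin(centres + 0.5))
        grid, rate = stitch_trial_psth([seg, seg2])
        assert np.allclose(rate, np.sin(grid), atol=1e-9)

    def test_overlap_averages_constant_segments(self):
        centres = np.arange(0, 1.0, 0.01)
        a = (0.0, centres, np.full(centres.size, 2.0))
        b = (0.5, centres, np.full(centres.size, 6.0))
        grid, rate = stitch_trial_psth([a, b])
        overlap = (grid >= 0.5) & (grid <= 0.99)
        assert np.allclose(rate[overlap], 4.0)
        assert np.allclose(rate[grid < 0.5], 2.0)

    def test_gap_between_segments_is_error(self):
        centres = np.arange(0, 0.3, 0.01)
        a = (0.0, centres, np.zeros(centres.size))
        b = (1.0, centres, np.zeros(centres.size))
        with pytest.raises(ValueError, match="gap"):
            stitch_trial_psth([a, b])

    def test_idempotent_on_continuous_series(self):
        centres = np.arange(0, 1.0, 0.01)
        series = np.cos(centres)
        grid, rate = stitch_trial_psth([(0.0, centres, series)])
        assert np.allclose(rate, series)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self, rng):
        vectors = rng.normal(size=(6, 40))
        corr = population_correlation_matrix(vectors)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_identical_patterns_correlate_perfectly(self, rng):
        v = rng.normal(size=40)
        corr = population_correlation_matrix(np.vstack([v, v + 0.0]))
        assert corr[0, 1] == pytest.approx(1.0)

    def test_orthogonal_patterns_near_zero(self, rng):
        """Centred orthogonal patterns at N=200 neurons correlate within
        +/- 0.05 of zero."""
        n = 200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        b -= (a - a.mean()) @ (b - b.mean()) / ((a - a.mean()) @ (a - a.mean())) * (
            a - a.mean()
        )
        corr = population_correlation_matrix(np.vstack([a, b]))
        assert abs(corr[0, 1]) < 0.05

    def test_zero_variance_vector_flagged_nan(self, rng):
        vectors = np.vstack([np.full(30, 2.0), rng.normal(size=30)])
        corr = population_correlation_matrix(vectors)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[0, 0])
        assert corr[1, 1] == pytest.approx(1.0)


class TestPCA:
    def test_explained_variance_non_increasing(self, rng):
        xbar = rng.normal(size=(12, 2, 2, 30))
        res = pca_trajectories(xbar)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)

    def test_full_reconstruction_identity(self, rng):
        xbar = rng.normal(size=(5, 2, 2, 10))
        flat = xbar.reshape(5, -1)
        flat -= flat.mean(axis=1, keepdims=True)
        U, S, Vt = np.linalg.svd(flat, full_matrices=False)
        assert np.allclose(U @ np.diag(S) @ Vt, flat, atol=1e-10)

    def test_rank_one_data_single_component(self, rng):
        load = rng.normal(size=5)
        time_course = rng.normal(size=40)
        xbar = np.outer(load, time_course).reshape(5, 2, 2, 10)
        res = pca_trajectories(xbar)
        assert res.singular_values[1] < 1e-10 * res.singular_values[0]


class TestSignalVariance:
    @staticmethod
    def _brute_force(X):
        """Direct evaluation of the decomposition formulas on a small
        array (independent of the vectorized implementation)."""
        N, C, O, T, K = X.shape
        xbar = X.mean(axis=-1)
        total = 0.0
        for n in range(N):
            m = xbar[n].mean()
            for c in range(C):
                for o in range(O):
                    for t in range(T):
                        total += (xbar[n, c, o, t] - m) ** 2
        theta = 0.0
        for n in range(N):
            cn = 0.0
            for c in range(C):
                for o in range(O):
                    for t in range(T):
                        for k in range(K):
                            cn += (X[n, c, o, t, k] - xbar[n, c, o, t]) ** 2 / K
            cn /= C * O * T
            theta += cn / K
        theta *= C * O * T
        return total, theta

    def test_matches_brute_force_on_toy_array(self, rng):
        X = rng.normal(size=(3, 2, 2, 4, 5))
        total, theta, sigvar, fraction = signal_variance_decomposition(X)
        bf_total, bf_theta = self._brute_force(X)
        assert total == pytest.approx(bf_total, abs=1e-10)
        assert theta == pytest.approx(bf_theta, abs=1e-10)
        assert sigvar == pytest.approx(bf_total - bf_theta, abs=1e-10)

    def test_zero_noise_gives_full_signal_fraction(self, rng):
        xbar = rng.normal(size=(4, 2, 2, 6))
        X = np.repeat(xbar[..., None], 5, axis=-1)
        total, theta, sigvar, fraction = signal_variance_decomposition(X)
        assert theta == pytest.approx(0.0, abs=1e-12)
        assert fraction == pytest.approx(100.0)

    def test_pure_noise_fraction_near_zero(self, rng):
        """All conditions share one mean with i.i.d. noise: the fraction is
        near zero (the 1/K normalisation leaves a ~1/K=5% bias)."""
        N, K = 100, 20
        mean = rng.uniform(2, 6, size=(N, 1, 1, 1, 1))
        X = rng.poisson(mean, size=(N, 2, 2, 10, K)).astype(float)
        *_, fraction = signal_variance_decomposition(X)
        assert abs(fraction) < 10.0

    def test_signal_never_exceeds_total_and_theta_nonnegative(self, rng):
        X = rng.normal(size=(4, 2, 2, 5, 6))
        total, theta, sigvar, _ = signal_variance_decomposition(X)
        assert theta >= 0
        assert sigvar <= total

    def test_single_trial_condition_rejected(self, rng):
        X = rng.normal(size=(2, 2, 2, 4, 3))
        X[1, 0, 1, :, 1:] = np.nan
        with pytest.raises(ValueError, match="fewer than 2 trials"):
            signal_variance_decomposition(X)


class TestDimensionality:
    def test_rank_one_signal_needs_one_component(self, rng):
        xbar = np.outer(rng.normal(size=6), rng.normal(size=40)).reshape(6, 2, 2, 10)
        assert dimensionality_estimate(xbar, 90.0) == 1

    def test_equal_eigenvalues_split_proportionally(self):
        """10 orthonormal rows (equal variance shares): 50% needs 5."""
        xbar = np.eye(10)
        flat = xbar - xbar.mean(axis=1, keepdims=True)
        assert dimensionality_estimate(flat.reshape(10, 1, 1, 10), 50.0) == 5

    def test_matches_cumulative_eigenvalue_scan(self, rng):
        xbar = rng.normal(size=(8, 2, 2, 12))
        flat = xbar.reshape(8, -1)
        flat = flat - flat.mean(axis=1, keepdims=True)
        var = np.linalg.svd(flat, compute_uv=False) ** 2
        cum = 100 * np.cumsum(var) / var.sum()
        for frac in (30.0, 60.0, 95.0):
            expected = int(np.argmax(cum >= frac - 1e-9)) + 1
            assert dimensionality_estimate(xbar, frac) == expected

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(ValueError, match="signal_fraction"):
            dimensionality_estimate(rng.normal(size=(3, 1, 1, 5)), 0.0)


class TestSpikecountCV:
    def test_constant_counts_zero_cv(self):
        counts = np.full((4, 20), 7.0)
        assert np.allclose(spikecount_cv(counts), 0.0)

    def test_poisson_cv_matches_moments(self, rng):
        """Poisson(mu) counts have CV ~ 1/sqrt(mu) within 3 SE at K=1000."""
        mu = 16.0
        counts = rng.poisson(mu, size=(50, 1000)).astype(float)
        cv = spikecount_cv(counts)
        se = 1 / np.sqrt(mu) / np.sqrt(2 * 1000)
        assert abs(cv.mean() - 1 / np.sqrt(mu)) < 3 * se

    def test_scale_invariance(self, rng):
        counts = rng.poisson(5.0, size=(6, 30)).astype(float) + 1
        assert np.allclose(spikecount_cv(counts), spikecount_cv(3.7 * counts))

    def test_zero_mean_flagged_nan(self):
        counts = np.zeros((2, 10))
        assert np.isnan(spikecount_cv(counts)).all()
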