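"""Poisson GLM fitting, evidence-based regularisation, CV, model selection."""

import numpy as np
import pytest

from trialglm.design import assemble_design_matrix
from trialglm.glm import (
    crossvalidated_performance,
    fit_map,
    forward_model_selection,
    make_trial_folds,
    poisson_log_likelihood,
    predict_rate,
    select_ridge_by_evidence,
    signed_rank_improvement,
    validate_exponential_nonlinearity,
)
from trialglm.session import (
    SessionConfig,
    make_ground_truth_kernels,
    simulate_spikes,
    simulate_trial_events,
)
from trialglm.validation import kernel_correlation


class TestPoissonLogLikelihood:
    def test_silent_bins(self):
        """No spikes over 10 bins at lambda*dt = 0.1: only -sum(lambda dt)
        survives, giving exactly -1."""
        ll = poisson_log_likelihood(np.zeros(10), np.full(10, 10.0), 0.01)
        assert ll == pytest.approx(-1.0)

    def test_single_spike_unit_mean(self):
        ll = poisson_log_likelihood(np.array([1]), np.array([100.0]), 0.01)
        assert ll == pytest.approx(-1.0)  # 1*log(1) - 1

    def test_constant_term(self):
        ll = poisson_log_likelihood(
            np.array([2]), np.array([100.0]), 0.01, include_constant=True
        )
        assert ll == pytest.approx(-1.0 - np.log(2.0))

    def test_zero_rate_with_spikes_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            poisson_log_likelihood(np.array([1]), np.array([0.0]), 0.01)


@pytest.fixture(scope="module")
def driven_neuron(cv_design):
    model = make_ground_truth_kernels(
        ("Inhal", "Odour"), cv_design.bases, seed=5, amplitude_range=(0.8, 1.2)
    )
    train = simulate_spikes(model, cv_design, seed=6)
    return model, train


class TestFitMAP:
    def test_unique_optimum_from_different_starts(self, cv_design, driven_neuron):
        """The penalized likelihood is concave: two starting points reach
        the same weights."""
        _, train = driven_neuron
        a = fit_map(cv_design, train.counts, 1.0, variables=("Inhal",))
        w0 = np.full(a.w.size, 0.3)
        b = fit_map(cv_design, train.counts, 1.0, variables=("Inhal",), w0=w0)
        assert np.abs(a.w - b.w).max() < 1e-6

    def test_huge_ridge_recovers_mean_rate(self, cv_design, driven_neuron):
        """xi -> 1e8 with unpenalized bias: kernel weights vanish and the
        predicted rate approaches the empirical mean rate."""
        _, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1e8, variables=("Inhal", "Odour"))
        kernel_w = np.concatenate(
            [fit.w[fit.col_slices[v]] for v in ("Inhal", "Odour")]
        )
        assert np.abs(kernel_w).max() < 1e-3
        rate = predict_rate(fit, cv_design)
        empirical = train.counts.mean() / cv_design.dt
        assert rate.mean() == pytest.approx(empirical, rel=1e-3)

    def test_objective_monotone_nondecreasing(self, cv_design, driven_neuron):
        _, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal", "Odour"))
        assert np.all(np.diff(fit.objective_path) >= -1e-9)

    def test_recovery_on_simulated_data(self, driven_neuron, cv_design):
        """Fitting the generating variable set recovers the kernels with
        correlation above 0.9."""
        model, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal", "Odour"))
        assert kernel_correlation(model, fit, cv_design.bases) > 0.9

    def test_negative_ridge_rejected(self, cv_design, driven_neuron):
        with pytest.raises(ValueError, match="xi"):
            fit_map(cv_design, driven_neuron[1].counts, -1.0)


class TestPredictRate:
    def test_bias_only_constant(self, cv_design):
        fit = fit_map(cv_design, np.zeros(cv_design.n_rows, int) + 1, 1.0, variables=())
        rate = predict_rate(fit, cv_design)
        assert np.allclose(rate, rate[0])

    def test_doubling_weights_squares_gain(self, cv_design, driven_neuron):
        _, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal",))
        doubled = fit.with_weights(fit.w.copy())
        sl = fit.col_slices["Inhal"]
        doubled.w[sl] = 2 * fit.w[sl]
        gain = predict_rate(doubled, cv_design) / predict_rate(fit, cv_design)
        base_gain = np.exp(cv_design.blocks["Inhal"] @ fit.w[sl])
        assert np.allclose(gain, base_gain, rtol=1e-10)

    def test_variable_mismatch_rejected(self, cv_design, small_design, driven_neuron):
        _, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal",))
        bad = fit.with_weights(np.append(fit.w, 0.0))
        with pytest.raises(ValueError, match="columns"):
            predict_rate(bad, cv_design)


class TestEvidence:
    def test_single_element_grid_returned(self, cv_design, driven_neuron):
        _, train = driven_neuron
        sel = select_ridge_by_evidence(
            cv_design, train.counts, np.array([3.0]), variables=("Inhal",)
        )
        assert sel.xi == 3.0

    def test_evidence_finite_on_grid(self, cv_design, driven_neuron):
        _, train = driven_neuron
        sel = select_ridge_by_evidence(
            cv_design, train.counts, np.logspace(-2, 4, 7), variables=("Inhal", "Odour")
        )
        assert np.isfinite(sel.log_evidence).all()

    def test_stronger_ridge_for_structureless_neuron(self, cv_design):
        """A constant-rate neuron supports no kernel structure, so the
        evidence prefers a larger ridge than for a strongly driven one."""
        null_model = make_ground_truth_kernels((), cv_design.bases, seed=1)
        driven = make_ground_truth_kernels(
            ("Inhal",), cv_design.bases, seed=2, amplitude_range=(1.0, 1.2)
        )
        counts_null = simulate_spikes(null_model, cv_design, seed=3).counts
        counts_driven = simulate_spikes(driven, cv_design, seed=4).counts
        grid = np.logspace(-2, 4, 13)
        xi_null = select_ridge_by_evidence(
            cv_design, counts_null, grid, variables=("Inhal",)
        ).xi
        xi_driven = select_ridge_by_evidence(
            cv_design, counts_driven, grid, variables=("Inhal",)
        ).xi
        assert xi_null > xi_driven


class TestCrossValidation:
    def test_fold_assignment_deterministic_and_partition(self):
        a = make_trial_folds(40, 10, seed=3)
        b = make_trial_folds(40, 10, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert np.array_equal(np.sort(np.concatenate(a)), np.arange(40))

    def test_true_model_beats_bias_in_most_folds(self, cv_design, driven_neuron):
        _, train = driven_neuron
        folds = make_trial_folds(40, 10, seed=0)
        cv_true = crossvalidated_performance(
            cv_design, train.counts, 1.0, variables=("Inhal", "Odour"), folds=folds
        )
        cv_bias = crossvalidated_performance(
            cv_design, train.counts, 1.0, variables=(), folds=folds
        )
        assert (cv_true.fold_ll > cv_bias.fold_ll).sum() >= 9
        assert signed_rank_improvement(cv_true.fold_ll, cv_bias.fold_ll) < 0.05

    def test_trial_shuffled_counts_destroy_advantage(self, cv_bundle, cv_design, rng):
        """Rotating counts across trials breaks the event-spike alignment;
        the true model's advantage disappears."""
        model = make_ground_truth_kernels(
            ("Inhal", "Odour"), cv_design.bases, seed=5, amplitude_range=(0.8, 1.2)
        )
        counts = simulate_spikes(model, cv_design, seed=6).counts.copy()
        slices = cv_bundle.trial_slices()
        order = rng.permutation(len(slices))
        shuffled = np.concatenate(
            [
                np.resize(counts[slices[j]], sl.stop - sl.start)
                for j, sl in zip(order, slices)
            ]
        )
        folds = make_trial_folds(40, 10, seed=0)
        cv_true = crossvalidated_performance(
            cv_design, shuffled, 1.0, variables=("Inhal", "Odour"), folds=folds
        )
        cv_bias = crossvalidated_performance(
            cv_design, shuffled, 1.0, variables=(), folds=folds
        )
        assert signed_rank_improvement(cv_true.fold_ll, cv_bias.fold_ll) > 0.05


class TestForwardSelection:
    def test_single_variable_neuron_recovered(self, cv_design):
        model = make_ground_truth_kernels(
            ("Inhal",), cv_design.bases, seed=8, amplitude_range=(0.9, 1.2)
        )
        counts = simulate_spikes(model, cv_design, seed=9).counts
        result = forward_model_selection(cv_design, counts, xi=1.0, seed=0)
        assert result.variables == ("Inhal",)

    def test_constant_neuron_selects_nothing(self, cv_design):
        model = make_ground_truth_kernels((), cv_design.bases, seed=10)
        counts = simulate_spikes(model, cv_design, seed=11).counts
        result = forward_model_selection(cv_design, counts, xi=1.0, seed=0)
        assert result.variables == ()

    def test_two_variable_neuron_selects_both(self, cv_design):
        model = make_ground_truth_kernels(
            ("Inhal", "Speed"), cv_design.bases, seed=12, amplitude_range=(0.9, 1.2)
        )
        counts = simulate_spikes(model, cv_design, seed=13).counts
        result = forward_model_selection(cv_design, counts, xi=1.0, seed=0)
        assert set(result.variables) == {"Inhal", "Speed"}


class TestExponentialNonlinearity:
    def test_self_consistency_on_exponential_data(self, cv_design, driven_neuron):
        """Data generated with the exponential link: observed rates match
        exp(g) within the 95% Poisson band in at least 90% of well-sampled
        bins."""
        model, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal", "Odour"))
        truth = fit.with_weights(np.zeros_like(fit.w))
        for name in ("Inhal", "O_R", "O_U"):
            truth.w[fit.kernel_slices[name]] = model.kernels[name]
        truth.w[fit.col_slices["Bias"]] = model.bias
        table = validate_exponential_nonlinearity(truth, cv_design, train.counts, 15)
        good = table[table.n_bins_occupied >= 100]
        assert good.within_ci.mean() >= 0.9

    def test_constant_rate_single_bin(self, cv_design):
        counts = np.ones(cv_design.n_rows, dtype=int)
        fit = fit_map(cv_design, counts, 1.0, variables=())
        table = validate_exponential_nonlinearity(fit, cv_design, counts, 10)
        assert (table.n_bins_occupied > 0).sum() == 1

    def test_linear_link_data_deviates_at_extremes(self, cv_design):
        """Counts generated with a *linear* rate map produce systematic
        misses of the exponential prediction in the extreme kernel-output
        bins."""
        model = make_ground_truth_kernels(
            ("Inhal",), cv_design.bases, seed=20, amplitude_range=(1.2, 1.4)
        )
        g = cv_design.blocks["Inhal"] @ model.kernels["Inhal"] + model.bias
        linear_rate = np.maximum(0.5, 8.0 * (1.0 + 1.5 * (g - g.mean())))
        counts = np.random.default_rng(21).poisson(linear_rate * cv_design.dt)
        fit = fit_map(cv_design, counts, 1.0, variables=("Inhal",))
        table = validate_exponential_nonlinearity(fit, cv_design, counts, 12)
        extremes = table.iloc[[0, -1]]
        assert not extremes.within_ci.all()

    def test_too_few_bins_rejected(self, cv_design, driven_neuron):
        _, train = driven_neuron
        fit = fit_map(cv_design, train.counts, 1.0, variables=("Inhal",))
        with pytest.raises(ValueError, match="n_bins"):
            validate_exponential_nonlinearity(fit, cv_design, train.counts, 1)
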