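"""LLR decoding, posteriors, ablation and the behaviour-delay regression."""

import numpy as np
import pytest

from trialglm.decoding import (
    ablate_kernels,
    delay_regression,
    linear_classifier_decode,
    llr_at_time,
    llr_timecourse,
    population_decode,
    posterior_probability,
)
from trialglm.design import assemble_design_matrix
from trialglm.glm import fit_map
from trialglm.session import (
    make_ground_truth_kernels,
    odour_of,
    simulate_spikes,
)


@pytest.fixture(scope="module")
def odour_setup(cv_bundle, cv_design):
    design_A = assemble_design_matrix(cv_bundle, odour_override="R")
    design_B = assemble_design_matrix(cv_bundle, odour_override="U")
    model = make_ground_truth_kernels(
        ("Inhal", "Odour"), cv_design.bases, seed=61, amplitude_range=(0.8, 1.2)
    )
    counts = simulate_spikes(model, cv_design, seed=62).counts
    fit = fit_map(cv_design, counts, 1.0, variables=("Inhal", "Odour"))
    return design_A, design_B, counts, fit


class TestLLR:
    def test_equal_kernels_give_zero_llr(self, cv_bundle, cv_design, odour_setup):
        design_A, design_B, counts, fit = odour_setup
        tied = fit.with_weights(fit.w.copy())
        tied.w[fit.kernel_slices["O_U"]] = tied.w[fit.kernel_slices["O_R"]]
        curves = llr_timecourse(tied, design_A, design_B, counts, cv_bundle)
        assert max(np.abs(c).max() for c in curves) < 1e-10

    def test_population_llr_is_sum_of_units(self, cv_bundle, cv_design, odour_setup):
        design_A, design_B, counts, fit = odour_setup
        single = llr_at_time(fit, design_A, design_B, counts, cv_bundle)
        stacked = np.vstack([single, single, single])
        total = np.nansum(stacked, axis=0)
        assert np.allclose(total[~np.isnan(single)], 3 * single[~np.isnan(single)])

    def test_llr_positive_under_true_category(self, cv_bundle, cv_design, odour_setup):
        """Trials simulated under odour R end with positive mean LLR."""
        design_A, design_B, counts, fit = odour_setup
        llr = llr_at_time(fit, design_A, design_B, counts, cv_bundle, t_rel=0.5)
        is_R = np.array([odour_of(t.trial_type) == "R" for t in cv_bundle.trials])
        ok = ~np.isnan(llr)
        assert llr[ok & is_R].mean() > 0
        assert llr[ok & ~is_R].mean() < 0

    def test_category_relabelling_flips_sign(self, cv_bundle, odour_setup):
        design_A, design_B, counts, fit = odour_setup
        ab = llr_at_time(fit, design_A, design_B, counts, cv_bundle)
        ba = llr_at_time(fit, design_B, design_A, counts, cv_bundle)
        ok = ~np.isnan(ab)
        assert np.allclose(ab[ok], -ba[ok])


class TestPosterior:
    def test_equal_likelihoods_give_half(self):
        assert posterior_probability(np.array([0.0]))[0] == 0.5

    def test_complementarity(self, rng):
        llr = rng.normal(size=100) * 5
        p = posterior_probability(llr)
        q = posterior_probability(-llr)
        assert np.abs(p + q - 1.0).max() < 1e-12

    def test_matches_logistic_transform(self, rng):
        llr = rng.normal(size=200) * 3
        assert np.abs(
            posterior_probability(llr) - 1 / (1 + np.exp(-llr))
        ).max() < 1e-10

    def test_extreme_llr_never_nan(self):
        p = posterior_probability(np.array([-1e4, 1e4]))
        assert np.isfinite(p).all()
        assert p[0] == pytest.approx(0.0)
        assert p[1] == pytest.approx(1.0)

    def test_sign_agrees_with_posterior_argmax(self, cv_bundle, odour_setup):
        design_A, design_B, counts, fit = odour_setup
        llr = llr_at_time(fit, design_A, design_B, counts, cv_bundle)
        llr = llr[~np.isnan(llr)]
        p = posterior_probability(llr)
        assert np.all((llr > 0) == (p > 0.5))


class TestPopulationDecode:
    def test_shuffled_labels_at_chance(self, rng):
        """Label-shuffled control stays inside the binomial 99% band around
        0.5."""
        n_trials = 200
        llr = rng.normal(size=(5, n_trials))
        labels = rng.random(n_trials) < 0.5
        res = population_decode(llr, labels, seed=1, match_trials=False)
        band = 2.58 * np.sqrt(0.25 / n_trials)
        assert abs(res.shuffle_accuracy - 0.5) < band + 0.05

    def test_accuracy_grows_with_population_of_informative_units(self, rng):
        """Independently informative neurons: average accuracy does not
        decrease with population size."""
        labels = np.repeat([True, False], 100)
        signal = np.where(labels, 1.0, -1.0)
        llr = signal[None, :] * 0.4 + rng.normal(size=(30, 200))
        res = population_decode(
            llr, labels, sizes=(1, 5, 15, 30), n_repeats=40, seed=2,
            match_trials=False,
        )
        acc = [res.accuracy_by_size[s] for s in (1, 5, 15, 30)]
        assert all(b >= a - 0.02 for a, b in zip(acc, acc[1:]))
        assert acc[-1] > acc[0]

    def test_size_beyond_available_units_rejected(self, rng):
        llr = rng.normal(size=(4, 50))
        labels = rng.random(50) < 0.5
        with pytest.raises(ValueError, match="exceeds"):
            population_decode(llr, labels, sizes=(10,), match_trials=False)


class TestLinearClassifier:
    def test_separable_means_perfect_accuracy(self, rng):
        labels = np.repeat([True, False], 30)
        X = np.where(labels[:, None], 5.0, -5.0) + 0.0 * rng.normal(size=(60, 8))
        res = linear_classifier_decode(X, labels, seed=3)
        assert res.accuracy == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        labels = np.repeat([True, False], 60)
        X = np.where(labels[:, None], 1.0, -1.0) + rng.normal(size=(120, 10))
        res = linear_classifier_decode(X, labels, seed=4)
        assert abs(res.shuffle_accuracy - 0.5) < 0.18

    def test_fewer_trials_do_not_help(self, rng):
        """Halving trials per class cannot increase accuracy on matched
        problems (averaged over repeats)."""
        accs = {}
        for n_per in (48, 25):
            reps = []
            for rep in range(10):
                r = np.random.default_rng(100 + rep)
                labels = np.repeat([True, False], n_per)
                X = np.where(labels[:, None], 0.35, -0.35) + r.normal(
                    size=(2 * n_per, 12)
                )
                reps.append(linear_classifier_decode(X, labels, seed=rep).accuracy)
            accs[n_per] = np.mean(reps)
        assert accs[25] <= accs[48] + 0.02

    def test_class_below_fold_count_rejected(self, rng):
        labels = np.array([True, True, False, False])
        X = rng.normal(size=(4, 3))
        with pytest.raises(ValueError, match="3-fold"):
            linear_classifier_decode(X, labels)


class TestAblation:
    def test_only_odour_neuron_unchanged(self, cv_design, odour_setup):
        _, _, counts, _ = odour_setup
        fit = fit_map(cv_design, counts, 1.0, variables=("Odour",))
        ablated = ablate_kernels(fit, keep_variables=("Odour",))
        assert np.array_equal(ablated.w, fit.w)

    def test_ablated_rate_keeps_only_kept_blocks(self, cv_design, odour_setup):
        _, _, counts, fit = odour_setup
        ablated = ablate_kernels(fit, keep_variables=("Odour",))
        d = cv_design.subset(fit.variables)
        expected = np.exp(
            d.blocks["Odour"] @ fit.w[fit.col_slices["Odour"]] + fit.bias
        )
        got = np.exp(d.X @ ablated.w)
        assert np.allclose(got, expected, rtol=1e-12)

    def test_disjoint_keep_set_passes_through_with_warning(self, cv_design, odour_setup):
        _, _, counts, _ = odour_setup
        fit = fit_map(cv_design, counts, 1.0, variables=("Inhal",))
        with pytest.warns(UserWarning, match="unchanged"):
            out = ablate_kernels(fit, keep_variables=("Odour",))
        assert out is fit

    def test_empty_keep_set_rejected(self, cv_design, odour_setup):
        _, _, _, fit = odour_setup
        with pytest.raises(ValueError, match="nonempty"):
            ablate_kernels(fit, keep_variables=())


class TestDelayRegression:
    def test_noiseless_linear_model_perfect_fit(self, rng):
        p_or = rng.random(50)
        p_cr = rng.random(50)
        delays = 2.0 - 1.5 * p_or * p_cr + 0.3 * p_or
        res = delay_regression(delays, p_or, p_cr)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_interaction_power_at_n200(self):
        """Delays generated as linear in the product term plus noise: the
        interaction is detected at alpha = 0.05 in at least 90% of runs."""
        hits = 0
        n_runs = 30
        for rep in range(n_runs):
            r = np.random.default_rng(rep)
            p_or, p_cr = r.random(200), r.random(200)
            delays = 1.5 - 1.0 * p_or * p_cr + 0.25 * r.normal(size=200)
            res = delay_regression(delays, p_or, p_cr)
            hits += res.interaction_p < 0.05
        assert hits / n_runs >= 0.9

    def test_null_rejection_near_nominal_rate(self):
        rejections = 0
        n_runs = 200
        for rep in range(n_runs):
            r = np.random.default_rng(1000 + rep)
            p_or, p_cr = r.random(60), r.random(60)
            delays = r.normal(size=60)
            res = delay_regression(delays, p_or, p_cr)
            rejections += res.interaction_F_p < 0.05
        # binomial 99% band around the nominal 5% level
        assert abs(rejections / n_runs - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / n_runs)

    def test_rank_deficiency_rejected(self, rng):
        p = rng.random(30)
        with pytest.raises(ValueError, match="rank"):
            delay_regression(rng.normal(size=30), p, np.full(30, 0.0))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            delay_regression(np.ones(5), np.ones(5), np.ones(5))


class TestAccuracyTimecourse:
    def test_accuracy_rises_through_odour_sampling(self, cv_bundle, cv_design, odour_setup):
        """Before odour information arrives the decoder is at chance; by
        0.5 s after the first odour inhalation it is far above chance."""
        from trialglm.decoding import accuracy_timecourse
        from trialglm.session import odour_of

        design_A, design_B, counts, fit = odour_setup
        labels = np.array([odour_of(t.trial_type) == "R" for t in cv_bundle.trials])
        acc = accuracy_timecourse(
            [fit], design_A, design_B, [counts], cv_bundle, labels,
            times=np.array([-1.0, 0.5]),
        )
        assert acc[0] < 0.75
        assert acc[1] > 0.85
        assert acc.shape == (2,)
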