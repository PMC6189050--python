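"""Trial-by-trial accumulator model: moments, likelihood, fitting."""

import dataclasses

import numpy as np
import pytest
from scipy.special import erf

import dynclicks as dc
from dynclicks.accumulator import (NO_PRIORS, AccumulatorParams, ChoiceData,
                                   PriorConfig, dataset_moments, nll_and_grad,
                                   predicted_p_right)

from oracles import euler_maruyama_moments
from test_agents import make_trial


class TestAdaptation:
    def test_unit_phi_is_identity(self):
        w = dc.adaptation_trace(np.linspace(0, 1, 20), phi=1.0, tau_phi=0.05)
        np.testing.assert_allclose(w, 1.0)

    def test_two_click_depression_recursion(self):
        w = dc.adaptation_trace(np.array([0.0, 0.08]), phi=0.5, tau_phi=0.04)
        assert w[0] == pytest.approx(1.0)
        assert w[1] == pytest.approx(1 + (0.5 - 1) * np.exp(-0.08 / 0.04))

    def test_wide_spacing_recovers(self):
        w = dc.adaptation_trace(np.arange(5) * 1.0, phi=0.3, tau_phi=0.01)
        np.testing.assert_allclose(w[1:], 1.0, atol=1e-6)

    def test_facilitation_grows_weights(self):
        w = dc.adaptation_trace(np.arange(5) * 0.01, phi=1.4, tau_phi=0.1)
        assert np.all(np.diff(w) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            dc.adaptation_trace(np.array([0.0]), phi=0.5, tau_phi=-1.0)


class TestTrialMoments:
    def test_noiseless_reduces_to_linear_agent(self, study_config):
        trial = dc.generate_trial(study_config, 3)
        params = AccumulatorParams(lam=5.0)
        m = dc.trial_moments(trial, params)
        assert m.var == 0.0
        assert m.mu == pytest.approx(dc.linear_terminal([trial], 5.0)[0], rel=1e-10)

    def test_pure_diffusion_limit(self):
        trial = make_trial(duration=1.3)
        params = AccumulatorParams(lam=0.0, sigma_a2=0.7, sigma_i2=0.2)
        m = dc.trial_moments(trial, params)
        assert m.mu == 0.0
        assert m.var == pytest.approx(0.2 + 0.7 * 1.3)

    def test_moments_match_stochastic_simulation(self, study_config):
        # closed-form Gaussian solution vs brute-force Euler–Maruyama paths
        trial = dc.generate_trial(study_config, 8)
        params = AccumulatorParams(lam=5.0, sigma_a2=1.0, sigma_s2=2.0,
                                   sigma_i2=0.5, phi=0.8, tau_phi=0.05)
        m = dc.trial_moments(trial, params)
        mean, var, se_mean, se_var = euler_maruyama_moments(
            trial, params, n_paths=150_000, dt=1e-4, seed=2)
        assert m.mu == pytest.approx(mean, abs=3 * se_mean)
        assert m.var == pytest.approx(var, abs=3 * se_var)

    def test_dataset_moments_match_per_trial(self, study_config):
        trials = dc.generate_trials(study_config, 30)
        params = AccumulatorParams(lam=4.0, sigma_a2=0.3, sigma_s2=1.0,
                                   sigma_i2=0.1, phi=1.2, tau_phi=0.08)
        data = ChoiceData.from_trials(trials, np.ones(30))
        mu, var = dataset_moments(data, params)
        for i, trial in enumerate(trials):
            m = dc.trial_moments(trial, params)
            assert mu[i] == pytest.approx(m.mu, rel=1e-9)
            assert var[i] == pytest.approx(m.var, rel=1e-9)


class TestChoiceProbability:
    def test_mu_at_bias_gives_half(self):
        params = AccumulatorParams(bias=0.7, lapse=0.3)
        p_r, p_l = dc.choice_probability(0.7, 2.0, params)
        assert p_r == pytest.approx(0.5) and p_l == pytest.approx(0.5)

    def test_full_lapse_is_pure_guessing(self):
        params = AccumulatorParams(lapse=1.0)
        p_r, _ = dc.choice_probability(10.0, 1.0, params)
        assert p_r == pytest.approx(0.5)

    def test_one_sigma_displacement(self):
        params = AccumulatorParams()
        p_r, _ = dc.choice_probability(1.0, 1.0, params)
        assert p_r == pytest.approx(0.5 * (1 + erf(1 / np.sqrt(2))))
        assert p_r == pytest.approx(0.8413, abs=1e-4)

    def test_zero_variance_step_function(self):
        params = AccumulatorParams(bias=0.5)
        assert dc.choice_probability(1.0, 0.0, params)[0] == 1.0
        assert dc.choice_probability(0.0, 0.0, params)[0] == 0.0
        assert dc.choice_probability(0.5, 0.0, params)[0] == 0.5


class TestLikelihood:
    @pytest.fixture(scope="class")
    def small_data(self, study_config):
        trials = dc.generate_trials(study_config, 400)
        gen = AccumulatorParams(lam=6.0, sigma_s2=1.5, phi=0.9, tau_phi=0.06,
                                lapse=0.1)
        choices = dc.simulate_choices(trials, gen, seed=21)
        return trials, gen, ChoiceData.from_trials(trials, choices)

    def test_fifty_fifty_trial_contributes_log_two(self):
        trial = make_trial(duration=1.0)  # no clicks
        data = ChoiceData.from_trials([trial], np.array([1.0]))
        params = AccumulatorParams(sigma_i2=1.0)
        assert dc.negative_log_likelihood(data, params, NO_PRIORS) == pytest.approx(
            np.log(2.0))

    def test_duplication_doubles_likelihood_term(self, small_data):
        trials, gen, data = small_data
        doubled = ChoiceData.from_trials(trials + trials,
                                         np.concatenate([data.choice, data.choice]))
        prior = PriorConfig()
        single = dc.negative_log_likelihood(data, gen, prior) - prior.penalty(gen)
        both = dc.negative_log_likelihood(doubled, gen, prior) - prior.penalty(gen)
        assert both == pytest.approx(2 * single, rel=1e-9)

    def test_impossible_choice_gives_infinity(self):
        trial = make_trial(duration=1.0, right=[0.5])
        data = ChoiceData.from_trials([trial], np.array([-1.0]))
        params = AccumulatorParams(lam=0.0)  # deterministic, predicts right
        assert dc.negative_log_likelihood(data, params, NO_PRIORS) == np.inf

    def test_generative_parameters_near_optimal(self, small_data):
        _, gen, data = small_data
        nll_true = dc.negative_log_likelihood(data, gen, NO_PRIORS)
        rng = np.random.default_rng(5)
        worse = 0
        for _ in range(20):
            pert = AccumulatorParams(
                lam=gen.lam * rng.uniform(0.3, 3.0),
                sigma_s2=gen.sigma_s2 * rng.uniform(0.3, 3.0),
                phi=np.clip(gen.phi * rng.uniform(0.5, 2.0), 0.1, 5.0),
                tau_phi=np.clip(gen.tau_phi * rng.uniform(0.5, 2.0), 0.005, 1.0),
                lapse=np.clip(gen.lapse + rng.uniform(-0.08, 0.3), 0.0, 0.5),
            )
            if dc.negative_log_likelihood(data, pert, NO_PRIORS) > nll_true:
                worse += 1
        assert worse >= 16  # distant parameters are worse on average

    def test_analytic_gradient_matches_finite_differences(self, small_data):
        _, _, data = small_data
        theta = np.array([5.0, 0.4, 1.5, 0.2, 0.85, 0.08, 0.05, 0.08])
        f, g = nll_and_grad(data, theta)
        num = np.zeros(8)
        for i in range(8):
            e = np.zeros(8)
            e[i] = 1e-6 * max(abs(theta[i]), 1e-2)
            num[i] = (nll_and_grad(data, theta + e)[0]
                      - nll_and_grad(data, theta - e)[0]) / (2 * e[i])
        np.testing.assert_allclose(g, num, rtol=1e-4, atol=1e-6)


class TestSimulateChoices:
    def test_full_lapse_choice_rate(self, small_trials):
        params = AccumulatorParams(lapse=1.0)
        trials = small_trials * 10  # 3000 draws
        trials = [dataclasses.replace(t, trial_id=i) for i, t in enumerate(trials)]
        ch = dc.simulate_choices(trials, params, seed=3)
        se = np.sqrt(0.25 / len(trials))
        assert abs(np.mean(ch == 1.0) - 0.5) < 3 * se

    def test_noiseless_choice_is_click_difference_sign(self, small_trials):
        params = AccumulatorParams(lam=0.0)
        ch = dc.simulate_choices(small_trials, params, seed=3)
        diff = np.array([t.right_clicks.size - t.left_clicks.size
                         for t in small_trials])
        sel = diff != 0
        np.testing.assert_array_equal(ch[sel], np.sign(diff[sel]))

    def test_choice_frequency_matches_probability(self, study_config):
        base = dc.generate_trial(study_config, 0)
        params = AccumulatorParams(lam=3.0, sigma_s2=2.0, phi=0.9, tau_phi=0.05,
                                   lapse=0.1)
        repeats = [dataclasses.replace(base, trial_id=i) for i in range(20_000)]
        p = predicted_p_right(ChoiceData.from_trials([base], np.ones(1)), params)[0]
        ch = dc.simulate_choices(repeats, params, seed=9)
        se = np.sqrt(p * (1 - p) / len(repeats))
        assert abs(np.mean(ch == 1.0) - p) < 3 * se


class TestNoiseLevel:
    def test_zero_sensory_noise(self, small_trials):
        assert dc.noise_level(AccumulatorParams(sigma_s2=0.0), small_trials) == 0.0

    def test_unit_adaptation_standard_value(self, small_trials):
        # ϕ = 1 keeps ⟨C⟩ = 1; σs² = 1 gives the standard normal tail
        params = AccumulatorParams(sigma_s2=1.0, phi=1.0)
        n = dc.noise_level(params, small_trials)
        assert n == pytest.approx(0.5 * (1 + erf(-1 / np.sqrt(2))), abs=1e-9)
        assert n == pytest.approx(0.1587, abs=1e-4)

    def test_monotone_in_sensory_noise(self, small_trials):
        ns = [dc.noise_level(AccumulatorParams(sigma_s2=s, phi=0.9, tau_phi=0.05),
                             small_trials) for s in (0.5, 1.0, 2.0, 8.0, 100.0)]
        assert all(a < b for a, b in zip(ns, ns[1:]))
        assert ns[-1] < 0.5  # saturates below chance


class TestFitting:
    def test_recovered_lambda_in_confidence_interval(self, recovery_bundle):
        rb = recovery_bundle
        lo, hi = rb.result.ci["lam"]
        assert lo <= rb.generative.lam <= hi
        assert not rb.result.pseudo_inverse

    def test_identifiable_core_recovered(self, recovery_bundle):
        rb = recovery_bundle
        for name in ("bias", "lapse"):
            lo, hi = rb.result.ci[name]
            assert lo <= getattr(rb.generative, name) <= hi
        # weakly identified noise variances stay within regularized bounds
        assert 0.0 <= rb.result.params.sigma_a2 <= 5.0
        assert 0.0 <= rb.result.params.sigma_i2 <= 5.0

    def test_prior_removal_keeps_discounting_conclusion(self, recovery_bundle):
        rb = recovery_bundle
        refit = dc.fit(rb.data, init=rb.result.params, prior=NO_PRIORS,
                       n_starts=0, seed=1)
        half_width = 0.5 * (rb.result.ci["lam"][1] - rb.result.ci["lam"][0])
        assert abs(refit.params.lam - rb.result.params.lam) < half_width

    def test_static_vs_dynamic_discounting_separates(self, study_config):
        shared = dict(sigma_s2=2.0, phi=0.9, tau_phi=0.06, lapse=0.05)
        trials = dc.generate_trials(
            dataclasses.replace(study_config, seed=311), 4000)
        fitted = {}
        for lam_gen in (0.2, 10.0):
            gen = AccumulatorParams(lam=lam_gen, **shared)
            ch = dc.simulate_choices(trials, gen, seed=int(lam_gen * 10))
            res = dc.fit(ChoiceData.from_trials(trials, ch), n_starts=2, seed=4)
            fitted[lam_gen] = res.params.lam
        assert fitted[10.0] > 8.0 * max(fitted[0.2], 0.05)

    def test_residuals_flat_in_duration(self, recovery_bundle):
        # well-specified fit: mean choice residual has no duration trend
        import statsmodels.api as sm
        rb = recovery_bundle
        p = predicted_p_right(rb.data, rb.result.params)
        resid = (rb.data.choice > 0).astype(float) - p
        X = sm.add_constant(rb.data.T)
        ols = sm.OLS(resid, X).fit()
        lo, hi = ols.conf_int()[1]
        assert lo < 0.0 < hi

    def test_model_reproduces_reverse_correlation_timescale(self, recovery_bundle):
        rb = recovery_bundle
        sub = rb.trials[:8000]
        model_ch = dc.simulate_choices(sub, rb.result.params, seed=71)
        cfg = dc.TaskConfig()
        res_subj = dc.reverse_correlation(sub, rb.choices[:8000],
                                          cfg.rate_high, cfg.rate_low)
        res_model = dc.reverse_correlation(sub, model_ch,
                                           cfg.rate_high, cfg.rate_low)
        b_subj, b_model = res_subj.fit_right.b, res_model.fit_right.b
        assert b_model == pytest.approx(b_subj, abs=0.35 * abs(b_subj))


class TestOptimalityAnalyses:
    def test_accuracy_maximizing_lambda_near_generative(self, recovery_bundle):
        rb = recovery_bundle
        lam_acc, _, curve, gain = dc.accuracy_maximizing_lambda(
            rb.result.params, rb.trials[:6000])
        assert gain < 0.01  # < 1 percentage point improvement
        assert lam_acc == pytest.approx(rb.generative.lam, abs=3.0)
        # expected accuracy is unimodal on the coarse grid (after smoothing noise)
        peak = int(np.argmax(curve))
        assert np.all(np.diff(curve[:peak + 1]) >= -1e-6) or peak == 0

    def test_zero_noise_params_recover_normative_lambda(self, study_config):
        # with all noise off the model is the linear agent, so the
        # accuracy-maximizing λ matches the normative numerical optimum
        trials = dc.generate_trials(
            dataclasses.replace(study_config, seed=411), 6000)
        noisy = dc.mislocalize_trials(trials, 0.35, 412)
        lam_star, _, _ = dc.optimize_lambda(noisy)
        params = AccumulatorParams(lam=lam_star)
        lam_acc, _, _, gain = dc.accuracy_maximizing_lambda(params, noisy)
        assert lam_acc == pytest.approx(lam_star, abs=1.0)
        assert gain < 0.005


class TestBlockFits:
    @pytest.fixture(scope="class")
    def switch_dataset(self, study_config):
        gen = AccumulatorParams(lam=5.0, sigma_a2=0.5, sigma_s2=2.0, sigma_i2=0.3,
                                phi=0.9, tau_phi=0.06, lapse=0.05)
        bs = 2000
        trials = dc.generate_trials(
            dataclasses.replace(study_config, seed=77), 6 * bs)
        ch = np.empty(6 * bs)
        ch[:3 * bs] = dc.simulate_choices(trials[:3 * bs], gen, seed=8)
        low = dataclasses.replace(gen, lam=0.5)
        ch[3 * bs:] = dc.simulate_choices(trials[3 * bs:], low, seed=9)
        return trials, ch, gen, bs

    def test_tracks_generative_switch(self, switch_dataset):
        trials, ch, gen, bs = switch_dataset
        blocks = dc.fit_lambda_blocks(trials, ch, gen, block_size=bs)
        lams = [b.lam for b in blocks]
        assert all(3.5 < x < 7.0 for x in lams[:3])
        assert all(x < 1.5 for x in lams[3:])  # adjusts within one block

    def test_stationary_blocks_are_consistent(self, switch_dataset):
        trials, ch, gen, bs = switch_dataset
        blocks = dc.fit_lambda_blocks(trials[:3 * bs], ch[:3 * bs], gen,
                                      block_size=bs)
        for a in blocks:
            for b in blocks:
                assert a.ci[0] <= b.lam + (b.ci[1] - b.ci[0])  # CI-compatible

    def test_partial_final_block_dropped(self, switch_dataset, caplog):
        trials, ch, gen, bs = switch_dataset
        n = 2 * bs + 100  # trailing 100 trials < 20% of block size
        blocks = dc.fit_lambda_blocks(trials[:n], ch[:n], gen, block_size=bs)
        assert len(blocks) == 2
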