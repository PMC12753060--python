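import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priorcfc import geometry as geo, observers as obs
from priorcfc.observers import ModelTag, ObserverParams

from oracles import (
    prior_only_choice_probs,
    quadrature_choice_probs,
    quadrature_truncated_mean_distance,
)

NOBIAS = geo.preferred_directions("NoBias")
BLUE = geo.preferred_directions("Bias", "blue")
ORANGE = geo.preferred_directions("Bias", "orange")


class TestPosteriorAlgebra:
    def test_symmetry_at_zero_signal_nobias(self, base_params):
        s = obs.posterior_choice_probabilities(0.0, base_params, NOBIAS)
        assert s.p_orange == pytest.approx(0.5, abs=1e-12)
        assert s.p_blue == pytest.approx(0.5, abs=1e-12)

    def test_blue_bias_pulls_choice_at_zero_signal(self, base_params):
        s = obs.posterior_choice_probabilities(0.0, base_params, BLUE)
        assert s.p_blue > 0.5

    @pytest.mark.parametrize("directions", [NOBIAS, BLUE, ORANGE])
    @pytest.mark.parametrize("r", [-40.0, 0.0, 10.0, 55.0])
    def test_matches_quadrature_oracle(self, r, directions, base_params):
        s = obs.posterior_choice_probabilities(r, base_params, directions)
        po, pb = quadrature_choice_probs(
            r,
            base_params.sigma_p,
            base_params.sigma_l,
            directions.mu_orth1,
            directions.mu_orth2,
        )
        assert s.p_blue == pytest.approx(pb, abs=1e-6)
        assert s.p_orange == pytest.approx(po, abs=1e-6)

    @given(
        r=st.floats(-85, 85),
        sigma_p=st.floats(5, 200),
        sigma_l=st.floats(2, 60),
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_probabilities_normalize(self, r, sigma_p, sigma_l):
        params = ObserverParams(sigma_p=sigma_p, sigma_l=sigma_l)
        for d in (NOBIAS, BLUE):
            s = obs.posterior_choice_probabilities(r, params, d)
            assert s.p_orange + s.p_blue == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= s.p_blue <= 1.0
            assert sum(s.component_weights) == pytest.approx(1.0, abs=1e-12)

    def test_mirror_symmetry_of_bias_directions(self, base_params):
        r = np.linspace(-80, 80, 41)
        mo_b, mb_b, tot_b = obs.posterior_masses(
            r, base_params.sigma_p, base_params.sigma_l, BLUE
        )
        mo_o, mb_o, tot_o = obs.posterior_masses(
            -r, base_params.sigma_p, base_params.sigma_l, ORANGE
        )
        np.testing.assert_allclose(mb_b / tot_b, mo_o / tot_o, atol=1e-12)

    def test_single_gaussian_simplification_is_close(self, base_params):
        """The far mixture component (145 deg out) is negligible for the
        Bias condition in the study's parameter range: the choice
        probability shifts by < 1e-3 near the stimulus range and stays
        below 5e-3 even for extreme internal signals."""
        r = np.linspace(-60, 60, 241)
        _, mb_full, tot_full = obs.posterior_masses(
            r, base_params.sigma_p, base_params.sigma_l, BLUE
        )
        _, mb_single, tot_single = obs.posterior_masses(
            r, base_params.sigma_p, base_params.sigma_l, BLUE, single_gaussian=True
        )
        diff = np.abs(mb_full / tot_full - mb_single / tot_single)
        assert diff[np.abs(r) <= 20].max() < 1e-3
        assert diff.max() < 5e-3

    def test_decision_threshold_matches_probability_crossing(self, base_params):
        r_star = obs.decision_threshold(
            base_params.sigma_p, base_params.sigma_l, BLUE
        )
        s = obs.posterior_choice_probabilities(r_star, base_params, BLUE)
        assert s.p_blue == pytest.approx(0.5, abs=1e-9)
        assert r_star < 0  # blue bias: blue chosen even for mildly orange signals


class TestDecisionRule:
    def test_majority_side_wins(self):
        rng = np.random.default_rng(0)
        hi = obs.PosteriorSummary(0.3, 0.7, 1.0, (1.0,), (10.0,), 5.0)
        lo = obs.PosteriorSummary(0.7, 0.3, 1.0, (1.0,), (-10.0,), 5.0)
        assert obs.perceptual_decision(hi, rng) == 1
        assert obs.perceptual_decision(lo, rng) == 0

    def test_tie_is_fair_coin(self):
        tie = obs.PosteriorSummary(0.5, 0.5, 1.0, (1.0,), (0.0,), 5.0)
        outcomes = {
            obs.perceptual_decision(tie, np.random.default_rng(s))
            for s in range(30)
        }
        assert outcomes == {0, 1}


class TestConfidenceRules:
    def test_bayesian_confidence_is_chosen_probability(self):
        s = obs.PosteriorSummary(0.2, 0.8, 1.0, (1.0,), (10.0,), 5.0)
        assert obs.confidence_bayesian(s, 1).value == pytest.approx(0.8)
        s_tie = obs.PosteriorSummary(0.5, 0.5, 1.0, (1.0,), (0.0,), 5.0)
        assert obs.confidence_bayesian(s_tie, 0).value == pytest.approx(0.5)

    def test_bayesian_confidence_flat_prior_matches_quadrature(self):
        params = ObserverParams(sigma_p=1e6, sigma_l=15.0)
        r = 20.0
        s = obs.posterior_choice_probabilities(r, params, NOBIAS)
        _, pb = quadrature_choice_probs(r, 1e6, 15.0, 90.0, -90.0)
        assert obs.confidence_bayesian(s, 1).value == pytest.approx(pb, abs=1e-6)

    def test_distance_sample_point_mass_limit(self):
        s = obs.PosteriorSummary(0.0, 1.0, 1.0, (1.0, 0.0), (40.0, -140.0), 1e-9)
        c = obs.confidence_distance_to_criterion(s, 1, np.random.default_rng(1))
        assert c.value == pytest.approx(40.0, abs=1e-6)
        assert c.scale == "distance_deg"

    def test_distance_samples_respect_side_and_mean(self, base_params):
        r = 12.0
        s = obs.posterior_choice_probabilities(r, base_params, BLUE)
        rng = np.random.default_rng(7)
        n = 20_000
        samples = np.array(
            [obs.sample_posterior_side(s, 1, rng.random(), rng.random())
             for _ in range(n)]
        )
        assert np.all(samples >= 0.0)
        expected = quadrature_truncated_mean_distance(
            r, base_params.sigma_p, base_params.sigma_l,
            BLUE.mu_orth1, BLUE.mu_orth2, side=1,
        )
        se = samples.std() / np.sqrt(n)
        assert abs(samples.mean() - expected) < 3 * se

    def test_decoupled_prior_reduces_to_bayes_at_w1(self, base_params):
        p = ObserverParams(sigma_p=30, sigma_l=15, w=1.0)
        for r in (-20.0, 3.0, 40.0):
            s = obs.posterior_choice_probabilities(r, p, BLUE)
            choice = int(s.p_blue > 0.5)
            assert obs.confidence_decoupled_prior(r, p, BLUE, choice).value == (
                pytest.approx(obs.confidence_bayesian(s, choice).value, abs=0)
            )

    def test_decoupled_prior_overweights_prior(self):
        """At the group-fit w = 1.54 a blue choice congruent with the blue
        bias gets a confidence boost relative to the Bayesian read-out."""
        p1 = ObserverParams(sigma_p=30, sigma_l=15, w=1.0)
        p154 = ObserverParams(sigma_p=30, sigma_l=15, w=1.54)
        r = 5.0
        c1 = obs.confidence_decoupled_prior(r, p1, BLUE, 1).value
        c154 = obs.confidence_decoupled_prior(r, p154, BLUE, 1).value
        assert c154 > c1

    def test_decoupled_prior_large_w_approaches_prior_only(self):
        p = ObserverParams(sigma_p=30, sigma_l=15, w=1e8)
        _, pb_prior = prior_only_choice_probs(30.0, BLUE.mu_orth1, BLUE.mu_orth2)
        c = obs.confidence_decoupled_prior(10.0, p, BLUE, 1)
        assert c.value == pytest.approx(pb_prior, abs=1e-5)

    def test_decoupled_prior_monotone_in_w_above_one(self):
        """For w >= 1 (prior increasingly overweighted) confidence in a
        bias-congruent choice is non-decreasing in w.  Below w = 1 the
        sharpening likelihood takes over and confidence rises again, so
        monotonicity holds only on the overweighting side."""
        ws = [1.0, 1.25, 1.54, 2.0, 3.0, 4.0]
        vals = [
            obs.confidence_decoupled_prior(
                5.0, ObserverParams(sigma_p=30, sigma_l=15, w=w), BLUE, 1
            ).value
            for w in ws
        ]
        assert np.all(np.diff(vals) >= 0)

    @pytest.mark.parametrize(
        "theta_r, theta_p, expected",
        [(35.0, 35.0, 1.0), (125.0, 35.0, 0.0), (95.0, 35.0, 0.5)],
    )
    def test_pce_cosine_values(self, theta_r, theta_p, expected):
        assert obs.confidence_pce(theta_r, theta_p).value == pytest.approx(
            expected, abs=1e-12
        )

    def test_pce_is_antipode_invariant(self):
        """Either mixture mean gives the same prior-congruent evidence."""
        for theta_r in (-50.0, 0.0, 20.0):
            a = obs.confidence_pce(theta_r, BLUE.mu_orth1).value
            b = obs.confidence_pce(theta_r, BLUE.mu_orth2).value
            assert a == pytest.approx(b, abs=1e-12)

    def test_wppce_mixture(self):
        assert obs.confidence_wppce(0.8, 0.5, 0.34).value == pytest.approx(0.698)
        assert obs.confidence_wppce(0.8, 0.5, 0.0).value == pytest.approx(0.8)
        assert obs.confidence_wppce(0.8, 0.5, 1.0).value == pytest.approx(0.5)
        with pytest.raises(ValueError):
            obs.confidence_wppce(0.8, 0.5, 1.2)

    @given(
        bpe=st.floats(0.5, 1.0),
        pce=st.floats(0.0, 1.0),
        a1=st.floats(0.0, 1.0),
        a2=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=40)
    def test_wppce_linear_in_alpha(self, bpe, pce, a1, a2):
        mid = obs.confidence_wppce(bpe, pce, (a1 + a2) / 2).value
        ends = (
            obs.confidence_wppce(bpe, pce, a1).value
            + obs.confidence_wppce(bpe, pce, a2).value
        ) / 2
        assert mid == pytest.approx(ends, abs=1e-12)


class TestForcedChoice:
    def test_larger_confidence_wins(self):
        rng = np.random.default_rng(0)
        c = obs.ConfidenceValue
        assert obs.confidence_forced_choice(c(0.9, "x"), c(0.6, "x"), rng) == 1
        assert obs.confidence_forced_choice(c(0.55, "x"), c(0.8, "x"), rng) == 2

    def test_scale_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            obs.confidence_forced_choice(
                obs.ConfidenceValue(0.9, "posterior_prob"),
                obs.ConfidenceValue(0.6, "distance_deg"),
                rng,
            )

    def test_tie_is_fair_coin(self):
        c = obs.ConfidenceValue(0.7, "x")
        outcomes = {
            obs.confidence_forced_choice(c, c, np.random.default_rng(s))
            for s in range(30)
        }
        assert outcomes == {1, 2}


class TestEfficientCoding:
    def test_flat_prior_reduces_to_plain_gaussian_decoding(self):
        """With an (effectively) uniform prior the cumulative mapping is
        linear, so the induced likelihood is a constant-width Gaussian and
        grid decoding must agree with the closed-form flat-prior posterior."""
        enc = obs.EfficientCodingEncoder(1e6, 0.05, 0.02, geo.Condition.NO_BIAS)
        sigma_theta = 0.05 * 360.0  # measurement SD mapped back to degrees
        for theta in (-30.0, 0.0, 20.0):
            m = float(enc.cumulative_prior(np.array([theta]))[0])
            pb_grid = float(enc.p_blue(m)[0])
            # flat prior: posterior is the truncated likelihood around theta
            from scipy.stats import norm

            mass_blue = norm.cdf((90 - theta) / sigma_theta) - norm.cdf(
                (0 - theta) / sigma_theta
            )
            mass_orange = norm.cdf((0 - theta) / sigma_theta) - norm.cdf(
                (-90 - theta) / sigma_theta
            )
            assert pb_grid == pytest.approx(
                mass_blue / (mass_blue + mass_orange), abs=1e-6
            )

    def test_encoding_precision_follows_prior(self):
        """The cumulative-prior slope (hence encoding precision) is higher
        at the prior peak than far from it."""
        enc = obs.EfficientCodingEncoder(30.0, 0.1, 0.05, geo.Condition.NO_BIAS)
        grid = enc.theta_grid
        dF = np.gradient(enc.cumulative_prior(grid), grid)
        at_peak = dF[np.argmin(np.abs(grid - 90 + 1))]
        at_reference = dF[np.argmin(np.abs(grid))]
        assert at_peak > at_reference

    def test_grid_refinement_converges(self):
        enc = obs.EfficientCodingEncoder(
            30.0, 0.1, 0.05, geo.Condition.BIAS, geo.BiasDirection.BLUE
        )
        fine = obs.EfficientCodingEncoder(
            30.0, 0.1, 0.05, geo.Condition.BIAS, geo.BiasDirection.BLUE,
            grid_step=0.01,
        )
        for m in (0.2, 0.45, 0.6, 0.8):
            assert float(enc.p_blue(m)[0]) == pytest.approx(
                float(fine.p_blue(m)[0]), abs=1e-4
            )

    def test_p_blue_monotone_in_measurement(self):
        enc = obs.EfficientCodingEncoder(
            30.0, 0.1, 0.05, geo.Condition.BIAS, geo.BiasDirection.BLUE
        )
        m = np.linspace(0.05, 0.95, 61)
        assert np.all(np.diff(enc.p_blue(m)) > 0)

    def test_interpolated_p_blue_matches_exact(self):
        enc = obs.EfficientCodingEncoder(
            40.0, 0.08, 0.04, geo.Condition.NO_BIAS
        )
        m = np.linspace(0.1, 0.9, 33)
        np.testing.assert_allclose(enc.p_blue_fast(m), enc.p_blue(m), atol=1e-5)

    def test_likelihood_warning_on_coarse_grid(self):
        params = ObserverParams(sigma_p=30, sigma_n=0.05, sigma_t=0.02)
        with pytest.warns(UserWarning, match="coarse"):
            obs.ec_likelihood(
                10.0,
                params,
                (geo.Condition.NO_BIAS, geo.BiasDirection.NONE),
                np.linspace(-90, 90, 19),
                np.random.default_rng(0),
            )


class TestTrialSimulation:
    @pytest.mark.parametrize(
        "model_a, params_a, model_b, params_b",
        [
            (
                ModelTag.DP,
                ObserverParams(sigma_p=30, sigma_l=15, w=1.0),
                ModelTag.BAYES,
                ObserverParams(sigma_p=30, sigma_l=15),
            ),
            (
                ModelTag.WPPCE,
                ObserverParams(sigma_p=30, sigma_l=15, alpha=0.0),
                ModelTag.BAYES,
                ObserverParams(sigma_p=30, sigma_l=15),
            ),
            (
                ModelTag.WPPCE,
                ObserverParams(sigma_p=30, sigma_l=15, alpha=1.0),
                ModelTag.PCE,
                ObserverParams(sigma_p=30, sigma_l=15),
            ),
        ],
    )
    def test_identity_reductions_bitwise(
        self, small_design, model_a, params_a, model_b, params_b
    ):
        rec_a = obs.simulate_trials(
            small_design.trials, model_a, params_a, np.random.default_rng(99)
        )
        rec_b = obs.simulate_trials(
            small_design.trials, model_b, params_b, np.random.default_rng(99)
        )
        for a, b in zip(rec_a, rec_b):
            assert a.responses == b.responses
            assert a.confidence_choice == b.confidence_choice

    def test_symmetric_stimuli_yield_fair_coins(self):
        spec = geo.StimulusSpec(geo.Condition.NO_BIAS, 0.0)
        pairs = [(spec, spec)] * 4000
        recs = obs.simulate_trials(
            pairs, "bayes", ObserverParams(), np.random.default_rng(5)
        )
        resp = np.array([r.responses for r in recs])
        cfc = np.array([r.confidence_choice for r in recs])
        se = 0.5 / np.sqrt(len(recs))
        assert abs(resp.mean() - 0.5) < 4 * se / np.sqrt(2)
        assert abs((cfc == 1).mean() - 0.5) < 4 * se
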