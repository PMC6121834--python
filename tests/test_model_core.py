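"""Model primitives: fitness surface, losses, distributions, rule containers."""

import numpy as np
import pytest

from signalgap import (
    InferenceRule,
    LossSpec,
    ModelParams,
    QualityDist,
    SignallingRule,
    average_receiver_loss,
    male_fitness,
    non_informational_optimum,
    receiver_loss,
)


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"beta_slope": 0.0},
            {"beta_slope": -1.0},
            {"sigma_cost": 0.0},
            {"a_min": -1.0},
            {"lambda_pref": -0.5},
            {"q_min": 2.0, "q_max": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_caption_formulas(self):
        p = ModelParams(lambda_pref=1.0, sigma_cost=2.0, beta_slope=1.0)
        assert p.asymptote == pytest.approx(2.0)
        assert p.half_life == pytest.approx(2.0 * np.log(2.0))


class TestNonInformationalOptimum:
    def test_intercept_and_linearity(self):
        p = ModelParams(a_min=1.0, q_min=0.0, q_max=5.0, beta_slope=1.0)
        assert non_informational_optimum(p.q_min, p) == pytest.approx(1.0)
        assert non_informational_optimum(2.0, p) == pytest.approx(3.0)
        q = np.linspace(0, 5, 11)
        assert np.all(np.diff(non_informational_optimum(q, p)) > 0)

    def test_out_of_range_quality_rejected(self, unit_params):
        with pytest.raises(ValueError):
            non_informational_optimum(unit_params.q_max + 1.0, unit_params)


class TestMaleFitness:
    def test_no_deviation_no_preference_gives_unit_fitness(self, unit_params):
        n0 = non_informational_optimum(0.0, unit_params)
        assert male_fitness(n0, 0.0, 0.0, unit_params) == pytest.approx(1.0)
        lam0 = unit_params.replace(lambda_pref=0.0)
        assert male_fitness(n0, 3.0, 0.0, lam0) == pytest.approx(1.0)

    def test_unit_deviation_costs_exp_half(self, unit_params):
        n0 = non_informational_optimum(0.0, unit_params)
        w = male_fitness(n0 + 1.0, 0.0, 0.0, unit_params)
        assert w == pytest.approx(np.exp(-0.5))

    def test_maximised_at_the_optimum(self, unit_params):
        q = 2.0
        n_q = non_informational_optimum(q, unit_params)
        a = np.linspace(0.5, 8.0, 301)
        w = male_fitness(a, 3.0, q, unit_params)
        assert abs(a[np.argmax(w)] - n_q) < (a[1] - a[0])

    def test_log_fitness_separates_benefit_and_cost(self, unit_params):
        # log w(a, p, q) - log w(a, 0, q) must equal lambda * p for any a
        for a in (1.0, 2.5, 4.0):
            diff = np.log(male_fitness(a, 1.7, 1.0, unit_params)) - np.log(
                male_fitness(a, 0.0, 1.0, unit_params)
            )
            assert diff == pytest.approx(unit_params.lambda_pref * 1.7)

    def test_nonpositive_trait_rejected(self, unit_params):
        with pytest.raises(ValueError):
            male_fitness(0.0, 1.0, 1.0, unit_params)

    def test_single_crossing_mrs_decreases_in_quality(self, unit_params):
        # MRS = (a - n(q)) / (lambda sigma) falls with q at every fixed a
        a = np.linspace(1.0, 7.0, 13)
        q = np.linspace(0.0, 5.0, 11)
        n_q = np.asarray(non_informational_optimum(q, unit_params))
        mrs = (a[None, :] - n_q[:, None]) / (
            unit_params.lambda_pref * unit_params.sigma_cost
        )
        assert np.all(np.diff(mrs, axis=0) < 0)


class TestReceiverLoss:
    def test_zero_at_truth_and_symmetric_square(self):
        assert receiver_loss(0.7, 0.7) == 0.0
        assert receiver_loss(0.5, 1.0) == pytest.approx(0.25)

    def test_monotone_in_discrepancy(self):
        q = 2.0
        d = np.array([0.1, 0.4, 0.9, 1.7])
        up = np.asarray(receiver_loss(q, q + d))
        dn = np.asarray(receiver_loss(q, q - d))
        assert np.all(np.diff(up) > 0) and np.all(np.diff(dn) > 0)

    def test_asymmetric_weights(self):
        loss = LossSpec(over_weight=2.0, under_weight=1.0)
        assert loss(1.0, 1.5) == pytest.approx(2.0 * 0.25)
        assert loss(1.0, 0.5) == pytest.approx(0.25)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            LossSpec(form="absolute")
        with pytest.raises(ValueError):
            LossSpec(over_weight=0.0)


class TestQualityDist:
    def test_uniform_normalisation(self):
        G = QualityDist(0.0, 5.0)
        q = np.linspace(0, 5, 1001)
        assert np.trapezoid(np.asarray(G.pdf(q)), q) == pytest.approx(1.0)
        assert G.cdf(5.0) == 1.0 and G.cdf(0.0) == 0.0
        assert np.all(np.asarray(G.pdf(q)) > 0)


class TestAverageReceiverLoss:
    def test_honest_pair_gives_zero(self, unit_solution, unit_quality_dist):
        val = average_receiver_loss(
            unit_solution.rule, unit_solution.P_star, unit_quality_dist
        )
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_constant_inference_matches_closed_form(self):
        # uniform G on [0,1], P = 1/2: integral of (q - 1/2)^2 dq = 1/12
        G = QualityDist(0.0, 1.0)
        val = average_receiver_loss(lambda q: q + 1.0, lambda a: 0.5, G)
        assert val == pytest.approx(1.0 / 12.0)

    def test_worse_constant_inference_has_larger_loss(self):
        G = QualityDist(0.0, 1.0)
        at_min = average_receiver_loss(lambda q: q + 1.0, lambda a: 0.0, G)
        at_mid = average_receiver_loss(lambda q: q + 1.0, lambda a: 0.5, G)
        assert at_min > at_mid


class TestRuleContainers:
    def test_signalling_rule_validates(self):
        with pytest.raises(ValueError):
            SignallingRule(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
        with pytest.raises(ValueError):
            SignallingRule(np.array([1.0, 0.0]), np.array([1.0, 2.0]))

    def test_inference_rule_clamps(self):
        P = InferenceRule(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 5.0]), 0.0, 5.0)
        assert P(0.0) == pytest.approx(0.0)  # below range -> lowest node value
        assert P(10.0) == pytest.approx(5.0)
        assert float(P(2.0)) == pytest.approx(1.0)

    def test_single_node_inference_is_constant(self):
        P = InferenceRule(np.array([2.0]), np.array([2.5]), 0.0, 5.0)
        assert P(0.5) == pytest.approx(2.5) and P(7.0) == pytest.approx(2.5)
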