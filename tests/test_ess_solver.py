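"""Separating-equilibrium solver: ODE route, closed form, costs, limits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from signalgap import (
    ModelParams,
    asymptote_halflife,
    equilibrium_cost,
    exaggeration_implicit,
    exaggeration_rhs,
    solve_equilibrium,
    solve_equilibrium_general,
)
from signalgap.model_core import non_informational_optimum

param_scale = st.floats(min_value=0.25, max_value=4.0)


class TestExaggerationRhs:
    def test_zero_at_asymptote_and_divergent_at_origin(self, unit_params):
        assert exaggeration_rhs(unit_params.asymptote, unit_params) == pytest.approx(0.0)
        assert exaggeration_rhs(0.0, unit_params) == np.inf
        # lambda sigma / E - beta at E = 0.5 with unit parameters
        assert exaggeration_rhs(0.5, unit_params) == pytest.approx(1.0)

    def test_negative_exaggeration_rejected(self, unit_params):
        with pytest.raises(ValueError):
            exaggeration_rhs(-0.1, unit_params)


class TestImplicitSolution:
    def test_boundary_is_exact_zero(self, unit_params):
        assert exaggeration_implicit(unit_params.q_min, unit_params) == 0.0

    def test_limit_is_caption_asymptote(self):
        p = ModelParams(lambda_pref=1.0, sigma_cost=2.0, beta_slope=1.0, q_max=1e4)
        assert exaggeration_implicit(1e4, p) == pytest.approx(2.0, abs=1e-12)

    def test_agrees_with_ode_at_tau_one(self, unit_params, unit_solution):
        E_closed = exaggeration_implicit(1.0, unit_params)
        E_ode = float(unit_solution.exaggeration_at(1.0))
        assert E_ode == pytest.approx(E_closed, abs=1e-8)

    def test_near_boundary_square_root_law(self, unit_params):
        # E(q) ~ sqrt(2 lambda sigma (q - q_min)) as q -> q_min+
        for dq, tol in [(1e-4, 5e-3), (1e-6, 5e-4), (1e-8, 5e-5)]:
            ratio = exaggeration_implicit(dq, unit_params) / np.sqrt(2.0 * dq)
            assert abs(ratio - 1.0) < tol


class TestSolveEquilibrium:
    def test_boundary_condition_for_any_valid_parameters(self):
        for lam, sig, beta in [(1, 1, 1), (0.5, 2, 0.25), (3, 0.5, 2)]:
            p = ModelParams(lambda_pref=lam, sigma_cost=sig, beta_slope=beta)
            sol = solve_equilibrium(p)
            assert sol.E[0] == 0.0

    def test_solution_invariants(self, unit_solution):
        sol = unit_solution
        assert np.all(sol.E[1:] > 0)
        assert np.all(np.diff(sol.A_star) > 0)
        assert np.all(sol.E < sol.params.asymptote)
        # slope decreasing toward beta
        dA = np.gradient(sol.A_star, sol.q_grid)
        assert np.all(np.diff(dA) < 1e-6)
        assert dA[-1] > sol.params.beta_slope

    def test_honest_inference_across_grid(self, unit_solution):
        recovered = np.asarray(unit_solution.P_star(unit_solution.A_star))
        assert np.max(np.abs(recovered - unit_solution.q_grid)) < 1e-6

    def test_lambda_zero_returns_cue_equilibrium(self):
        p = ModelParams(lambda_pref=0.0)
        sol = solve_equilibrium(p)
        assert not sol.signalling
        assert np.all(sol.E == 0.0)
        assert np.allclose(sol.A_star, sol.n)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(lam=param_scale, sig=param_scale, beta=param_scale)
    def test_oracle_equivalence_ode_vs_closed_form(self, lam, sig, beta):
        p = ModelParams(lambda_pref=lam, sigma_cost=sig, beta_slope=beta)
        sol = solve_equilibrium(p, np.linspace(0.0, 5.0, 401))
        probe = sol.q_grid[::40][1:]
        closed = np.asarray(exaggeration_implicit(probe, p))
        ode = np.interp(probe, sol.q_grid, sol.E)
        assert np.max(np.abs(ode - closed) / closed) < 1e-6

    def test_bad_grid_rejected(self, unit_params):
        with pytest.raises(ValueError):
            solve_equilibrium(unit_params, np.linspace(1.0, 5.0, 10))


class TestGeneralOptimumSolver:
    def test_linear_curve_reproduces_specific_model(self, unit_params, unit_solution):
        n_lin = lambda q: np.asarray(non_informational_optimum(q, unit_params))  # noqa: E731
        sol = solve_equilibrium_general(n_lin, unit_params)
        assert np.max(np.abs(sol.A_star - unit_solution.A_star)) < 1e-8

    def test_convex_optimum_still_separates(self, unit_params):
        sol = solve_equilibrium_general(
            lambda q: 1.0 + 0.5 * q + 0.2 * q**2, unit_params
        )
        assert np.all(sol.E[1:] > 0)
        assert np.all(np.diff(sol.A_star) > 0)

    def test_steeper_optimum_means_less_exaggeration(self, unit_params):
        shallow = solve_equilibrium_general(lambda q: 1.0 + 0.5 * q, unit_params)
        steep = solve_equilibrium_general(lambda q: 1.0 + 3.0 * q, unit_params)
        assert np.all(steep.E[1:] < shallow.E[1:])

    def test_non_monotone_curve_rejected(self, unit_params):
        with pytest.raises(ValueError):
            solve_equilibrium_general(lambda q: np.cos(q), unit_params)


class TestEquilibriumCost:
    def test_zero_at_bottom_and_increasing(self, unit_solution):
        assert equilibrium_cost(0.0, unit_solution) == pytest.approx(0.0, abs=1e-14)
        q = np.linspace(0, 5, 41)
        c = np.asarray(equilibrium_cost(q, unit_solution))
        assert np.all(np.diff(c) > 0)
        assert np.all(c <= 1.0 - np.exp(-0.5) + 1e-12)

    def test_asymptotic_cost_matches_closed_form(self, long_range_solution):
        # E -> lambda sigma / beta = 1, so cost -> 1 - exp(-1/2)
        c_top = float(equilibrium_cost(35.0, long_range_solution))
        assert c_top == pytest.approx(1.0 - np.exp(-0.5), abs=1e-6)


class TestComparativeMonotonicity:
    def test_exaggeration_orders_with_parameters(self):
        base = dict(lambda_pref=1.0, sigma_cost=1.0, beta_slope=1.0)
        q = np.linspace(0.0, 5.0, 201)[1:]
        E0 = np.asarray(exaggeration_implicit(q, ModelParams(**base)))
        up_lam = np.asarray(
            exaggeration_implicit(q, ModelParams(**{**base, "lambda_pref": 2.0}))
        )
        up_sig = np.asarray(
            exaggeration_implicit(q, ModelParams(**{**base, "sigma_cost": 2.0}))
        )
        up_beta = np.asarray(
            exaggeration_implicit(q, ModelParams(**{**base, "beta_slope": 2.0}))
        )
        assert np.all(up_lam > E0)
        assert np.all(up_sig > E0)
        assert np.all(up_beta < E0)

    def test_exaggeration_unbounded_as_slope_vanishes(self):
        # E(q) rises monotonically as beta falls at every fixed q, and the
        # overall exaggeration exceeds any bound once beta is small enough
        # (pointwise it is capped by sqrt(2 lambda sigma (q - q_min)))
        q = 1.0
        E_prev = 0.0
        for beta in (1.0, 0.1, 0.01):
            E = exaggeration_implicit(q, ModelParams(beta_slope=beta, q_max=5.0))
            assert E > E_prev
            E_prev = E
        for target in (5.0, 50.0, 500.0):
            beta = 0.1 / target
            p = ModelParams(beta_slope=beta, q_max=10.0 / beta**2)
            assert exaggeration_implicit(p.q_max, p) > target


class TestAsymptoteHalflife:
    def test_caption_values(self):
        assert asymptote_halflife(ModelParams()) == pytest.approx(
            (1.0, np.log(2.0))
        )
        p = ModelParams(lambda_pref=1.0, sigma_cost=2.0, beta_slope=1.0)
        assert asymptote_halflife(p) == pytest.approx((2.0, 2.0 * np.log(2.0)))

    def test_half_life_scales_inverse_square_of_slope(self):
        h1 = asymptote_halflife(ModelParams(beta_slope=1.0))[1]
        h2 = asymptote_halflife(ModelParams(beta_slope=2.0))[1]
        assert h2 == pytest.approx(h1 / 4.0)
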