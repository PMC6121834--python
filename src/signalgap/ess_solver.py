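"""Separating-equilibrium solver for the signalling game.

At a separating (honest) equilibrium the signaller first-order condition
gives an ODE for the exaggeration E(q) = A*(q) - n(q), the amount by which
the equilibrium trait exceeds its non-informational optimum:

    dE/dq = lambda*sigma/E - n'(q),      E(q_min) = 0.

For the linear optimum n(q) = a_min + beta*(q - q_min) this is
dE/dq = lambda*sigma/E - beta, which starts with infinite slope at q_min,
decelerates monotonically, and approaches the asymptote lambda*sigma/beta
with deficit half-life (lambda*sigma/beta**2) * ln 2.

Two independent routes are provided: numerical integration of the ODE in the
squared variable u = E**2 (whose rate 2*lambda*sigma - 2*beta*sqrt(u) stays
finite at the singular start), and the closed-form implicit solution

    tau = x - 1 - ln x,   x = 1 - beta*E/(lambda*sigma),
    tau = beta**2 * (q - q_min) / (lambda*sigma),

solved by bracketed root finding (equivalently the principal branch of
x = -W(-exp(-(1+tau))) in terms of the Lambert W function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import (
    InferenceRule,
    ModelParams,
    SignallingRule,
    non_informational_optimum,
)

__all__ = [
    "EquilibriumSolution",
    "exaggeration_rhs",
    "exaggeration_implicit",
    "solve_equilibrium",
    "solve_equilibrium_general",
    "equilibrium_cost",
    "asymptote_halflife",
]

#: Relative tolerance below which numerical non-monotonicity of A* aborts.
_MONOTONE_TOL = 1e-9


@dataclass(frozen=True)
class EquilibriumSolution:
    """Tabulated separating ESS.

    Attributes
    ----------
    params : ModelParams
    q_grid : ndarray
        Quality grid, starting at ``params.q_min``.
    A_star : ndarray
        Equilibrium signalling rule A*(q) = n(q) + E(q) on the grid.
    E : ndarray
        Exaggeration (signalling gap) above the non-informational optimum.
    P_star : InferenceRule
        Honest inference rule, the inverse of A* (clamped off-path).
    cost : ndarray
        Proportional fitness reduction 1 - exp(-E**2 / (2 sigma)) paid at
        equilibrium by each quality type.
    signalling : bool
        False for the degenerate cue-only equilibrium (lambda = 0), where
        E is identically zero and A* = n.
    diagnostics : dict
        Solver method, tolerances, residuals.
    """

    params: ModelParams
    q_grid: np.ndarray
    A_star: np.ndarray
    E: np.ndarray
    P_star: InferenceRule
    cost: np.ndarray
    signalling: bool = True
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> np.ndarray:
        return np.asarray(non_informational_optimum(self.q_grid, self.params))

    @property
    def rule(self) -> SignallingRule:
        return SignallingRule(self.q_grid, self.A_star)

    def exaggeration_at(self, q) -> np.ndarray | float:
        out = self.rule(q) - non_informational_optimum(q, self.params)
        return out if np.ndim(out) else float(out)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the solution (q, n, A_star, E, P_star_check, cost)."""
        return pd.DataFrame(
            {
                "q": self.q_grid,
                "n": self.n,
                "A_star": self.A_star,
                "E": self.E,
                "P_star_check": np.asarray(self.P_star(self.A_star)),
                "cost": self.cost,
            }
        )


def exaggeration_rhs(E, params: ModelParams) -> np.ndarray | float:
    """Right-hand side dE/dq = lambda*sigma/E - beta of the exaggeration ODE.

    Diverges to +inf as E -> 0+ (the infinite initial slope of the
    equilibrium rule) and crosses zero at the asymptote E = lambda*sigma/beta.
    """
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("exaggeration E must be nonnegative")
    ls = params.lambda_pref * params.sigma_cost
    with np.errstate(divide="ignore"):
        out = np.where(E > 0, ls / np.where(E > 0, E, 1.0), np.inf) - params.beta_slope
    return out if out.ndim else float(out)


def _solve_x(tau: float) -> float:
    """Solve tau = x - 1 - ln(x) for x in (0, 1] by bracketed root finding."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0.0:
        return 1.0
    if tau > 700.0:  # x underflows; E is the asymptote to machine precision
        return 0.0

    def f(x: float) -> float:
        return x - 1.0 - math.log(x) - tau

    # f(1) = -tau < 0 and f -> +inf as x -> 0+, so [tiny, 1] always brackets.
    return brentq(f, 1e-300, 1.0, xtol=1e-16, rtol=4 * np.finfo(float).eps)


def exaggeration_implicit(q, params: ModelParams) -> np.ndarray | float:
    """Closed-form exaggeration E(q) from the implicit solution of the ODE.

    Exact 0 at q = q_min; approaches lambda*sigma/beta as q grows. Serves as
    an independent oracle for :func:`solve_equilibrium`.
    """
    scalar = np.ndim(q) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < params.q_min - 1e-12):
        raise ValueError("q must be >= q_min")
    if params.lambda_pref == 0.0:
        out = np.zeros_like(q)
        return float(out[0]) if scalar else out
    ls = params.lambda_pref * params.sigma_cost
    beta = params.beta_slope
    tau = beta**2 * np.clip(q - params.q_min, 0.0, None) / ls
    x = np.array([_solve_x(float(t)) for t in tau.ravel()]).reshape(tau.shape)
    E = (ls / beta) * (1.0 - x)
    return float(E[0]) if scalar else E


def _default_grid(params: ModelParams, num: int = 2001) -> np.ndarray:
    return np.linspace(params.q_min, params.q_max, num)


def _package_solution(
    params: ModelParams,
    q_grid: np.ndarray,
    E: np.ndarray,
    signalling: bool,
    diagnostics: dict[str, Any],
    n_values: np.ndarray | None = None,
) -> EquilibriumSolution:
    n = (
        np.asarray(non_informational_optimum(q_grid, params))
        if n_values is None
        else n_values
    )
    A = n + E
    dA = np.diff(A)
    if signalling and np.any(dA <= 0):
        scale = max(abs(A[0]), abs(A[-1]))
        if np.min(dA) < -_MONOTONE_TOL * scale:
            raise RuntimeError(
                "equilibrium rule A* lost strict monotonicity: "
                f"min step {np.min(dA):.3e} on grid of {q_grid.size} points"
            )
        raise RuntimeError(
            "equilibrium rule A* is numerically non-increasing somewhere; "
            "refine the grid or tolerances"
        )
    if signalling:
        # at a separating equilibrium A*'(q) = lambda*sigma/E, so the
        # inverse has exact slope dP/da = E/(lambda*sigma) (0 at a_min)
        ls = params.lambda_pref * params.sigma_cost
        P_star = InferenceRule(A, q_grid, params.q_min, params.q_max, p_derivs=E / ls)
    else:
        # cue equilibrium: A = n is still invertible with slope 1/n'(q)
        P_star = InferenceRule(
            A, q_grid, params.q_min, params.q_max, p_derivs=1.0 / np.gradient(n, q_grid)
        )
    cost = 1.0 - np.exp(-(E**2) / (2.0 * params.sigma_cost))
    return EquilibriumSolution(
        params=params,
        q_grid=q_grid,
        A_star=A,
        E=E,
        P_star=P_star,
        cost=cost,
        signalling=signalling,
        diagnostics=diagnostics,
    )


def solve_equilibrium(
    params: ModelParams,
    q_grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> EquilibriumSolution:
    """Integrate the exaggeration ODE and assemble the separating ESS.

    The singular boundary (infinite dE/dq at E = 0) is handled by
    integrating u = E**2, whose rate 2*lambda*sigma - 2*beta*sqrt(u) is
    finite at u = 0. With lambda = 0 the degenerate cue-only equilibrium
    (E identically 0, A* = n) is returned rather than an error.
    """
    q_grid = _default_grid(params) if q_grid is None else np.asarray(q_grid, float)
    if q_grid.ndim != 1 or q_grid.size < 2 or np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be strictly increasing with >= 2 points")
    if abs(q_grid[0] - params.q_min) > 1e-12 * (1 + abs(params.q_min)):
        raise ValueError("q_grid must start at q_min")

    if params.lambda_pref == 0.0:
        E = np.zeros_like(q_grid)
        return _package_solution(
            params, q_grid, E, signalling=False,
            diagnostics={"method": "degenerate-cue", "note": "lambda = 0"},
        )

    ls = params.lambda_pref * params.sigma_cost
    beta = params.beta_slope

    def rhs(_q: float, u: np.ndarray) -> list[float]:
        return [2.0 * ls - 2.0 * beta * math.sqrt(max(u[0], 0.0))]

    res = solve_ivp(
        rhs,
        (q_grid[0], q_grid[-1]),
        [0.0],
        t_eval=q_grid,
        method="RK45",
        rtol=rtol,
        atol=atol,
    )
    if not res.success:
        raise RuntimeError(f"exaggeration ODE integration failed: {res.message}")
    u = np.clip(res.y[0], 0.0, None)
    E = np.sqrt(u)
    E[0] = 0.0  # boundary condition is exact
    diagnostics = {
        "method": "solve_ivp/RK45 on u = E^2",
        "rtol": rtol,
        "atol": atol,
        "n_steps": int(res.t.size),
        "rhs_evals": int(res.nfev),
        "asymptote": params.asymptote,
        "half_life": params.half_life,
    }
    return _package_solution(params, q_grid, E, True, diagnostics)


def solve_equilibrium_general(
    n_curve: Callable[[np.ndarray], np.ndarray],
    params: ModelParams,
    q_grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> EquilibriumSolution:
    """Separating ESS for an arbitrary strictly increasing optimum n(q).

    Integrates A*'(q) = lambda*sigma / (A*(q) - n(q)) with A*(q_min) =
    n(q_min), again via u = (A* - n)**2. The slope n'(q) is taken by central
    finite differences of ``n_curve``; the asymptote/half-life formulas of
    the linear model do not apply here, but honesty (A* strictly increasing,
    E > 0 above q_min) does whenever n is increasing.
    """
    q_grid = _default_grid(params) if q_grid is None else np.asarray(q_grid, float)
    if q_grid.ndim != 1 or q_grid.size < 2 or np.any(np.diff(q_grid) <= 0):
        raise ValueError("q_grid must be strictly increasing with >= 2 points")
    n_vals = np.asarray(n_curve(q_grid), dtype=float)
    if np.any(np.diff(n_vals) <= 0):
        raise ValueError("n_curve must be strictly increasing on the grid")

    if params.lambda_pref == 0.0:
        E = np.zeros_like(q_grid)
        return _package_solution(
            params, q_grid, E, signalling=False,
            diagnostics={"method": "degenerate-cue", "note": "lambda = 0"},
            n_values=n_vals,
        )

    ls = params.lambda_pref * params.sigma_cost
    h = 1e-6 * (q_grid[-1] - q_grid[0])

    def n_slope(qv: float) -> float:
        lo = max(qv - h, q_grid[0])
        hi = min(qv + h, q_grid[-1])
        return (float(n_curve(np.asarray(hi))) - float(n_curve(np.asarray(lo)))) / (hi - lo)

    def rhs(qv: float, u: np.ndarray) -> list[float]:
        return [2.0 * ls - 2.0 * n_slope(qv) * math.sqrt(max(u[0], 0.0))]

    res = solve_ivp(
        rhs, (q_grid[0], q_grid[-1]), [0.0], t_eval=q_grid,
        method="RK45", rtol=rtol, atol=atol,
    )
    if not res.success:
        raise RuntimeError(f"general exaggeration ODE failed: {res.message}")
    E = np.sqrt(np.clip(res.y[0], 0.0, None))
    E[0] = 0.0
    diagnostics = {
        "method": "solve_ivp/RK45 on u = (A*-n)^2, numeric n'",
        "rtol": rtol,
        "atol": atol,
        "rhs_evals": int(res.nfev),
    }
    return _package_solution(params, q_grid, E, True, diagnostics, n_values=n_vals)


def equilibrium_cost(q, sol: EquilibriumSolution) -> np.ndarray | float:
    """Proportional fitness reduction 1 - exp(-E(q)**2 / (2 sigma)) paid for
    exaggerating the trait beyond its non-informational optimum.

    Zero at q_min, increasing in q, bounded by the cost at the asymptotic
    exaggeration, 1 - exp(-(lambda*sigma/beta)**2 / (2 sigma)).
    """
    E = sol.exaggeration_at(q)
    E = np.clip(np.asarray(E, dtype=float), 0.0, None)
    out = 1.0 - np.exp(-(E**2) / (2.0 * sol.params.sigma_cost))
    return out if out.ndim else float(out)


def asymptote_halflife(params: ModelParams) -> tuple[float, float]:
    """Caption formulas of the linear model: the limiting exaggeration
    lambda*sigma/beta and the deficit half-life (lambda*sigma/beta**2) ln 2."""
    return params.asymptote, params.half_life
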