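"""Parameter sweeps over the separating equilibrium.

The model's comparative statics are its main empirical content: exaggeration
grows with the preference scale lambda and the cost scale sigma, shrinks
with the slope beta of the non-informational optimum, and the maximum
equilibrium cost traces a continuum from effectively cost-free cues (large
beta, or sigma -> 0) to costly handicaps (small beta). This module produces
the corresponding curve families and extracts the asymptote and deficit
half-life from numerical solutions. Everything here is deterministic:
identical configurations reproduce identical tables bit for bit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ess_solver import (
    EquilibriumSolution,
    exaggeration_implicit,
    solve_equilibrium,
)
from .model_core import ModelParams, non_informational_optimum

__all__ = [
    "figure1a_curves",
    "figure1b_curves",
    "cost_continuum",
    "extract_asymptote_halflife",
    "sweep_summary",
]

#: Reference quality range for figure-grade tables (plots are unitless).
FIGURE_PARAMS = dict(a_min=1.0, q_min=0.0, q_max=5.0)


def figure1a_curves(num: int = 501) -> pd.DataFrame:
    """Equilibrium signalling rules A*(q) for lambda = 1, beta = 1 and
    sigma in {1, 2}, next to the straight non-informational optimum n(q).

    Both curves start at n(q_min) and approach parallels of n at heights
    lambda*sigma/beta = 1 and 2; the low-cost (sigma = 2) curve lies
    strictly above the high-cost one for every q > q_min.
    """
    q = np.linspace(FIGURE_PARAMS["q_min"], FIGURE_PARAMS["q_max"], num)
    out = {"q": q}
    p1 = ModelParams(lambda_pref=1.0, sigma_cost=1.0, beta_slope=1.0, **FIGURE_PARAMS)
    out["n"] = np.asarray(non_informational_optimum(q, p1))
    for sigma in (1.0, 2.0):
        p = ModelParams(lambda_pref=1.0, sigma_cost=sigma, beta_slope=1.0, **FIGURE_PARAMS)
        out[f"A_star_sigma_{sigma:g}"] = out["n"] + np.asarray(exaggeration_implicit(q, p))
    return pd.DataFrame(out)


def figure1b_curves(num: int = 501) -> pd.DataFrame:
    """Exaggeration E(q) for lambda = sigma = 1 and beta in {0.5, 1, 2}.

    The three curves all vanish at q_min and order top-to-bottom as beta
    0.5, 1, 2 with asymptotes 2, 1 and 0.5: a shallower cue slope buys
    cheaper mimicry for low-quality signallers and therefore forces more
    exaggeration at equilibrium.
    """
    q = np.linspace(FIGURE_PARAMS["q_min"], FIGURE_PARAMS["q_max"], num)
    out = {"q": q}
    for beta in (0.5, 1.0, 2.0):
        p = ModelParams(lambda_pref=1.0, sigma_cost=1.0, beta_slope=beta, **FIGURE_PARAMS)
        out[f"E_beta_{beta:g}"] = np.asarray(exaggeration_implicit(q, p))
    return pd.DataFrame(out)


def cost_continuum(
    beta_grid: np.ndarray | list[float],
    params_base: ModelParams | None = None,
) -> pd.DataFrame:
    """Maximum equilibrium signalling cost as a function of the cue slope.

    For each beta the equilibrium is solved on the base quality range and
    the largest proportional fitness reduction (attained at q_max, since
    cost increases with quality) is recorded. The resulting curve decreases
    strictly in beta and tends to zero as beta grows — the continuum from
    costly handicaps to effectively cost-free cues.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0:
        raise ValueError("beta grid must be non-empty")
    if np.any(beta_grid <= 0):
        raise ValueError("beta grid must be positive")
    base = params_base or ModelParams(**FIGURE_PARAMS)
    rows = []
    for beta in beta_grid:
        p = base.replace(beta_slope=float(beta))
        E_max = float(exaggeration_implicit(p.q_max, p))
        max_cost = 1.0 - np.exp(-(E_max**2) / (2.0 * p.sigma_cost))
        rows.append({"beta": float(beta), "E_at_q_max": E_max, "max_cost": max_cost})
    return pd.DataFrame(rows)


def extract_asymptote_halflife(
    sol: EquilibriumSolution,
    tau_ref: float = 8.0,
) -> tuple[float, float]:
    """Estimate the asymptote and deficit half-life from a solved rule.

    The asymptote is read off at the top of the grid, which must extend to
    scaled distance tau = beta**2 (q - q_min)/(lambda*sigma) >= 30 so that
    the remaining deficit is negligible. The half-life is the quality
    distance over which the deficit from that asymptote halves, measured
    from the reference point tau = ``tau_ref`` by bracketed root finding on
    the interpolated deficit. (The reference sits in the tail because the
    deficit is only asymptotically exponential; at tau = 8 the residual
    relative bias of the halving distance is ~1e-4.)
    """
    p = sol.params
    ls = p.lambda_pref * p.sigma_cost
    tau_max = p.beta_slope**2 * (sol.q_grid[-1] - p.q_min) / ls
    if tau_max < 30.0:
        raise ValueError(
            f"grid reaches only tau = {tau_max:.2f} < 30; extend q_max to at least "
            f"{p.q_min + 30 * ls / p.beta_slope**2:g} to estimate the asymptote"
        )
    asym_hat = float(sol.E[-1])
    from scipy.interpolate import PchipInterpolator

    E_of_q = PchipInterpolator(sol.q_grid, sol.E)
    q1 = p.q_min + tau_ref * ls / p.beta_slope**2
    d1 = asym_hat - float(E_of_q(q1))
    if d1 <= 0:
        raise ValueError("deficit vanished at the reference point; grid too coarse")

    def f(qv: float) -> float:
        return (asym_hat - float(E_of_q(qv))) - 0.5 * d1

    half_hat = brentq(f, q1, sol.q_grid[-1], xtol=1e-12) - q1
    return asym_hat, float(half_hat)


def sweep_summary(
    lambdas: np.ndarray | list[float],
    sigmas: np.ndarray | list[float],
    betas: np.ndarray | list[float],
    reference_q: float | None = None,
    grid_points: int = 2001,
) -> pd.DataFrame:
    """Full factorial sweep over (lambda, sigma, beta).

    For each combination the equilibrium is solved out to tau = 35 and
    summarised: exaggeration at the reference quality, empirical asymptote
    and half-life (with their closed-form values), and maximum equilibrium
    cost. Degenerate combinations (lambda = 0) are flagged rather than
    dropped.
    """
    rows = []
    for lam in np.asarray(lambdas, dtype=float):
        for sig in np.asarray(sigmas, dtype=float):
            for beta in np.asarray(betas, dtype=float):
                if lam == 0.0:
                    rows.append(
                        {
                            "lambda": lam, "sigma": sig, "beta": beta,
                            "degenerate": True, "E_ref": 0.0, "asymptote": 0.0,
                            "half_life": np.nan, "max_cost": 0.0,
                            "asymptote_formula": 0.0, "half_life_formula": np.nan,
                        }
                    )
                    continue
                ls = lam * sig
                q_max = 35.0 * ls / beta**2
                p = ModelParams(
                    lambda_pref=lam, sigma_cost=sig, beta_slope=beta,
                    a_min=1.0, q_min=0.0, q_max=q_max,
                )
                sol = solve_equilibrium(p, np.linspace(0.0, q_max, grid_points))
                q_ref = reference_q if reference_q is not None else ls / beta**2
                asym, half = extract_asymptote_halflife(sol)
                rows.append(
                    {
                        "lambda": lam, "sigma": sig, "beta": beta,
                        "degenerate": False,
                        "E_ref": float(sol.exaggeration_at(min(q_ref, q_max))),
                        "asymptote": asym,
                        "half_life": half,
                        "max_cost": float(sol.cost.max()),
                        "asymptote_formula": p.asymptote,
                        "half_life_formula": p.half_life,
                    }
                )
    return pd.DataFrame(rows)
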