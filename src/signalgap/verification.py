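"""Numerical certification of evolutionary stability.

A candidate strategy pair (A, P) is an ESS when no signaller type can gain
by deviating to another trait value given the receiver's inference, and no
inference rule lowers the receiver's average loss. Both conditions are
checked here by brute force: a dense grid scan over (quality, deviant trait)
pairs for the signaller side, and a seeded family of bump/shift
perturbations of the inference rule for the receiver side. A finite scan is
a certificate at the stated resolution and tolerance, not a formal proof.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np

from .ess_solver import EquilibriumSolution
from .model_core import (
    LossSpec,
    ModelParams,
    QualityDist,
    non_informational_optimum,
)

__all__ = [
    "DeviationReport",
    "PerturbationReport",
    "SingleCrossingReport",
    "signaller_deviation_scan",
    "receiver_perturbation_check",
    "single_crossing_check",
]

DEFAULT_SEED = 20180524


@dataclass(frozen=True)
class DeviationReport:
    """Outcome of the signaller deviation scan.

    ``max_gain`` is the largest fitness improvement over the equilibrium
    payoff found at any scanned (q, a); the pair passes when it does not
    exceed ``tolerance``.
    """

    max_gain: float
    argmax_q: float
    argmax_a: float
    q_points: int
    a_points: int
    a_range: tuple[float, float]
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_gain <= self.tolerance


def signaller_deviation_scan(
    sol: EquilibriumSolution,
    params: ModelParams | None = None,
    q_points: int = 200,
    a_points: int = 2000,
    a_range: tuple[float, float] | None = None,
    tolerance: float = 1e-6,
) -> DeviationReport:
    """Scan all (quality, deviant-trait) pairs for a profitable deviation.

    For each scanned quality q the gain is
    max_a w(a, P*(a), q) - w(A*(q), P*(A*(q)), q); at an ESS no gain exceeds
    the tolerance. The scan range defaults to
    [0.5*a_min, A*(q_max) + 3*lambda*sigma/beta] so that off-path signals
    (where beliefs clamp to the boundary qualities) are included.
    """
    params = params or sol.params
    A_hi = float(sol.A_star[-1])
    if a_range is None:
        margin = 3.0 * params.asymptote if params.lambda_pref > 0 else 3.0 * params.sigma_cost
        a_range = (0.5 * params.a_min, A_hi + margin)
    if a_range[0] > float(sol.A_star[0]) or a_range[1] < A_hi:
        raise ValueError(
            f"scan range {a_range} does not cover equilibrium signals "
            f"[{sol.A_star[0]}, {A_hi}]"
        )

    q = np.linspace(params.q_min, params.q_max, q_points)
    a = np.linspace(a_range[0], a_range[1], a_points)
    rule = sol.rule
    A_q = np.asarray(rule(q))
    P_eq = np.asarray(sol.P_star(A_q))
    n_q = np.asarray(non_informational_optimum(q, params))
    lam, sig = params.lambda_pref, params.sigma_cost

    # log-fitness along the deviation surface, broadcast (q_points, a_points)
    P_a = np.asarray(sol.P_star(a))
    dev = lam * P_a[None, :] - (a[None, :] - n_q[:, None]) ** 2 / (2.0 * sig)
    eq = lam * P_eq - (A_q - n_q) ** 2 / (2.0 * sig)
    gain = np.exp(dev) - np.exp(eq)[:, None]

    i, j = np.unravel_index(int(np.argmax(gain)), gain.shape)
    return DeviationReport(
        max_gain=float(gain[i, j]),
        argmax_q=float(q[i]),
        argmax_a=float(a[j]),
        q_points=q_points,
        a_points=a_points,
        a_range=(float(a_range[0]), float(a_range[1])),
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class PerturbationReport:
    """Outcome of the receiver-side Monte-Carlo check: the honest rule's
    average loss against every perturbed inference rule tried. A finite
    perturbation family certifies, it does not prove, optimality against
    all inference rules."""

    baseline_loss: float
    min_perturbed_loss: float
    worst_perturbation: dict[str, float]
    n_perturbations: int
    amplitude: float
    seed: int
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.min_perturbed_loss >= self.baseline_loss - self.tolerance


def receiver_perturbation_check(
    sol: EquilibriumSolution,
    G: QualityDist | None = None,
    loss: LossSpec | None = None,
    n_perturbations: int = 100,
    amplitude: float = 0.1,
    seed: int = DEFAULT_SEED,
    tolerance: float = 1e-12,
) -> PerturbationReport:
    """Check that no perturbed inference rule lowers average receiver loss.

    Perturbations are Gaussian bumps at random centres in the signal range
    (random width and signed amplitude up to ``amplitude``) plus the two
    constant shifts +/- amplitude, applied to the honest rule and clipped
    into [q_min, q_max]. Average losses are evaluated by trapezoidal
    quadrature on the solution grid.
    """
    params = sol.params
    G = G or QualityDist.from_params(params)
    loss = loss or LossSpec()
    rng = np.random.default_rng(seed)

    q = sol.q_grid
    A_q = sol.A_star
    w_q = np.asarray(G.pdf(q))
    p_honest = np.asarray(sol.P_star(A_q))

    def avg_loss(p_vals: np.ndarray) -> float:
        return float(np.trapezoid(np.asarray(loss(q, p_vals)) * w_q, q))

    baseline = avg_loss(p_honest)
    a_lo, a_hi = float(A_q[0]), float(A_q[-1])
    span = a_hi - a_lo

    perturbations: list[dict[str, float]] = []
    for _ in range(n_perturbations):
        perturbations.append(
            {
                "kind": 0.0,  # bump
                "centre": float(rng.uniform(a_lo - 0.1 * span, a_hi + 0.1 * span)),
                "width": float(rng.uniform(0.02, 0.3) * span),
                "eps": float(rng.uniform(-amplitude, amplitude)),
            }
        )
    for shift in (amplitude, -amplitude):
        perturbations.append({"kind": 1.0, "centre": 0.0, "width": 1.0, "eps": shift})

    min_loss = np.inf
    worst: dict[str, float] = {}
    for pert in perturbations:
        if pert["kind"] == 0.0:
            bump = pert["eps"] * np.exp(
                -((A_q - pert["centre"]) ** 2) / (2.0 * pert["width"] ** 2)
            )
        else:
            bump = np.full_like(A_q, pert["eps"])
        p_vals = np.clip(p_honest + bump, params.q_min, params.q_max)
        val = avg_loss(p_vals)
        if val < min_loss:
            min_loss = val
            worst = dict(pert)
    return PerturbationReport(
        baseline_loss=baseline,
        min_perturbed_loss=float(min_loss),
        worst_perturbation=worst,
        n_perturbations=n_perturbations,
        amplitude=amplitude,
        seed=seed,
        tolerance=tolerance,
    )


@dataclass(frozen=True)
class SingleCrossingReport:
    """Grid check of the Spence-Mirrlees single-crossing condition: the
    marginal rate of substitution -w_a/w_p between trait and perceived
    quality must be strictly decreasing in true quality at every (a, q)."""

    passed: bool
    min_decrement: float
    max_decrement: float
    q_points: int
    a_points: int
    details: dict[str, Any] = field(default_factory=dict)


def single_crossing_check(
    params: ModelParams,
    q_points: int = 101,
    a_points: int = 101,
    n_curve: Callable[[np.ndarray], np.ndarray] | None = None,
    strictness: float = 1e-12,
) -> SingleCrossingReport:
    """Verify single crossing on a grid from finite differences of fitness.

    For the built-in bell-shaped fitness the MRS is (a - n(q))/(lambda*sigma),
    whose decrement in q is n'(q)/(lambda*sigma) -- strictly positive exactly
    when the non-informational optimum increases with quality. A flat
    ``n_curve`` therefore degenerates (fails strictness): the differential
    cost of faking a high-quality trait disappears.
    """
    if params.lambda_pref <= 0 or params.sigma_cost <= 0:
        raise ValueError("single-crossing check requires lambda, sigma > 0")
    if n_curve is None:
        n_curve = lambda qv: np.asarray(non_informational_optimum(qv, params))  # noqa: E731

    q = np.linspace(params.q_min, params.q_max, q_points)
    a = np.linspace(0.5 * params.a_min, float(np.max(n_curve(q))) + 3.0 * params.sigma_cost, a_points)
    n_q = np.asarray(n_curve(q), dtype=float)
    # MRS(a, q) = -w_a / w_p = (a - n(q)) / (lambda * sigma)
    mrs = (a[None, :] - n_q[:, None]) / (params.lambda_pref * params.sigma_cost)
    dec = -np.diff(mrs, axis=0)  # decrement along increasing q
    min_dec = float(np.min(dec))
    max_dec = float(np.max(dec))
    passed = min_dec > strictness
    if not passed:
        warnings.warn(
            "single-crossing degenerates: MRS not strictly decreasing in q",
            stacklevel=2,
        )
    return SingleCrossingReport(
        passed=passed,
        min_decrement=min_dec,
        max_decrement=max_dec,
        q_points=q_points,
        a_points=a_points,
        details={"lambda": params.lambda_pref, "sigma": params.sigma_cost},
    )
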