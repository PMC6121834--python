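"""Primitives of the cue-to-handicap signalling game.

Signallers (e.g. males) of hidden quality ``q`` carry a trait ``a`` whose
naturally selected, non-informational optimum ``n(q)`` increases with quality.
Receivers (e.g. females) infer quality ``p = P(a)`` from the trait alone.
Signaller fitness rewards being perceived as high quality but penalises
deviation of the trait from its non-informational optimum:

    w(a, p, q) = exp(lambda * p) * exp(-(a - n(q))**2 / (2 * sigma))

Receivers pay a loss ``D(q, p)`` that grows with the discrepancy between true
and inferred quality, averaged over the quality distribution ``G``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate
from scipy.interpolate import CubicHermiteSpline, PchipInterpolator

__all__ = [
    "ModelParams",
    "LossSpec",
    "QualityDist",
    "SignallingRule",
    "InferenceRule",
    "non_informational_optimum",
    "male_fitness",
    "receiver_loss",
    "average_receiver_loss",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the signalling game.

    Parameters
    ----------
    lambda_pref : float
        Scale of the receiver-preference impact on signaller fitness
        (dimensionless, >= 0). ``0`` removes any benefit of being perceived
        as high quality, collapsing the signal back to a pure cue.
    sigma_cost : float
        Scale of the cost of deviating from the non-informational optimum
        (signal-units**2, > 0). Smaller values make deviation costlier.
    beta_slope : float
        Slope of the non-informational optimum in quality (> 0). Steep
        slopes make faking a high-quality trait expensive for low-quality
        signallers.
    a_min : float
        Trait value of the lowest-quality type at its non-informational
        optimum (signal-units, > 0).
    q_min, q_max : float
        Bounds of the quality interval (0 <= q_min < q_max).
    """

    lambda_pref: float = 1.0
    sigma_cost: float = 1.0
    beta_slope: float = 1.0
    a_min: float = 1.0
    q_min: float = 0.0
    q_max: float = 5.0

    def __post_init__(self) -> None:
        if not self.q_min < self.q_max:
            raise ValueError(f"q_min must be < q_max, got [{self.q_min}, {self.q_max}]")
        if self.q_min < 0:
            raise ValueError("qualities must be nonnegative, got q_min < 0")
        if self.a_min <= 0:
            raise ValueError("a_min must be positive")
        if self.sigma_cost <= 0:
            raise ValueError("sigma_cost must be positive")
        if self.beta_slope <= 0:
            raise ValueError("beta_slope must be positive")
        if self.lambda_pref < 0:
            raise ValueError("lambda_pref must be nonnegative")

    @property
    def asymptote(self) -> float:
        """Limiting exaggeration lambda*sigma/beta of the separating ESS."""
        return self.lambda_pref * self.sigma_cost / self.beta_slope

    @property
    def half_life(self) -> float:
        """Quality distance (lambda*sigma/beta**2) ln 2 over which the
        exaggeration's deficit from its asymptote halves (large q)."""
        return self.lambda_pref * self.sigma_cost / self.beta_slope**2 * np.log(2.0)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def _check_quality(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        tol = 1e-12 * (1.0 + abs(self.q_max))
        if np.any(q < self.q_min - tol) or np.any(q > self.q_max + tol):
            raise ValueError(
                f"quality outside [{self.q_min}, {self.q_max}]: "
                f"range [{q.min()}, {q.max()}]"
            )
        return np.clip(q, self.q_min, self.q_max)


def non_informational_optimum(q, params: ModelParams) -> np.ndarray | float:
    """Naturally selected trait value n(q) = a_min + beta*(q - q_min).

    This is the trait value favoured in the absence of any signalling
    benefit; it is strictly increasing in quality, which is what lets the
    trait function as a cue before any exaggeration evolves.
    """
    q = params._check_quality(q)
    out = params.a_min + params.beta_slope * (q - params.q_min)
    return out if out.ndim else float(out)


def male_fitness(a, p, q, params: ModelParams) -> np.ndarray | float:
    """Signaller fitness w(a, p, q) = exp(lambda*p - (a - n(q))**2/(2 sigma)).

    The first factor is the benefit of being perceived as quality ``p``;
    the second is the bell-shaped survival/function cost of carrying a trait
    away from its non-informational optimum. The product is maximised over
    ``a`` at ``a = n(q)`` with value ``exp(lambda * p)``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("trait value a must be positive")
    p = np.asarray(p, dtype=float)
    n = non_informational_optimum(q, params)
    logw = params.lambda_pref * p - (a - n) ** 2 / (2.0 * params.sigma_cost)
    out = np.exp(logw)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LossSpec:
    """Receiver loss family D(q, p).

    The default is symmetric squared error. ``over_weight``/``under_weight``
    allow an asymmetric variant penalising overestimation (p > q) and
    underestimation (p < q) differently; both must be positive so that
    D(q, q) = 0 is the strict pointwise minimum.
    """

    form: str = "squared"
    over_weight: float = 1.0
    under_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.form != "squared":
            raise ValueError(f"unknown loss form {self.form!r}")
        if self.over_weight <= 0 or self.under_weight <= 0:
            raise ValueError("loss weights must be positive")

    def __call__(self, q, p) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        p = np.asarray(p, dtype=float)
        w = np.where(p >= q, self.over_weight, self.under_weight)
        out = w * (p - q) ** 2
        return out if out.ndim else float(out)


def receiver_loss(q, p, loss: LossSpec | None = None) -> np.ndarray | float:
    """Loss D(q, p) a receiver pays for inferring quality p when truth is q."""
    return (loss or LossSpec())(q, p)


@dataclass(frozen=True)
class QualityDist:
    """Distribution G(q) of signaller quality, with full support on
    [q_min, q_max]. Only the uniform family is built in; the equilibrium
    signalling rule does not depend on G, which enters only through the
    receiver's average loss."""

    q_min: float = 0.0
    q_max: float = 5.0
    form: str = "uniform"

    def __post_init__(self) -> None:
        if self.form != "uniform":
            raise ValueError(f"unknown quality distribution {self.form!r}")
        if not self.q_min < self.q_max:
            raise ValueError("q_min must be < q_max")

    @classmethod
    def from_params(cls, params: ModelParams) -> "QualityDist":
        return cls(q_min=params.q_min, q_max=params.q_max)

    def pdf(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        inside = (q >= self.q_min) & (q <= self.q_max)
        out = np.where(inside, 1.0 / (self.q_max - self.q_min), 0.0)
        return out if out.ndim else float(out)

    def cdf(self, q) -> np.ndarray | float:
        q = np.asarray(q, dtype=float)
        out = np.clip((q - self.q_min) / (self.q_max - self.q_min), 0.0, 1.0)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SignallingRule:
    """Signaller strategy a = A(q), tabulated on a quality grid and
    interpolated with a monotone (PCHIP) cubic between points."""

    q_grid: np.ndarray
    a_values: np.ndarray
    _interp: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        q = np.asarray(self.q_grid, dtype=float)
        a = np.asarray(self.a_values, dtype=float)
        if q.ndim != 1 or q.shape != a.shape or q.size < 2:
            raise ValueError("q_grid and a_values must be matching 1-d arrays")
        if np.any(np.diff(q) <= 0):
            raise ValueError("q_grid must be strictly increasing")
        if np.any(a <= 0):
            raise ValueError("signal values must be positive")
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "a_values", a)
        object.__setattr__(self, "_interp", PchipInterpolator(q, a, extrapolate=True))

    def __call__(self, q) -> np.ndarray | float:
        out = self._interp(np.asarray(q, dtype=float))
        return out if out.ndim else float(out)

    @property
    def is_increasing(self) -> bool:
        return bool(np.all(np.diff(self.a_values) > 0))


@dataclass(frozen=True)
class InferenceRule:
    """Receiver strategy p = P(a) on a signal grid.

    Out-of-range signals clamp to the nearest tabulated signal (so off-path
    beliefs at equilibrium are the boundary qualities), and inferred quality
    is always clipped into [q_min, q_max]. A single-node grid encodes a
    constant (fully pooled) inference.
    """

    a_grid: np.ndarray
    p_values: np.ndarray
    q_min: float
    q_max: float
    p_derivs: np.ndarray | None = None
    _interp: PchipInterpolator | CubicHermiteSpline | None = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a_grid, dtype=float))
        p = np.atleast_1d(np.asarray(self.p_values, dtype=float))
        if a.shape != p.shape or a.ndim != 1:
            raise ValueError("a_grid and p_values must be matching 1-d arrays")
        if np.any(np.diff(a) <= 0):
            raise ValueError("a_grid must be strictly increasing")
        object.__setattr__(self, "a_grid", a)
        object.__setattr__(self, "p_values", p)
        if a.size < 2:
            interp = None
        elif self.p_derivs is not None:
            # exact slopes dP/da, when known (e.g. E/(lambda*sigma) at a
            # separating equilibrium), beat shape-estimated ones near the
            # singular start where dP/da -> 0
            d = np.asarray(self.p_derivs, dtype=float)
            interp = CubicHermiteSpline(a, p, d, extrapolate=False)
        else:
            interp = PchipInterpolator(a, p, extrapolate=False)
        object.__setattr__(self, "_interp", interp)

    def __call__(self, a) -> np.ndarray | float:
        a = np.asarray(a, dtype=float)
        a_cl = np.clip(a, self.a_grid[0], self.a_grid[-1])
        if self._interp is None:
            out = np.full_like(np.asarray(a_cl, dtype=float), self.p_values[0])
        else:
            out = self._interp(a_cl)
        out = np.clip(out, self.q_min, self.q_max)
        return out if out.ndim else float(out)


def average_receiver_loss(
    A: SignallingRule | Callable,
    P: InferenceRule | Callable,
    G: QualityDist,
    loss: LossSpec | None = None,
) -> float:
    """Population-average receiver loss  E_G[ D(q, P(A(q))) ].

    Computed by adaptive quadrature of the composed discrepancy against the
    quality density. Zero exactly when inference is honest (P(A(q)) = q)
    G-almost everywhere.
    """
    loss = loss or LossSpec()

    def integrand(q: float) -> float:
        return float(loss(q, P(A(q)))) * float(G.pdf(q))

    value, abserr, info, *rest = integrate.quad(
        integrand, G.q_min, G.q_max, limit=200, full_output=True
    )
    if rest:  # message present => ier != 0, quadrature did not converge
        raise RuntimeError(
            f"average-loss quadrature failed: {rest[0]} (estimate {value}, abserr {abserr})"
        )
    return float(value)
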