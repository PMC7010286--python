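"""Three-compartment model of serum soluble DNAM-1 after allo-HSCT.

Total serum sDNAM-1 is modelled as the sum of three sources:

* ``x1`` — transient, alloreactive donor lymphocytes: gamma-kernel
  production with first-order clearance,
  ``dx1/dt = lam * t**(k-1) * exp(-t/theta) / (Gamma(k) * theta**k) - mu*x1``.
* ``x2`` — persistent, non-alloreactive donor lymphocytes: logistic growth
  with effective rate ``r - mu`` and carrying capacity ``N``,
  ``dx2/dt = (r - mu) * x2 * (1 - x2/N)``.
* ``x3`` — residual recipient-derived sDNAM-1: exponential decay,
  ``dx3/dt = -mu * x3``.

All concentrations are in pM, time in days since transplantation.  x2 and
x3 have exact closed forms; x1 has an exact solution in terms of the
regularized lower incomplete gamma function / Kummer's confluent
hypergeometric function, so no numerical integration is needed anywhere in
the forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
from scipy import special

__all__ = [
    "ModelParameters",
    "Trajectory",
    "gamma_production_rate",
    "transient_solution",
    "persistent_solution",
    "residual_solution",
    "solve_trajectories",
]


@dataclass(frozen=True)
class ModelParameters:
    """The eight quantities parameterizing the three-source model.

    Parameters
    ----------
    lam : float
        Total mass delivered by the transient gamma kernel (pM).  ``lam = 0``
        is the two-source restriction (no transient compartment).
    k : float
        Gamma-kernel shape (dimensionless), > 0.
    theta : float
        Gamma-kernel scale (days), > 0.
    mu : float
        First-order clearance rate (per day), > 0; shared by x1, x3 and the
        effective logistic rate ``r - mu``.
    r : float
        Intrinsic growth rate of the persistent source (per day), >= 0.
    N : float
        Carrying capacity of the persistent source (pM), > 0.
    x2_0 : float
        Persistent-source concentration at day 0 (pM), in [0, N].
    x3_0 : float
        Residual recipient-derived concentration at day 0 (pM), >= 0.
    """

    lam: float
    k: float
    theta: float
    mu: float
    r: float
    N: float
    x2_0: float
    x3_0: float

    def __post_init__(self) -> None:
        if not (self.lam >= 0):
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if not (self.k > 0):
            raise ValueError(f"k must be > 0, got {self.k}")
        if not (self.theta > 0):
            raise ValueError(f"theta must be > 0, got {self.theta}")
        if not (self.mu > 0):
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if not (self.r >= 0):
            raise ValueError(f"r must be >= 0, got {self.r}")
        if not (self.N > 0):
            raise ValueError(f"N must be > 0, got {self.N}")
        if not (0 <= self.x2_0 <= self.N):
            raise ValueError(
                f"x2_0 must lie in [0, N]={[0, self.N]}, got {self.x2_0}"
            )
        if not (self.x3_0 >= 0):
            raise ValueError(f"x3_0 must be >= 0, got {self.x3_0}")

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form, suitable for JSON/CSV serialization."""
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        names = [f.name for f in fields(cls)]
        return cls(**{k: float(d[k]) for k in names})


@dataclass(frozen=True)
class Trajectory:
    """Model components evaluated on a time grid (all pM)."""

    times: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    total: np.ndarray


def _check_times(t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be >= 0 (days since transplantation)")
    return t


def gamma_production_rate(t, params: ModelParameters) -> np.ndarray:
    """Transient production rate ``lam * gamma_pdf(t; k, scale=theta)`` in pM/day.

    Integrates to ``lam`` over [0, inf).  At t=0 the rate is ``lam/theta``
    for k=1, 0 for k>1 and +inf for k<1 (integrable singularity).
    """
    t = _check_times(t)
    k, theta = params.k, params.theta
    with np.errstate(divide="ignore"):
        log_pdf = (
            special.xlogy(k - 1.0, t) - t / theta
            - special.gammaln(k) - k * np.log(theta)
        )
        rate = params.lam * np.exp(log_pdf)
    if k < 1.0:
        rate = np.where(t == 0.0, np.inf if params.lam > 0 else 0.0, rate)
    elif k == 1.0:
        rate = np.where(t == 0.0, params.lam / theta, rate)
    return rate


def transient_solution(t, params: ModelParameters) -> np.ndarray:
    """Exact x1(t): gamma-kernel production convolved with exp(-mu t) clearance.

    With a = 1/theta - mu the convolution integral reduces to

    * a > 0:  ``lam * exp(-mu t) * P(k, a t) / (a theta)**k`` where P is the
      regularized lower incomplete gamma function;
    * a <= 0: ``lam * t**k * exp(-t/theta) * 1F1(1; k+1; a t) / (Gamma(k) theta**k k)``,
      the Kummer-transformed branch whose 1F1 argument is <= 0 (no overflow).

    x1(0) = 0 (no donor-derived material before graft infusion) and
    x1(t) -> 0 at asymptotic rate mu.
    """
    t = _check_times(t)
    lam, k, theta, mu = params.lam, params.k, params.theta, params.mu
    out = np.zeros_like(t)
    if lam == 0.0:
        return out
    pos = t > 0
    tp = t[pos]
    a = 1.0 / theta - mu
    # the gammainc branch loses accuracy as a*t -> 0; switch a little early
    if a * theta > 1e-8:
        out[pos] = lam * np.exp(-mu * tp) * special.gammainc(k, a * tp) / (a * theta) ** k
    else:
        log_c = (
            k * np.log(tp) - tp / theta
            - special.gammaln(k) - k * np.log(theta) - np.log(k)
        )
        out[pos] = lam * np.exp(log_c) * special.hyp1f1(1.0, k + 1.0, a * tp)
    return np.maximum(out, 0.0)


def persistent_solution(t, params: ModelParameters) -> np.ndarray:
    """Closed-form logistic solution for the persistent source x2.

    ``x2(t) = N / (1 + ((N - x2_0)/x2_0) * exp(-(r - mu) t))`` for x2_0 > 0;
    identically 0 when x2_0 = 0 (absorbing state).
    """
    t = _check_times(t)
    N, x2_0 = params.N, params.x2_0
    if x2_0 == 0.0:
        return np.zeros_like(t)
    rho = params.r - params.mu
    c = (N - x2_0) / x2_0
    return N / (1.0 + c * np.exp(-rho * t))


def residual_solution(t, params: ModelParameters) -> np.ndarray:
    """Exponentially decaying recipient-derived residual: ``x3_0 * exp(-mu t)``."""
    t = _check_times(t)
    return params.x3_0 * np.exp(-params.mu * t)


def solve_trajectories(params: ModelParameters, times) -> Trajectory:
    """Evaluate all three components and their sum on a sorted grid of days >= 0."""
    t = _check_times(times)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    x1 = transient_solution(t, params)
    x2 = persistent_solution(t, params)
    x3 = residual_solution(t, params)
    return Trajectory(times=t, x1=x1, x2=x2, x3=x3, total=x1 + x2 + x3)


def total_concentration(t, params: ModelParameters) -> np.ndarray:
    """Total serum sDNAM-1 x1 + x2 + x3 at times t (pM)."""
    return (
        transient_solution(t, params)
        + persistent_solution(t, params)
        + residual_solution(t, params)
    )
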