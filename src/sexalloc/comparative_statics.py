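"""Comparative statics of the optimal male share under environmental pressure.

Along an optimal allocation strategy the growth factor lambda(x, mu(x)) is
stationary in x (d lambda / dx = 0).  Differentiating
lambda = P + M (1 - mu) E(x) C(E(x)) and solving for the strategy's slope
gives the governing ordinary differential equation

    d mu / dx = (1 - mu) * (E'(x) / E(x)) * (1 + delta(E(x))),

where delta = E C'(E)/C(E) is the signed resource elasticity of offspring
survival.  Because E' < 0 and 1 - mu > 0 in the interior, the sign of the
response is -sign(1 + delta): elasticities below -1 (r-type strategies)
raise the male share as pressure grows, elasticities above -1 (K-type)
lower it, and delta = -1 leaves the sex ratio untouched.

For a constant elasticity (power-family survival) the ODE integrates in
closed form: (1 - mu(x)) * E(x)**(1 + delta) is conserved, i.e.

    mu(x) = 1 - (1 - mu0) * (E(x0) / E(x))**(1 + delta),

which also shows lambda is exactly constant along the solution.  The
fixed-step RK4 integrator below is checked against this closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import bisect, brentq

from .exceptions import BracketingError, DomainError, UnsupportedFamilyError
from .model_core import LifeHistoryModel

__all__ = [
    "SexAllocationTrajectory",
    "RegimeLabel",
    "mu_prime",
    "integrate_trajectory",
    "closed_form_trajectory",
    "stationarity_residual",
    "classify_regime",
    "critical_elasticity",
]

#: bisection tolerance (in x) for locating a boundary exit of mu
BOUNDARY_XTOL = 1e-9


@dataclass
class SexAllocationTrajectory:
    """Gridded solution mu(x) of the optimal-allocation ODE.

    Attributes
    ----------
    xs, mus, dmudx, lambdas
        Pressure grid (strictly increasing), male share, its slope, and the
        growth factor at every reported point.
    exit_x, exit_reason
        If the trajectory hit mu = 0 (``hit_zero``), mu = 1 (``hit_one``) or
        the end of the allocation curve's domain (``domain_end``) before the
        requested span finished, it is truncated there; ``completed``
        otherwise, with ``exit_x`` None.
    """

    xs: np.ndarray
    mus: np.ndarray
    dmudx: np.ndarray
    lambdas: np.ndarray
    exit_x: float | None = None
    exit_reason: str = "completed"

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.mus = np.asarray(self.mus, dtype=float)
        self.dmudx = np.asarray(self.dmudx, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if len(self.xs) and np.any(np.diff(self.xs) <= 0):
            raise DomainError("trajectory grid must be strictly increasing")
        if np.any(self.mus < -1e-12) or np.any(self.mus > 1 + 1e-12):
            raise DomainError("male share left [0, 1] in a trajectory")

    def __len__(self) -> int:
        return len(self.xs)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x": self.xs,
                "mu": self.mus,
                "dmudx": self.dmudx,
                "lambda_fitness": self.lambdas,
            }
        )

    def mu_at(self, x: float) -> float:
        """Linear interpolation of mu on the stored grid."""
        if not (self.xs[0] <= x <= self.xs[-1]):
            raise DomainError(f"x = {x} outside the trajectory grid")
        return float(np.interp(x, self.xs, self.mus))


@dataclass(frozen=True)
class RegimeLabel:
    """Qualitative response regime, determined solely by sign(1 + delta).

    ``regime`` is ``r_increasing`` (delta < -1: pressure raises the male
    share), ``boundary_constant`` (delta = -1) or ``K_decreasing``
    (delta > -1).  ``sub`` grades the magnitude the way price elasticity of
    demand is graded: ``elastic`` (|delta| > 1), ``unitary`` (|delta| = 1),
    ``inelastic`` (0 < |delta| < 1), ``zero`` (delta = 0); ``none`` is used
    where no sub-grade applies (e.g. interval-based classification).
    """

    regime: str
    sub: str = "none"


def classify_regime(delta: float) -> RegimeLabel:
    """Classify a signed elasticity into the r/K response regimes."""
    if not math.isfinite(delta):
        raise DomainError(f"elasticity must be finite, got {delta}")
    if delta < -1.0:
        regime = "r_increasing"
    elif delta == -1.0:
        regime = "boundary_constant"
    else:
        regime = "K_decreasing"
    if delta == 0.0:
        sub = "zero"
    elif abs(delta) == 1.0:
        sub = "unitary"
    elif abs(delta) > 1.0:
        sub = "elastic"
    else:
        sub = "inelastic"
    return RegimeLabel(regime=regime, sub=sub)


def mu_prime(model: LifeHistoryModel, x: float, mu: float) -> float:
    """Right-hand side (1-mu)*(E'/E)*(1+delta) of the optimal-share ODE.

    Returns 0 at the clamped boundaries mu = 0 and mu = 1; raises outside
    [0, 1].  Does not evaluate C itself, so it is well defined even where a
    survival scale would push C out of (0, 1].
    """
    if not 0.0 <= mu <= 1.0:
        raise DomainError(f"male share mu must lie in [0, 1], got {mu}")
    if mu == 0.0 or mu == 1.0:
        return 0.0
    return _rhs(model, x, mu)


def _rhs(model: LifeHistoryModel, x: float, mu: float) -> float:
    # smooth continuation of the ODE right-hand side; no mu clamping so the
    # RK4 stages stay consistent near a boundary
    E = model.allocation.value(x)
    dlogE = model.allocation.log_derivative(x)
    delta = model.survival.elasticity(E)
    return (1.0 - mu) * dlogE * (1.0 + delta)


def _rk4_step(model: LifeHistoryModel, x: float, mu: float, h: float) -> float:
    k1 = _rhs(model, x, mu)
    k2 = _rhs(model, x + 0.5 * h, mu + 0.5 * h * k1)
    k3 = _rhs(model, x + 0.5 * h, mu + 0.5 * h * k2)
    k4 = _rhs(model, x + h, mu + h * k3)
    return mu + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _locate_exit(
    model: LifeHistoryModel, x: float, mu: float, h: float, bound: float
) -> float:
    """Bisect the step length at which mu(x + h*) crosses ``bound``."""
    lo, hi = 0.0, h
    while hi - lo > BOUNDARY_XTOL:
        mid = 0.5 * (lo + hi)
        mu_mid = _rk4_step(model, x, mu, mid)
        if (mu_mid - bound) * (mu - bound) > 0:  # same side as the start
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def integrate_trajectory(
    model: LifeHistoryModel,
    mu0: float,
    x_span: tuple[float, float],
    step: float = 1e-3,
) -> SexAllocationTrajectory:
    """Fixed-step RK4 solution of d mu/dx = mu_prime over ``x_span``.

    The step is fixed so runs are bit-reproducible for identical
    configurations; the final partial step lands exactly on the span end.
    If mu crosses 0 or 1 the crossing is located by bisection to within
    1e-9 in x and the trajectory is truncated there with an exit event.
    """
    if step <= 0:
        raise DomainError(f"step must be positive, got {step}")
    x0, x1 = float(x_span[0]), float(x_span[1])
    if x1 <= x0:
        raise DomainError(f"x_span must be increasing, got {x_span}")
    if not 0.0 < mu0 < 1.0:
        raise DomainError(f"initial male share mu0 must lie in (0, 1), got {mu0}")

    exit_reason = "completed"
    domain_end = model.allocation.domain_end
    if x1 >= domain_end:
        x1 = domain_end * (1.0 - 1e-9)
        exit_reason = "domain_end"

    xs = [x0]
    mus = [float(mu0)]
    n_full = int(math.floor((x1 - x0) / step * (1.0 + 1e-12)))
    exit_x: float | None = x1 if exit_reason == "domain_end" else None

    x, mu = x0, float(mu0)
    i = 0
    while x < x1 - 1e-15:
        h = min(step, x1 - x) if i >= n_full else step
        mu_new = _rk4_step(model, x, mu, h)
        if mu_new <= 0.0 or mu_new >= 1.0:
            bound = 0.0 if mu_new <= 0.0 else 1.0
            h_exit = _locate_exit(model, x, mu, h, bound)
            x = x + h_exit
            mu = bound
            xs.append(x)
            mus.append(mu)
            exit_x = x
            exit_reason = "hit_zero" if bound == 0.0 else "hit_one"
            break
        x = x0 + (i + 1) * step if i + 1 <= n_full else x1
        if x > x1:
            x = x1
        mu = mu_new
        xs.append(x)
        mus.append(mu)
        i += 1

    xs_arr = np.asarray(xs)
    mus_arr = np.clip(np.asarray(mus), 0.0, 1.0)
    dmudx = np.array([mu_prime(model, xi, mi) for xi, mi in zip(xs_arr, mus_arr)])
    lambdas = np.asarray(model.fitness(xs_arr, mus_arr))
    return SexAllocationTrajectory(
        xs=xs_arr,
        mus=mus_arr,
        dmudx=dmudx,
        lambdas=lambdas,
        exit_x=exit_x,
        exit_reason=exit_reason,
    )


def closed_form_trajectory(
    model: LifeHistoryModel, mu0: float, xs: Sequence[float]
) -> SexAllocationTrajectory:
    """Exact trajectory for constant elasticity (power-family survival).

    Uses the conservation law (1 - mu) E**(1+delta) = const anchored at the
    first grid point; truncates with an exactly-located exit event when the
    boundary mu in {0, 1} is reached inside the grid.
    """
    if model.survival.family != "power":
        raise UnsupportedFamilyError(
            "closed-form trajectory requires the constant-elasticity "
            f"(power) survival family, got {model.survival.family!r}"
        )
    xs_arr = np.asarray(xs, dtype=float)
    if xs_arr.ndim != 1 or len(xs_arr) < 1 or np.any(np.diff(xs_arr) <= 0):
        raise DomainError("xs must be a strictly increasing grid")
    if not 0.0 < mu0 < 1.0:
        raise DomainError(f"initial male share mu0 must lie in (0, 1), got {mu0}")

    delta = float(model.survival.delta)
    E = np.asarray(model.allocation.value(xs_arr))
    E_anchor = float(E[0])

    def mu_of(x: float | np.ndarray) -> np.ndarray:
        ratio = E_anchor / np.asarray(model.allocation.value(x))
        return 1.0 - (1.0 - mu0) * ratio ** (1.0 + delta)

    mus = mu_of(xs_arr)
    exit_x: float | None = None
    exit_reason = "completed"
    out = np.where((mus <= 0.0) | (mus >= 1.0))[0]
    if out.size:
        i = int(out[0])
        bound = 0.0 if mus[i] <= 0.0 else 1.0
        if i == 0:
            raise DomainError("trajectory starts outside (0, 1)")
        if mus[i] == bound:
            exit_x = float(xs_arr[i])
        else:
            exit_x = float(
                brentq(
                    lambda x: float(mu_of(x)) - bound,
                    xs_arr[i - 1],
                    xs_arr[i],
                    xtol=1e-14,
                    rtol=8.881784197001252e-16,
                )
            )
        exit_reason = "hit_zero" if bound == 0.0 else "hit_one"
        xs_arr = np.append(xs_arr[:i], exit_x)
        mus = np.append(mus[:i], bound)

    mus = np.clip(mus, 0.0, 1.0)
    dmudx = np.array([mu_prime(model, xi, mi) for xi, mi in zip(xs_arr, mus)])
    lambdas = np.asarray(model.fitness(xs_arr, mus))
    return SexAllocationTrajectory(
        xs=xs_arr,
        mus=mus,
        dmudx=dmudx,
        lambdas=lambdas,
        exit_x=exit_x,
        exit_reason=exit_reason,
    )


def stationarity_residual(
    model: LifeHistoryModel, traj: SexAllocationTrajectory
) -> float:
    """Max relative deviation of lambda from its value at the grid start.

    Zero (to integration error) along any exact solution of the ODE, since
    d lambda/dx = 0 is precisely the condition the ODE encodes.
    """
    if len(traj) < 2:
        raise DomainError("trajectory must have at least 2 points")
    lam = np.asarray(model.fitness(traj.xs, traj.mus))
    return float(np.max(np.abs(lam - lam[0])) / lam[0])


def critical_elasticity(
    model_factory: Callable[[float], LifeHistoryModel],
    x_eval: float,
    mu_eval: float,
    delta_interval: tuple[float, float],
    xtol: float = 1e-9,
) -> float:
    """Bisect the elasticity at which d mu/dx changes sign at (x_eval, mu_eval).

    For any valid model this is the zero of the (1 + delta) factor, i.e. -1,
    independently of the allocation curve and of mu_eval.
    """
    lo, hi = delta_interval
    if not lo < hi:
        raise DomainError(f"delta_interval must be increasing, got {delta_interval}")

    def f(delta: float) -> float:
        return mu_prime(model_factory(delta), x_eval, mu_eval)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0:
        return float(lo)
    if f_hi == 0.0:
        return float(hi)
    if f_lo * f_hi > 0:
        raise BracketingError(
            f"d mu/dx does not change sign on delta in [{lo}, {hi}]"
        )
    return float(bisect(f, lo, hi, xtol=xtol))
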