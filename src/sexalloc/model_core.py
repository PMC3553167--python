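"""Life-history primitives for sex allocation under limited resources.

The model describes an organism that funds its own survival first and
reproduction with whatever resource remains.  Environmental selection
pressure ``x`` (dimensionless, nonnegative) diverts resource away from
reproduction, so the reproductive share ``E(x)`` decreases monotonically
to zero.  A fraction ``mu`` of the reproductive share goes to the male
function and ``1 - mu`` to females; female output is linear in its
resource input, with ``M`` the maximum female offspring count when the
whole reproductive share goes to females.  Offspring survive to adulthood
with probability ``C(E)`` and adults survive each step with constant
probability ``P``, giving the per-step growth factor (fitness)

    lambda(x, mu) = P + M * (1 - mu) * E(x) * C(E(x)).

The central statistic is the resource elasticity of offspring survival,

    delta(E) = E * C'(E) / C(E),

the percentage change in offspring survival per one-percent change in
reproductive allocation.  The elasticity is kept *signed*: the regime
boundary of the comparative statics sits at delta = -1 on a signed axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from .exceptions import DomainError, ValidationError

ArrayLike = Union[float, np.ndarray]

ALLOCATION_FAMILIES = ("exponential", "rational", "linear_clamped")
SURVIVAL_FAMILIES = ("power", "saturating", "constant")

#: relative step used by the finite-difference elasticity path
FD_RELATIVE_STEP = 1e-6


def _as_array(x: ArrayLike) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def _maybe_scalar(arr: np.ndarray, scalar: bool) -> ArrayLike:
    return float(arr) if scalar else arr


@dataclass(frozen=True)
class AllocationCurve:
    """Monotone-decreasing reproductive share E(x) of total resource.

    Parameters
    ----------
    family
        One of ``"exponential"`` (E0 * exp(-k x), valid on [0, inf)),
        ``"rational"`` (E0 / (1 + k x), valid on [0, inf)) or
        ``"linear_clamped"`` (E0 * (1 - k x), valid on [0, 1/k)).
    E0
        Reproductive share at zero pressure, in (0, 1].
    k
        Decay rate per unit pressure, > 0.
    """

    family: str = "exponential"
    E0: float = 0.8
    k: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ALLOCATION_FAMILIES:
            raise DomainError(
                f"unknown allocation family {self.family!r}; "
                f"expected one of {ALLOCATION_FAMILIES}"
            )
        if not (0.0 < self.E0 <= 1.0):
            raise DomainError(f"E0 must lie in (0, 1], got {self.E0}")
        if not (self.k > 0.0 and math.isfinite(self.k)):
            raise DomainError(f"k must be positive and finite, got {self.k}")

    @property
    def domain_end(self) -> float:
        """Right end of the valid pressure domain (exclusive for linear_clamped)."""
        return 1.0 / self.k if self.family == "linear_clamped" else math.inf

    def _check_domain(self, x: np.ndarray) -> None:
        if np.any(x < 0):
            raise DomainError("pressure x must be nonnegative")
        if np.any(x >= self.domain_end):
            raise DomainError(
                f"pressure x beyond the valid domain [0, {self.domain_end}) "
                f"of the {self.family} allocation curve"
            )

    def value(self, x: ArrayLike) -> ArrayLike:
        arr, scalar = _as_array(x)
        self._check_domain(arr)
        if self.family == "exponential":
            out = self.E0 * np.exp(-self.k * arr)
        elif self.family == "rational":
            out = self.E0 / (1.0 + self.k * arr)
        else:  # linear_clamped
            out = self.E0 * (1.0 - self.k * arr)
        return _maybe_scalar(out, scalar)

    def derivative(self, x: ArrayLike) -> ArrayLike:
        arr, scalar = _as_array(x)
        self._check_domain(arr)
        if self.family == "exponential":
            out = -self.k * self.E0 * np.exp(-self.k * arr)
        elif self.family == "rational":
            out = -self.E0 * self.k / (1.0 + self.k * arr) ** 2
        else:
            out = np.full_like(arr, -self.E0 * self.k)
        return _maybe_scalar(out, scalar)

    def log_derivative(self, x: ArrayLike) -> ArrayLike:
        """d log E / dx = E'(x)/E(x); always negative on the valid domain."""
        arr, scalar = _as_array(x)
        self._check_domain(arr)
        if self.family == "exponential":
            out = np.full_like(arr, -self.k)
        elif self.family == "rational":
            out = -self.k / (1.0 + self.k * arr)
        else:
            out = -self.k / (1.0 - self.k * arr)
        return _maybe_scalar(out, scalar)


def allocation_at(curve: AllocationCurve, x: ArrayLike) -> tuple[ArrayLike, ArrayLike]:
    """Reproductive share and its pressure derivative, both analytic."""
    return curve.value(x), curve.derivative(x)


@dataclass(frozen=True)
class OffspringSurvivalCurve:
    """Offspring survival probability C(E) as a function of reproductive share.

    Families
    --------
    power
        ``C(E) = c0 * E**delta`` — constant signed elasticity ``delta``.
    saturating
        ``C(E) = 1 - exp(-a * E)`` — elasticity in (0, 1) for all E > 0.
    constant
        ``C(E) = c0`` — elasticity 0.
    """

    family: str = "power"
    c0: float = 0.5
    delta: float | None = None
    a: float | None = None

    def __post_init__(self) -> None:
        if self.family not in SURVIVAL_FAMILIES:
            raise DomainError(
                f"unknown survival family {self.family!r}; "
                f"expected one of {SURVIVAL_FAMILIES}"
            )
        if self.family in ("power", "constant") and not (
            self.c0 > 0.0 and math.isfinite(self.c0)
        ):
            raise DomainError(f"c0 must be positive and finite, got {self.c0}")
        if self.family == "power":
            if self.delta is None or not math.isfinite(self.delta):
                raise DomainError("power family requires a finite elasticity delta")
        if self.family == "saturating":
            if self.a is None or not (self.a > 0.0 and math.isfinite(self.a)):
                raise DomainError("saturating family requires a rate a > 0")

    def _check_share(self, E: np.ndarray) -> None:
        if np.any(E <= 0):
            raise DomainError("reproductive share E must be positive")

    def value(self, E: ArrayLike) -> ArrayLike:
        arr, scalar = _as_array(E)
        self._check_share(arr)
        if self.family == "power":
            out = self.c0 * arr ** self.delta
        elif self.family == "saturating":
            out = 1.0 - np.exp(-self.a * arr)
        else:
            out = np.full_like(arr, self.c0)
        return _maybe_scalar(out, scalar)

    def derivative(self, E: ArrayLike) -> ArrayLike:
        arr, scalar = _as_array(E)
        self._check_share(arr)
        if self.family == "power":
            out = self.c0 * self.delta * arr ** (self.delta - 1.0)
        elif self.family == "saturating":
            out = self.a * np.exp(-self.a * arr)
        else:
            out = np.zeros_like(arr)
        return _maybe_scalar(out, scalar)

    def elasticity(self, E: ArrayLike, method: str = "analytic") -> ArrayLike:
        """Signed point elasticity E*C'(E)/C(E).

        ``method="analytic"`` uses the closed form of the family;
        ``method="finite-difference"`` uses a central difference with
        relative step 1e-6 * max(E, 1), available for any family.
        """
        if method == "analytic":
            arr, scalar = _as_array(E)
            self._check_share(arr)
            if self.family == "power":
                out = np.full_like(arr, self.delta)
            elif self.family == "saturating":
                aE = self.a * arr
                out = aE * np.exp(-aE) / (1.0 - np.exp(-aE))
            else:
                out = np.zeros_like(arr)
            return _maybe_scalar(out, scalar)
        if method == "finite-difference":
            arr, scalar = _as_array(E)
            self._check_share(arr)
            h = FD_RELATIVE_STEP * np.maximum(arr, 1.0)
            if np.any(arr - h <= 0):
                raise DomainError(
                    "E too close to the domain boundary for a central difference"
                )
            c = self.value(arr)
            dc = (self.value(arr + h) - self.value(arr - h)) / (2.0 * h)
            return _maybe_scalar(np.asarray(arr * dc / c), scalar)
        raise DomainError(f"unknown elasticity method {method!r}")


def survival_at(curve: OffspringSurvivalCurve, E: ArrayLike) -> tuple[ArrayLike, ArrayLike]:
    """Survival probability and its derivative in E; validates C in (0, 1]."""
    C = curve.value(E)
    if np.any(np.asarray(C) <= 0) or np.any(np.asarray(C) > 1.0):
        raise ValidationError(
            f"survival probability C(E) = {C} outside (0, 1] for E = {E}"
        )
    return C, curve.derivative(E)


def point_elasticity(
    curve: OffspringSurvivalCurve, E: ArrayLike, method: str = "analytic"
) -> ArrayLike:
    """Signed resource elasticity of offspring survival at share E."""
    return curve.elasticity(E, method=method)


@dataclass(frozen=True)
class LifeHistoryModel:
    """Full parameterization: adult survival, fecundity scale, and both curves.

    ``P`` is constant in pressure because survival is funded first; ``M`` is
    the maximum female offspring count.  The constructor only type-checks
    ``P`` and ``M`` so that :func:`validate_model` can *diagnose* out-of-range
    values; the curves validate their own parameters on construction.
    """

    P: float = 0.5
    M: float = 10.0
    allocation: AllocationCurve = field(default_factory=AllocationCurve)
    survival: OffspringSurvivalCurve = field(default_factory=OffspringSurvivalCurve)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.P) and math.isfinite(self.M)):
            raise DomainError("P and M must be finite")

    def female_output(self, x: ArrayLike, mu: ArrayLike) -> ArrayLike:
        """Expected female offspring M*(1-mu)*E(x); linear in resource input."""
        mu_arr = np.asarray(mu, dtype=float)
        if np.any(mu_arr < 0) or np.any(mu_arr > 1):
            raise DomainError(f"male share mu must lie in [0, 1], got {mu}")
        out = self.M * (1.0 - mu_arr) * np.asarray(self.allocation.value(x))
        return float(out) if out.ndim == 0 else out

    def fitness(self, x: ArrayLike, mu: ArrayLike) -> ArrayLike:
        """Growth factor lambda = P + female_output * C(E(x))."""
        E = self.allocation.value(x)
        C, _ = survival_at(self.survival, E)
        mu_arr = np.asarray(mu, dtype=float)
        if np.any(mu_arr < 0) or np.any(mu_arr > 1):
            raise DomainError(f"male share mu must lie in [0, 1], got {mu}")
        lam = self.P + self.M * (1.0 - mu_arr) * np.asarray(E) * np.asarray(C)
        return float(lam) if np.ndim(lam) == 0 else lam

    def elasticity_at(self, x: ArrayLike) -> ArrayLike:
        """Survival elasticity evaluated along the allocation curve."""
        return self.survival.elasticity(self.allocation.value(x))


def female_output(model: LifeHistoryModel, x: ArrayLike, mu: ArrayLike) -> ArrayLike:
    return model.female_output(x, mu)


def fitness(model: LifeHistoryModel, x: ArrayLike, mu: ArrayLike) -> ArrayLike:
    return model.fitness(x, mu)


@dataclass(frozen=True)
class PopulationState:
    """Expected organism count at an integer time step (deterministic model)."""

    N: float
    T: int

    def __post_init__(self) -> None:
        if self.N < 0:
            raise DomainError("population size N must be nonnegative")
        if self.T < 0 or int(self.T) != self.T:
            raise DomainError("time index T must be a nonnegative integer")


def project_population(
    model: LifeHistoryModel, x: float, mu: float, N0: float, T: int
) -> list[PopulationState]:
    """Geometric projection N(t+1) = lambda * N(t) with lambda = fitness(x, mu)."""
    if N0 < 0:
        raise DomainError("initial population N0 must be nonnegative")
    if T < 0 or int(T) != T:
        raise DomainError("number of steps T must be a nonnegative integer")
    lam = model.fitness(x, mu)
    states = [PopulationState(N=float(N0), T=0)]
    for t in range(1, int(T) + 1):
        states.append(PopulationState(N=states[-1].N * lam, T=t))
    return states


@dataclass
class ValidationReport:
    """Diagnostics from :func:`validate_model`; empty ``violations`` iff valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthy when valid, so `if report:` reads naturally
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "model valid"
        return "; ".join(self.violations)


def validate_model(
    model: LifeHistoryModel,
    x_domain: tuple[float, float] = (0.0, 3.0),
    n_samples: int = 201,
) -> ValidationReport:
    """Check the model's biological invariants over a pressure interval.

    Flags: adult survival P outside [0, 1); nonpositive fecundity scale M;
    a non-monotone or nonpositive allocation curve; and offspring survival
    C(E(x)) leaving (0, 1] anywhere on the induced share range.
    """
    report = ValidationReport()
    if not (0.0 <= model.P < 1.0):
        report.violations.append(
            f"adult survival P = {model.P} outside the probability bound [0, 1)"
        )
    if not model.M > 0:
        report.violations.append(f"fecundity scale M = {model.M} must be positive")

    lo, hi = x_domain
    if lo < 0 or hi <= lo:
        report.violations.append(f"invalid pressure domain {x_domain}")
        return report
    hi = min(hi, model.allocation.domain_end * (1.0 - 1e-12))
    xs = np.linspace(lo, hi, n_samples)
    E = np.asarray(model.allocation.value(xs))
    if np.any(E <= 0):
        report.violations.append("allocation E(x) not strictly positive on the domain")
    if np.any(np.diff(E) >= 0):
        report.violations.append("allocation E(x) not strictly decreasing on the domain")
    if np.all(E > 0):
        C = np.asarray(model.survival.value(E))
        if np.any(C <= 0) or np.any(C > 1.0):
            worst = float(C.max()) if np.any(C > 1.0) else float(C.min())
            report.violations.append(
                f"offspring survival C(E(x)) leaves (0, 1] on the domain "
                f"(worst value {worst:.6g})"
            )
    return report
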