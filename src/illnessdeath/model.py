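"""Transition-intensity model for the three-state illness-death process.

States are coded 1 (healthy), 2 (history of illness) and 3 (death); death is
absorbing and recovery (2 -> 1) is excluded.  Transition intensities are
log-linear in age and baseline covariates,

    q_1j(A)      = exp( Z(A) . beta_1j ),          j in {2, 3}
    q_23(A | W)  = exp( Z(A) . beta_23 + gamma (A - W) ),

where ``Z(A) = (1, A, X_1, ..., X_r)`` and ``W`` is the (possibly unobserved)
age at illness onset, so ``A - W`` is the sojourn time in state 2.  With
``Z(A) = (1, A)`` the 1->j baselines are Gompertz hazards in age, and q_23 is
a Gompertz hazard in sojourn time with rate ``alpha_23 = exp(b0 + bA W)`` and
shape ``xi_23 = gamma + bA``; a negative shape makes the sojourn distribution
improper, so a fraction ``exp(alpha_23 / xi_23)`` of ill individuals never
dies from the modelled hazard.

Age is the time scale throughout; ages are in years and rates per year.
Likelihood evaluation holds intensities piecewise constant on a grid of
subintervals of resolution ``h``, evaluating each intensity at the left
subinterval limit; subintervals are closed-open ``[left, right)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LINPRED_CAP",
    "HEALTHY",
    "ILL",
    "DEAD",
    "CoefficientSet",
    "CovariateProfile",
    "AgeGrid",
    "intensity_1j",
    "intensity_23",
    "derive_gompertz_23",
    "eventual_transition_fraction",
    "build_grid",
    "stay_probability",
]

# Cap on the log-intensity before exponentiation: keeps the optimiser from
# producing non-finite likelihood values during line searches.
LINPRED_CAP = 50.0

# State codes.
HEALTHY, ILL, DEAD = 1, 2, 3

#: tolerance used when snapping interval lengths to multiples of h
_GRID_EPS = 1e-9


def _capped_exp(x):
    """exp with the linear predictor capped at +/- LINPRED_CAP."""
    return np.exp(np.clip(x, -LINPRED_CAP, LINPRED_CAP))


@dataclass
class CoefficientSet:
    """All regression parameters of the three-transition model.

    Each beta vector is laid out as (intercept, age slope, extra covariate
    slopes...) over one shared covariate layout; ``gamma`` is the per-year
    effect of the sojourn time A - W on the 2->3 log-intensity.
    """

    beta_12: np.ndarray
    beta_13: np.ndarray
    beta_23: np.ndarray
    gamma: float
    covariate_names: tuple = ()

    def __post_init__(self):
        self.beta_12 = np.asarray(self.beta_12, dtype=float)
        self.beta_13 = np.asarray(self.beta_13, dtype=float)
        self.beta_23 = np.asarray(self.beta_23, dtype=float)
        self.gamma = float(self.gamma)
        self.covariate_names = tuple(self.covariate_names)
        n = 2 + len(self.covariate_names)
        for name in ("beta_12", "beta_13", "beta_23"):
            b = getattr(self, name)
            if b.shape != (n,):
                raise ValueError(
                    f"{name} must have length {n} "
                    f"(intercept, age{''.join(', ' + c for c in self.covariate_names)})"
                )
            if not np.all(np.isfinite(b)):
                raise ValueError(f"{name} contains non-finite entries")
        if not np.isfinite(self.gamma):
            raise ValueError("gamma is not finite")

    @property
    def n_params(self) -> int:
        return 3 * (2 + len(self.covariate_names)) + 1

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.beta_12, self.beta_13, self.beta_23, [self.gamma]])

    @classmethod
    def from_vector(cls, v: np.ndarray, covariate_names: Sequence[str] = ()) -> "CoefficientSet":
        v = np.asarray(v, dtype=float)
        p = 2 + len(covariate_names)
        if v.shape != (3 * p + 1,):
            raise ValueError(f"expected vector of length {3 * p + 1}, got {v.shape}")
        return cls(v[:p], v[p:2 * p], v[2 * p:3 * p], v[3 * p], tuple(covariate_names))

    def param_names(self) -> list:
        names = []
        for ij in ("12", "13", "23"):
            names.append(f"beta_0.{ij}")
            names.append(f"beta_A.{ij}")
            names.extend(f"beta_{c}.{ij}" for c in self.covariate_names)
        # regroup in the (intercepts, age, covariates, gamma) table layout
        return names + ["gamma"]


@dataclass
class CovariateProfile:
    """The values-at-age contract Z(A) = (1, A, X_1, ..., X_r).

    ``values`` holds the baseline covariate values (everything past the
    intercept and age components).  A carry-forward ``schedule`` of
    (age, values) pairs may be supplied for covariates updated at visits;
    between visit ages Z(A) is then piecewise constant, holding the last
    observed values.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    schedule: tuple = ()  # ((age, values), ...) sorted by age

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.schedule = tuple(
            (float(a), np.asarray(v, dtype=float).ravel()) for a, v in self.schedule
        )
        if any(
            b[0] <= a[0] for a, b in zip(self.schedule, self.schedule[1:])
        ):
            raise ValueError("schedule ages must be strictly increasing")

    @property
    def n_extra(self) -> int:
        return len(self.values)

    def values_at(self, age: float) -> np.ndarray:
        """Covariate values in force at ``age`` (carry-forward rule)."""
        out = self.values
        for a, v in self.schedule:
            if a <= age:
                out = v
            else:
                break
        return out

    def z(self, age: float) -> np.ndarray:
        """The regression vector Z(age)."""
        return np.concatenate([[1.0, float(age)], self.values_at(age)])


def intensity_1j(theta: CoefficientSet, profile: CovariateProfile, A: float, j: int) -> float:
    """Transition intensity out of the healthy state, q_1j(A) = exp(Z(A).beta_1j)."""
    if j == 2:
        beta = theta.beta_12
    elif j == 3:
        beta = theta.beta_13
    else:
        raise ValueError(f"target state must be 2 or 3, got {j}")
    lp = float(profile.z(A) @ beta)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite linear predictor: invalid parameters")
    return float(_capped_exp(lp))


def intensity_23(theta: CoefficientSet, profile: CovariateProfile, A: float, W: float) -> float:
    """Illness-to-death intensity q_23(A | W) = exp(Z(A).beta_23 + gamma (A - W)).

    ``W`` is the onset age; A >= W is required since the sojourn A - W must be
    non-negative.
    """
    if A < W:
        raise ValueError(f"age A={A} precedes onset age W={W}")
    lp = float(profile.z(A) @ theta.beta_23) + theta.gamma * (A - W)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite linear predictor: invalid parameters")
    return float(_capped_exp(lp))


def derive_gompertz_23(theta: CoefficientSet, W: float,
                       profile: CovariateProfile | None = None) -> tuple:
    """Gompertz (rate, shape) of the sojourn-time hazard out of state 2.

    Writing q_23 as a function of sojourn time T2 = A - W at fixed onset age W
    gives q_23 = alpha_23 * exp(xi_23 * T2) with

        alpha_23 = exp(beta_0.23 + beta_A.23 * W + covariate terms at onset)
        xi_23    = gamma + beta_A.23

    Extra covariates fold into alpha_23 at their values at onset.
    """
    if profile is None:
        profile = CovariateProfile(np.zeros(len(theta.beta_23) - 2))
    alpha = float(np.exp(profile.z(W) @ theta.beta_23))
    xi = theta.gamma + float(theta.beta_23[1])
    return alpha, xi


def eventual_transition_fraction(alpha: float, xi: float) -> float:
    """Limiting fraction of ill individuals who eventually die of the modelled hazard.

    Under a Gompertz sojourn hazard alpha * exp(xi * t), survival tends to
    exp(alpha / xi) as t -> infinity when xi < 0 (improper distribution), so
    the fraction ever making the 2->3 transition is 1 - exp(alpha / xi); for
    xi >= 0 the distribution is proper and the fraction is 1.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if xi >= 0:
        return 1.0
    return 1.0 - float(np.exp(alpha / xi))


@dataclass(frozen=True)
class AgeGrid:
    """A [A_L, A_U] interval split into subintervals of resolution h.

    Starting from A_L the interval is split into as many subintervals of
    length h as fit; any remainder becomes a final shorter subinterval.
    Intensities are evaluated at each subinterval's left limit.
    """

    A_L: float
    A_U: float
    h: float
    lefts: np.ndarray
    lengths: np.ndarray

    @property
    def K(self) -> int:
        return len(self.lefts)

    @property
    def rights(self) -> np.ndarray:
        return self.lefts + self.lengths


def build_grid(A_L: float, A_U: float, h: float) -> AgeGrid:
    """Split [A_L, A_U] at resolution h, left-anchored at A_L."""
    if not h > 0:
        raise ValueError("resolution h must be positive")
    if not A_U > A_L:
        raise ValueError(f"empty age interval [{A_L}, {A_U}]")
    span = A_U - A_L
    n_full = int(np.floor(span / h + _GRID_EPS))
    rem = span - n_full * h
    if rem <= _GRID_EPS * max(1.0, abs(A_U)):
        rem = 0.0
    lefts = A_L + h * np.arange(n_full, dtype=float)
    lengths = np.full(n_full, h, dtype=float)
    if rem > 0.0:
        lefts = np.append(lefts, A_L + n_full * h)
        lengths = np.append(lengths, rem)
    elif n_full > 0:
        # make the union land exactly on A_U
        lengths[-1] = A_U - lefts[-1]
    return AgeGrid(float(A_L), float(A_U), float(h), lefts, lengths)


def stay_probability(escape_rates: np.ndarray, grid: AgeGrid) -> float:
    """Probability of remaining in a state across the grid's age interval.

    With a piecewise-constant escape rate lambda_k on subinterval k, the stay
    time in each subinterval is exponential, so the overall stay probability
    is the product exp(-sum_k lambda_k * len_k).
    """
    rates = np.asarray(escape_rates, dtype=float)
    if rates.shape != grid.lefts.shape:
        raise ValueError("need one escape rate per subinterval")
    if np.any(rates < 0):
        raise ValueError("escape rates must be non-negative")
    return float(np.exp(-np.sum(rates * grid.lengths)))
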