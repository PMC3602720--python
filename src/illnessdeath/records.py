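"""Individual panel records and follow-up pattern classification.

A record is one subject's longitudinal panel: baseline age, visit ages with
their observed states (1 healthy, 2 history of illness), and a terminal event
(exact death age, or the right-censoring age).  The onset age W of the
illness is never observed directly: it is interval-censored between the last
healthy visit (A_1N) and the first ill visit (A_20), or left-censored before
baseline when the subject enters the study already ill.

Records fall into six mutually exclusive follow-up patterns:

    A: healthy at baseline, illness observed at a visit, died
    B: healthy at baseline, illness observed at a visit, right censored
    C: healthy at every visit, died (illness possibly missed)
    D: healthy at every visit, right censored (illness possibly missed)
    E: ill at baseline (onset left-censored), died
    F: ill at baseline (onset left-censored), right censored
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import HEALTHY, ILL, CovariateProfile

__all__ = ["IndividualRecord", "PATTERNS", "classify_pattern"]

PATTERNS = ("A", "B", "C", "D", "E", "F")


@dataclass
class IndividualRecord:
    """One subject's panel data.

    visits: increasing (age, state) pairs with state in {1, 2}; the first
    visit is at the baseline age A_b.  ``death_age`` is exact when present;
    otherwise the subject is right censored at ``censor_age``.  Covariates
    are baseline values matching a CoefficientSet's covariate layout.
    """

    id: str
    visits: Sequence  # [(age, state), ...]
    death_age: Optional[float] = None
    censor_age: Optional[float] = None
    covariates: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self):
        self.visits = [(float(a), int(s)) for a, s in self.visits]
        self.covariates = np.asarray(self.covariates, dtype=float).ravel()
        if not self.visits:
            raise ValueError(f"record {self.id}: no visits")
        ages = [a for a, _ in self.visits]
        states = [s for _, s in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(f"record {self.id}: visit ages not strictly increasing")
        if any(s not in (HEALTHY, ILL) for s in states):
            raise ValueError(f"record {self.id}: visit states must be 1 or 2 "
                             "(death is recorded via death_age)")
        if any(b < a for a, b in zip(states, states[1:])):
            raise ValueError(f"record {self.id}: recovery (2 -> 1) observed")
        if (self.death_age is None) == (self.censor_age is None):
            raise ValueError(f"record {self.id}: exactly one of death_age / "
                             "censor_age is required")
        if self.end_age < ages[-1] - 1e-12:
            raise ValueError(f"record {self.id}: terminal age precedes last visit")

    # -- derived anchors ---------------------------------------------------
    @property
    def baseline_age(self) -> float:
        return self.visits[0][0]

    @property
    def baseline_state(self) -> int:
        return self.visits[0][1]

    @property
    def end_age(self) -> float:
        """A_N: age at the end of follow-up (death or censoring)."""
        return self.death_age if self.death_age is not None else self.censor_age

    @property
    def died(self) -> bool:
        return self.death_age is not None

    @property
    def last_healthy_age(self) -> Optional[float]:
        """A_1N: age at the last visit observed in state 1."""
        ages = [a for a, s in self.visits if s == HEALTHY]
        return ages[-1] if ages else None

    @property
    def first_ill_age(self) -> Optional[float]:
        """A_20: age at the first visit observed in state 2."""
        ages = [a for a, s in self.visits if s == ILL]
        return ages[0] if ages else None

    def profile(self) -> CovariateProfile:
        return CovariateProfile(self.covariates)

    @property
    def pattern(self) -> str:
        return classify_pattern(self)


def classify_pattern(record: IndividualRecord) -> str:
    """Assign one of the six follow-up patterns A-F to a record."""
    if record.baseline_state == ILL:
        return "E" if record.died else "F"
    if record.first_ill_age is not None:
        return "A" if record.died else "B"
    return "C" if record.died else "D"
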