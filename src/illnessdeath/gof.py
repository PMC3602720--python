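"""Microsimulation goodness-of-fit: model-implied survival and prevalence.

With time-varying covariates (age, sojourn time) there is no simple closed
form for model-implied survival curves, so fit is assessed by simulation:
clone the observed baseline (same subjects, ages, covariates, baseline
states and, for subjects ill at baseline, imputed sojourns), simulate each
clone forward under the fitted coefficients with the study's visit and
censoring design, and compare observed Kaplan-Meier survival and state
prevalence with the envelope of the simulated replicates.

Observed state-1 prevalence is biased upward by interval censoring (subjects
are seen in state 2 later than they enter it); state-3 prevalence is not,
because death ages are exact.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .model import CoefficientSet
from .records import IndividualRecord
from .simulate import ScenarioConfig, apply_observation_scheme, \
    simulate_trajectory

__all__ = ["microsimulate_fitted", "km_curve", "prevalence_by_age"]


def microsimulate_fitted(dataset: Sequence[IndividualRecord],
                         theta_hat: CoefficientSet,
                         W_hat: Optional[Dict[str, float]],
                         R: int,
                         rng: np.random.Generator,
                         followup: float = 12.0,
                         visit_spacing: float = 2.0,
                         h: float = 0.25) -> List[List[IndividualRecord]]:
    """R simulated datasets cloned from the observed baseline.

    Every replicate contains one simulated trajectory per observed subject,
    started at the subject's baseline age in the subject's baseline state
    (ill subjects keep their imputed onset age from ``W_hat``), observed
    under the panel design.  Clones dying before any follow-up elapses are
    retained with their exact death age.
    """
    config = ScenarioConfig(A_0=0.0, baseline_mean=0.0, baseline_sd=1.0,
                            theta=theta_hat, baseline_lower=-np.inf,
                            n_pool=1, n_keep=1, followup=followup,
                            visit_spacing=visit_spacing, h=h)
    out = []
    for r in range(R):
        replicate = []
        for rec in dataset:
            A_b = rec.baseline_age
            ill = rec.baseline_state == 2
            if ill:
                if W_hat is None or rec.id not in W_hat:
                    raise ValueError(f"no imputed onset age for ill subject {rec.id}")
                onset = W_hat[rec.id]
            else:
                onset = None
            traj = simulate_trajectory(
                theta_hat, rec.profile(), A_b, A_b + followup, h, rng,
                start_state=2 if ill else 1, onset_age=onset)
            replicate.append(apply_observation_scheme(
                traj, A_b, config, id=rec.id, covariates=rec.covariates))
        out.append(replicate)
    return out


def km_curve(records: Sequence[IndividualRecord],
             origin: str = "baseline",
             ci: bool = True) -> pd.DataFrame:
    """Kaplan-Meier survival from baseline age (product-limit estimator).

    Time is follow-up time A_N - A_b; death is the event, right censoring
    otherwise.  Returns a step function as a tidy frame (time, survival and,
    optionally, Greenwood 95% limits).
    """
    if origin != "baseline":
        raise ValueError("only the baseline origin is supported")
    if len(records) == 0:
        return pd.DataFrame(columns=["time", "survival", "lower", "upper"])
    durations = np.array([r.end_age - r.baseline_age for r in records])
    events = np.array([r.died for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(dtype=float),
        "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
    })
    if ci:
        band = kmf.confidence_interval_
        out["lower"] = band.iloc[:, 0].to_numpy()
        out["upper"] = band.iloc[:, 1].to_numpy()
    return out


def prevalence_by_age(records: Sequence[IndividualRecord],
                      ages: np.ndarray) -> pd.DataFrame:
    """Observed state-occupancy proportions at each grid age.

    At age a the risk set holds subjects with baseline at or before a who
    are not yet right censored; each is counted in the state last observed
    by a (state 3 from the exact death age onwards).  Proportions sum to 1
    at every age with a non-empty risk set.
    """
    ages = np.asarray(ages, dtype=float)
    A_b = np.array([r.baseline_age for r in records])
    end = np.array([r.end_age for r in records])
    death = np.array([r.death_age if r.died else np.inf for r in records])
    visit_ages = [np.array([a for a, _ in r.visits]) for r in records]
    visit_states = [np.array([s for _, s in r.visits]) for r in records]
    rows = []
    for a in ages:
        at_risk = (A_b <= a) & ((death <= a) | (end >= a))
        n = int(at_risk.sum())
        counts = {1: 0, 2: 0, 3: 0}
        for i in np.flatnonzero(at_risk):
            if death[i] <= a:
                counts[3] += 1
            else:
                seen = visit_states[i][visit_ages[i] <= a]
                counts[seen[-1]] += 1
        if n:
            rows.append((a, counts[1] / n, counts[2] / n, counts[3] / n, n))
        else:
            rows.append((a, np.nan, np.nan, np.nan, 0))
    return pd.DataFrame(rows, columns=["age", "state1", "state2", "state3",
                                       "n_at_risk"])
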