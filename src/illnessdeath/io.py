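"""Panel-data readers and writers.

Dialect: comma-separated UTF-8 text with header ``id,age,state,death`` plus
one column per baseline covariate.  Ages are decimal years; states are coded
1 (healthy), 2 (history of illness), 3 (death).  Rows with state 1/2 are
visits (death = 0); a death is one final row with state 3 and death = 1 and
the exact death age.  Right-censored subjects simply end at their last
visit, so the censoring age is the last visit age.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import IndividualRecord

__all__ = ["read_panel", "write_panel"]

_FIXED = ("id", "age", "state", "death")


def read_panel(path) -> Tuple[List[IndividualRecord], Tuple[str, ...]]:
    """Read and validate a longitudinal panel file.

    Returns the validated records and the covariate column names.  Malformed
    subjects are reported together with their first offending line number
    (1-based, counting the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in _FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    cov_names = tuple(c for c in df.columns if c not in _FIXED)
    df["_line"] = np.arange(2, len(df) + 2)
    records, errors = [], []
    for sid, g in df.groupby("id", sort=False):
        line0 = int(g["_line"].iloc[0])
        try:
            records.append(_build_record(str(sid), g, cov_names))
        except ValueError as e:
            errors.append(f"line {line0}: {e}")
    if errors:
        raise ValueError(f"{path}: invalid panel data:\n" + "\n".join(errors))
    return records, cov_names


def _build_record(sid: str, g: pd.DataFrame, cov_names) -> IndividualRecord:
    ages = g["age"].to_numpy(dtype=float)
    states = g["state"].to_numpy(dtype=int)
    death_flags = g["death"].to_numpy(dtype=int)
    if np.any((states == 3) != (death_flags == 1)):
        raise ValueError(f"id {sid}: state 3 and death flag disagree")
    if np.any(states[:-1] == 3):
        raise ValueError(f"id {sid}: death row must be the final row")
    cov = g[list(cov_names)].to_numpy(dtype=float) if cov_names else \
        np.zeros((len(g), 0))
    if len(g) > 1 and not np.allclose(cov, cov[0]):
        raise ValueError(f"id {sid}: covariates must be constant within subject")
    died = states[-1] == 3
    visits = list(zip(ages[:-1] if died else ages,
                      states[:-1] if died else states))
    if not visits:
        raise ValueError(f"id {sid}: no visit rows before the death row")
    # IndividualRecord enforces the remaining invariants (monotone ages,
    # no recovery, terminal age ordering) and reports them per id
    return IndividualRecord(
        id=sid, visits=visits,
        death_age=float(ages[-1]) if died else None,
        censor_age=None if died else float(ages[-1]),
        covariates=cov[0],
    )


def write_panel(records: Sequence[IndividualRecord], path,
                covariate_names: Sequence[str] = ()) -> None:
    """Write records in the panel dialect (inverse of read_panel)."""
    rows = []
    for rec in records:
        if len(rec.covariates) != len(covariate_names):
            raise ValueError(f"record {rec.id}: covariate length mismatch")
        cov = dict(zip(covariate_names, rec.covariates))
        for a, s in rec.visits:
            rows.append({"id": rec.id, "age": a, "state": s, "death": 0, **cov})
        if rec.died:
            rows.append({"id": rec.id, "age": rec.death_age, "state": 3,
                         "death": 1, **cov})
    pd.DataFrame(rows, columns=list(_FIXED) + list(covariate_names)) \
        .to_csv(path, index=False)
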