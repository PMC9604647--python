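"""Disease-status helpers shared by model ranking and the evaluation tables.

Baseline flags are prevalence indicators; follow-up flags are incident
indicators that exist only for participants free of the disease at baseline
who took part in the follow-up wave.  A composite outcome ("any metabolic
disease", "any cardiovascular disease") is positive if any member disease is
positive, negative if every member is observed negative, and missing
otherwise — the maximal-information reading, which the per-table denominators
make explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DISEASES

__all__ = ["CompositeOutcome", "COMPOSITES", "ALL_OUTCOMES",
           "baseline_status", "followup_at_risk", "followup_status"]


@dataclass(frozen=True)
class CompositeOutcome:
    name: str
    members: tuple[str, ...]


COMPOSITES = {
    "any_metabolic": CompositeOutcome(
        "any_metabolic", ("hypertension", "t2d", "dyslipidemia", "hyperuricemia")),
    "any_cvd": CompositeOutcome("any_cvd", ("mi", "stroke")),
}

#: Individual diseases plus the two composites, in reporting order.
ALL_OUTCOMES: tuple[str, ...] = DISEASES + tuple(COMPOSITES)


def _members(outcome: str) -> tuple[str, ...]:
    if outcome in COMPOSITES:
        return COMPOSITES[outcome].members
    if outcome in DISEASES:
        return (outcome,)
    raise KeyError(f"unknown outcome {outcome!r}")


def _any_all_missing(flags: pd.DataFrame) -> pd.Series:
    """1 if any member flag is 1, 0 if all observed and 0, else NaN."""
    any_pos = (flags == 1).any(axis=1)
    all_neg = (flags == 0).all(axis=1)
    out = pd.Series(np.nan, index=flags.index)
    out[any_pos] = 1.0
    out[all_neg & ~any_pos] = 0.0
    return out


def baseline_status(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """Prevalence indicator (1/0/NaN) for a disease or composite at baseline."""
    cols = [f"baseline_{m}" for m in _members(outcome)]
    return _any_all_missing(cohort[cols])


def followup_at_risk(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """At-risk mask: observed free of every member disease at baseline and
    participating in the follow-up wave."""
    cols = [f"baseline_{m}" for m in _members(outcome)]
    free = (cohort[cols] == 0).all(axis=1)
    return free & cohort["in_followup"].astype(bool)


def followup_status(cohort: pd.DataFrame, outcome: str) -> pd.Series:
    """Incident indicator (1/0/NaN) among the at-risk; NaN elsewhere."""
    at_risk = followup_at_risk(cohort, outcome)
    cols = [f"followup_{m}" for m in _members(outcome)]
    status = _any_all_missing(cohort[cols])
    status[~at_risk] = np.nan
    return status
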