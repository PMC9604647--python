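"""Builders for count-specified worked examples.

These construct cohort tables whose exclusion-step counts or case/at-risk
counts are fixed by the caller, so that ratio outputs of the pipeline
(retained n, prevalence and incidence percentages) can be verified against
independently known totals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import DISEASES, GeneratorConfig, generate_cohort

__all__ = ["roster_with_exclusion_counts", "prevalence_cohort",
           "incidence_cohort"]


def roster_with_exclusion_counts(n_total: int = 3080, n_nonfasting: int = 54,
                                 n_glucose_missing: int = 7,
                                 n_high_missing: int = 18,
                                 seed: int = 123) -> pd.DataFrame:
    """A roster hitting exactly the requested exclusion-step counts.

    The first block is flagged non-fasting, the next has fasting glucose
    deleted, the next has 2 of the 14 parameters deleted (14.3% > 10%),
    and the remainder is complete.
    """
    cfg = GeneratorConfig(n_participants=n_total, seed=seed, missing_rate=0.0,
                          nonfasting_rate=0.0)
    df = generate_cohort(cfg)
    stop_fast = n_nonfasting
    stop_glu = stop_fast + n_glucose_missing
    stop_miss = stop_glu + n_high_missing
    df.loc[: stop_fast - 1, "fasting_hours_ok"] = False
    df.loc[stop_fast: stop_glu - 1, "glucose"] = np.nan
    df.loc[stop_glu: stop_miss - 1, ["tg", "bmi"]] = np.nan
    return df


def _empty_cohort(n: int) -> pd.DataFrame:
    df = pd.DataFrame(index=range(n))
    df["in_followup"] = True
    for dz in DISEASES:
        df[f"baseline_{dz}"] = 0.0
        df[f"followup_{dz}"] = 0.0
    return df


def prevalence_cohort(n: int, cases: dict[str, int],
                      missing: dict[str, int] | None = None) -> pd.DataFrame:
    """Cohort with ``cases[disease]`` baseline cases (assigned from row 0)
    and optionally ``missing[disease]`` missing flags (assigned from the end)."""
    df = _empty_cohort(n)
    for dz, k in cases.items():
        df.loc[: k - 1, f"baseline_{dz}"] = 1.0
    for dz, k in (missing or {}).items():
        df.loc[n - k:, f"baseline_{dz}"] = np.nan
    return df


def incidence_cohort(n: int, at_risk: int, incident: int,
                     disease: str = "hypertension") -> pd.DataFrame:
    """Cohort where exactly ``at_risk`` participants are at risk for
    ``disease`` (hence for any composite containing it) and ``incident`` of
    them become incident cases; the remainder are removed from the at-risk
    set by prevalence, non-participation and missing follow-up status in
    roughly equal parts."""
    if not incident <= at_risk <= n:
        raise ValueError("need incident <= at_risk <= n")
    df = _empty_cohort(n)
    df.loc[: incident - 1, f"followup_{disease}"] = 1.0
    excess = n - at_risk
    third = excess // 3
    lo = at_risk
    df.loc[lo: lo + third - 1, f"baseline_{disease}"] = 1.0
    df.loc[lo + third: lo + 2 * third - 1, "in_followup"] = False
    df.loc[lo + 2 * third: n - 1, f"followup_{disease}"] = np.nan
    return df
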