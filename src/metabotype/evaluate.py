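"""Descriptive and inferential evaluation of metabotype clusters.

Continuous parameters are summarized as pooled medians and interquartile
ranges (computed within each imputed dataset, then averaged over the m
imputations) and compared across clusters with the Kruskal-Wallis test plus
Dunn's pairwise post hoc z-tests under Bonferroni correction.  Categorical
variables and disease outcomes are compared with Pearson's chi-square test,
switching to an exact (Fisher-type) test whenever an expected cell count
falls below 5.  Prevalence and incidence tables always report their own
denominators, because missing disease flags and follow-up attrition make
those denominators differ between outcomes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcomes import ALL_OUTCOMES, baseline_status, followup_status
from .preprocess import ImputationSet

__all__ = [
    "GroupTestResult",
    "pooled_median_iqr",
    "test_across_groups",
    "dunn_posthoc",
    "fisher_exact_rxc",
    "prevalence_table",
    "incidence_table",
]


@dataclass
class GroupTestResult:
    variable: str
    test: str  # kruskal_wallis | chi_square | fisher
    statistic: float
    p_value: float
    n_used: int
    posthoc: pd.DataFrame | None = None  # pairwise Bonferroni-adjusted p-values
    degenerate: bool = False


def pooled_median_iqr(imp: ImputationSet, variable: str,
                      groups: np.ndarray) -> pd.DataFrame:
    """Per-group median and IQR, each computed within every imputed dataset
    and then averaged across imputations."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    rows = {g: {"median": [], "iqr": []} for g in levels}
    for df in imp.completed:
        values = df[variable].to_numpy(dtype=float)
        for g in levels:
            sub = values[groups == g]
            if sub.size == 0:
                raise ValueError(f"group {g!r} is empty")
            q1, med, q3 = np.percentile(sub, [25, 50, 75])
            rows[g]["median"].append(med)
            rows[g]["iqr"].append(q3 - q1)
    out = pd.DataFrame({"median": [np.mean(rows[g]["median"]) for g in levels],
                        "iqr": [np.mean(rows[g]["iqr"]) for g in levels]},
                       index=pd.Index(levels, name="group"))
    return out


def dunn_posthoc(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's pairwise z-tests on the pooled ranks with tie correction,
    Bonferroni-adjusted over all group pairs."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(np.unique(groups))
    N = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: ranks[groups == g].mean() for g in levels}
    n = {g: int((groups == g).sum()) for g in levels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)))
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / n[a] + 1.0 / n[b])
        z = (mean_rank[a] - mean_rank[b]) / math.sqrt(var) if var > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p_raw,
                     "p_adjusted": min(1.0, p_raw * len(pairs))})
    return pd.DataFrame(rows)


def _exact_tables(row_sums, col_sums):
    """Enumerate all tables with the given margins (generator)."""
    r = len(row_sums)

    def rec(row_idx, remaining_cols, acc):
        if row_idx == r - 1:
            yield acc + [list(remaining_cols)]
            return
        total = row_sums[row_idx]
        c = len(remaining_cols)

        def fill(col_idx, left, row_acc):
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill(col_idx + 1, left - v, row_acc + [v])

        for row in fill(0, total, []):
            rest = [remaining_cols[j] - row[j] for j in range(c)]
            yield from rec(row_idx + 1, rest, acc + [row])

    yield from rec(0, list(col_sums), [])


def _log_table_prob(table, log_fact, row_sums, col_sums, N):
    lp = (sum(log_fact[s] for s in row_sums) + sum(log_fact[s] for s in col_sums)
          - log_fact[N])
    for row in table:
        for v in row:
            lp -= log_fact[v]
    return lp


def fisher_exact_rxc(table: np.ndarray, max_enumeration: int = 200_000,
                     n_resamples: int = 20_000,
                     random_state: int | None = 0) -> float:
    """Two-sided exact test of independence for an r x c contingency table.

    Uses scipy's 2x2 Fisher test when applicable; otherwise enumerates every
    table with the observed margins (Freeman-Halton) when the enumeration is
    small enough, and falls back to a seeded Monte Carlo version of the same
    test on large tables.
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table).pvalue)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    N = int(table.sum())
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, N + 1)))])
    lp_obs = _log_table_prob(table.tolist(), log_fact, row_sums, col_sums, N)

    approx_count = np.prod([min(r, c) + 1.0 for r, c
                            in itertools.product(row_sums[:-1], col_sums[:-1])])
    if approx_count <= max_enumeration:
        p = 0.0
        for t in _exact_tables(list(row_sums), list(col_sums)):
            lp = _log_table_prob(t, log_fact, row_sums, col_sums, N)
            if lp <= lp_obs + 1e-9:
                p += math.exp(lp)
        return float(min(1.0, p))

    rvs = stats.random_table(row_sums, col_sums).rvs(
        n_resamples, random_state=random_state)
    hits = 0
    for t in rvs:
        lp = _log_table_prob(t.astype(int).tolist(), log_fact, row_sums, col_sums, N)
        if lp <= lp_obs + 1e-9:
            hits += 1
    return float((hits + 1) / (n_resamples + 1))


def test_across_groups(values, groups, kind: str = "continuous",
                       random_state: int | None = 0) -> GroupTestResult:
    """Kruskal-Wallis (+ Dunn post hoc) for continuous data; Pearson
    chi-square, or an exact test when any expected cell count is below 5,
    for categorical data.  Complete-case per variable."""
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    keep = values.notna() & groups.notna()
    values, groups = values[keep], groups[keep]
    name = values.name or "value"
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty groups")

    if kind == "continuous":
        v = values.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            return GroupTestResult(name, "kruskal_wallis", 0.0, 1.0,
                                   int(keep.sum()), degenerate=True)
        samples = [v[groups == g] for g in sorted(levels)]
        stat, p = stats.kruskal(*samples)
        posthoc = dunn_posthoc(v, groups.to_numpy())
        return GroupTestResult(name, "kruskal_wallis", float(stat), float(p),
                               int(keep.sum()), posthoc=posthoc)

    if kind != "categorical":
        raise ValueError("kind must be 'continuous' or 'categorical'")
    table = pd.crosstab(groups, values)
    if table.shape[1] < 2:
        return GroupTestResult(name, "chi_square", 0.0, 1.0, int(keep.sum()),
                               degenerate=True)
    expected = stats.contingency.expected_freq(table.to_numpy())
    if (expected < 5).any():
        p = fisher_exact_rxc(table.to_numpy(), random_state=random_state)
        return GroupTestResult(name, "fisher", float("nan"), p, int(keep.sum()))
    stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return GroupTestResult(name, "chi_square", float(stat), float(p),
                           int(keep.sum()))


def _status_table(status: pd.Series, by, denominator: str) -> list[dict]:
    groups = (pd.Series(by).reset_index(drop=True)
              if by is not None else pd.Series(1, index=status.index))
    rows = []
    for g in sorted(groups.unique()):
        sub = status[groups.to_numpy() == g]
        denom = len(sub) if denominator == "all" else int(sub.notna().sum())
        cases = int((sub == 1).sum())
        rows.append({"group": g, "n_cases": cases, "n_denominator": denom,
                     "percent": 100.0 * cases / denom if denom else float("nan")})
    return rows


def prevalence_table(cohort: pd.DataFrame, outcomes=ALL_OUTCOMES, by=None,
                     denominator: str = "observed") -> pd.DataFrame:
    """Baseline cases per outcome (and optionally per cluster).

    ``denominator`` is either ``"observed"`` (participants with non-missing
    status — the complete-case convention) or ``"all"`` (every participant).
    """
    if denominator not in ("observed", "all"):
        raise ValueError("denominator must be 'observed' or 'all'")
    rows = []
    for outcome in outcomes:
        status = baseline_status(cohort, outcome).reset_index(drop=True)
        for row in _status_table(status, by, denominator):
            rows.append({"outcome": outcome, **row})
    return pd.DataFrame(rows)


def incidence_table(cohort: pd.DataFrame, outcomes=ALL_OUTCOMES,
                    by=None) -> pd.DataFrame:
    """Cumulative incidence per outcome: incident cases over the at-risk set
    (baseline-free, in follow-up, with observed follow-up status).  An empty
    at-risk set yields an undefined (NaN) percentage, never 0."""
    rows = []
    for outcome in outcomes:
        status = followup_status(cohort, outcome).reset_index(drop=True)
        for row in _status_table(status, by, denominator="observed"):
            row["at_risk"] = row.pop("n_denominator")
            rows.append({"outcome": outcome, "group": row["group"],
                         "n_incident": row["n_cases"], "at_risk": row["at_risk"],
                         "percent": row["percent"]})
    return pd.DataFrame(rows)
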