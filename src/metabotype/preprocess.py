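"""Cohort preprocessing: exclusions, derived variables, multiple imputation,
and z-standardization.

The preprocessing contract is the one the clustering stages rely on:
participants are excluded in a fixed order (non-fasting, missing fasting
glucose, more than ``max_missing_fraction`` of the candidate parameters
missing), the remaining gaps are filled by chained equations with predictive
mean matching into ``m`` completed copies, and each completed copy is
z-standardized column-wise so that no parameter dominates the Euclidean
metric of k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import PARAMETERS

__all__ = [
    "ExclusionReport",
    "ImputationSet",
    "apply_exclusions",
    "derive_non_hdl",
    "categorize_bmi",
    "ChainedImputer",
    "impute_chained",
    "ColumnStandardizer",
    "z_standardize",
    "inverse_standardize",
]

#: Default candidate parameter pool (the 14-variable reduced set in which
#: non-HDL cholesterol replaces total cholesterol, LDLc and the TC/HDL ratio).
DEFAULT_PARAMETER_POOL: tuple[str, ...] = PARAMETERS


@dataclass(frozen=True)
class ExclusionReport:
    """Tallies of the participant-exclusion cascade (applied in this order)."""

    n_input: int
    n_nonfasting: int
    n_missing_glucose: int
    n_high_missing: int

    @property
    def n_retained(self) -> int:
        return (self.n_input - self.n_nonfasting - self.n_missing_glucose
                - self.n_high_missing)


def apply_exclusions(
    cohort: pd.DataFrame,
    max_missing_fraction: float = 0.10,
    parameters: tuple[str, ...] = DEFAULT_PARAMETER_POOL,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop non-fasting participants, those without a fasting glucose value,
    and those missing more than ``max_missing_fraction`` of ``parameters``.

    Steps are applied sequentially, so each participant is counted in at most
    one exclusion tally and the report counts are conserved.
    """
    if "fasting_hours_ok" not in cohort or "glucose" not in cohort:
        raise ValueError("cohort must carry 'fasting_hours_ok' and 'glucose' columns")
    n_input = len(cohort)

    fasting = cohort[cohort["fasting_hours_ok"].astype(bool)]
    n_nonfasting = n_input - len(fasting)

    with_glucose = fasting[fasting["glucose"].notna()]
    n_missing_glucose = len(fasting) - len(with_glucose)

    frac = with_glucose[list(parameters)].isna().mean(axis=1)
    retained = with_glucose[frac <= max_missing_fraction]
    n_high_missing = len(with_glucose) - len(retained)

    if len(retained) == 0:
        raise ValueError("no participants retained after exclusions")
    report = ExclusionReport(n_input, n_nonfasting, n_missing_glucose, n_high_missing)
    return retained.reset_index(drop=True), report


def derive_non_hdl(tc, hdlc):
    """Non-HDL cholesterol (mmol/L): total cholesterol minus HDL cholesterol."""
    tc = np.asarray(tc, dtype=float)
    hdlc = np.asarray(hdlc, dtype=float)
    if np.any(hdlc <= 0):
        raise ValueError("HDLc must be strictly positive")
    if np.any(tc < hdlc):
        raise ValueError("TC must be >= HDLc")
    out = tc - hdlc
    return float(out) if out.ndim == 0 else out


_BMI_EDGES = (18.5, 25.0, 30.0)
_BMI_LABELS = ("underweight", "normal", "overweight", "obese")


def categorize_bmi(bmi):
    """WHO BMI class; intervals are left-closed, right-open."""
    arr = np.asarray(bmi, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("BMI must be strictly positive")
    idx = np.searchsorted(_BMI_EDGES, arr, side="right")
    out = np.asarray(_BMI_LABELS)[idx]
    return str(out) if out.ndim == 0 else out


@dataclass
class ImputationSet:
    """``m`` completed copies of the parameter matrix plus, once standardized,
    the per-imputation standardization constants for the inverse transform."""

    completed: list[pd.DataFrame]
    iterations: int
    seed: int | None
    column_means: list[pd.Series] = field(default_factory=list)
    column_sds: list[pd.Series] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.completed)

    @property
    def standardized(self) -> bool:
        return bool(self.column_means)

    @property
    def columns(self) -> list[str]:
        return list(self.completed[0].columns)


class ChainedImputer(BaseEstimator):
    """Multiple imputation by chained equations with predictive mean matching.

    Each incomplete column is regressed on all others; regression
    coefficients are drawn from their approximate posterior (Bayesian linear
    model with a flat prior), and each missing cell borrows the observed
    value of one of the ``n_donors`` donors whose predicted mean is nearest
    to the cell's prediction.  Cycling through columns in order of
    increasing missingness for ``iterations`` sweeps, repeated independently
    ``m`` times, yields ``m`` completed datasets.

    Parameters
    ----------
    m : number of completed datasets.
    iterations : chained-equation sweeps per dataset.
    n_donors : donor-pool size for predictive mean matching.
    random_state : seed; fixed seed gives byte-identical imputations.
    """

    def __init__(self, m: int = 5, iterations: int = 10, n_donors: int = 5,
                 random_state: int | None = None):
        self.m = m
        self.iterations = iterations
        self.n_donors = n_donors
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "ChainedImputer":
        X = pd.DataFrame(X).astype(float)
        n_obs_per_col = X.notna().sum(axis=0)
        fully_missing = [c for c in X.columns if n_obs_per_col[c] == 0]
        if fully_missing:
            raise ValueError(f"columns fully missing: {fully_missing}")
        thin = [c for c in X.columns if 0 < X[c].isna().sum() and n_obs_per_col[c] < 2]
        if thin:
            raise ValueError(f"columns with fewer than 2 observed values: {thin}")

        seeds = np.random.SeedSequence(self.random_state).spawn(self.m)
        self.imputations_ = [self._impute_once(X, np.random.default_rng(s))
                             for s in seeds]
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X: pd.DataFrame, y=None) -> ImputationSet:
        self.fit(X)
        return ImputationSet(completed=[df.copy() for df in self.imputations_],
                             iterations=self.iterations, seed=self.random_state)

    # -- single-chain PMM ---------------------------------------------------
    def _impute_once(self, X: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        data = X.to_numpy(copy=True)
        miss = np.isnan(data)
        if not miss.any():
            return X.copy()
        n_missing = miss.sum(axis=0)
        # visit order: increasing missingness, stable for ties
        visit = [j for j in np.argsort(n_missing, kind="stable") if n_missing[j] > 0]

        # initial fill: random draws from each column's observed values
        for j in range(data.shape[1]):
            if n_missing[j]:
                obs = data[~miss[:, j], j]
                data[miss[:, j], j] = rng.choice(obs, size=n_missing[j], replace=True)

        for _ in range(self.iterations):
            for j in visit:
                obs_mask = ~miss[:, j]
                others = np.delete(data, j, axis=1)
                Z = np.column_stack([np.ones(len(data)), others])
                y_obs = data[obs_mask, j]
                Z_obs = Z[obs_mask]
                beta, yhat_obs, yhat_mis = _bayesian_prediction(
                    Z_obs, y_obs, Z[miss[:, j]], rng)
                data[miss[:, j], j] = _pmm_draw(
                    yhat_obs, y_obs, yhat_mis, self.n_donors, rng)
        return pd.DataFrame(data, columns=X.columns, index=X.index)


def _bayesian_prediction(Z_obs, y_obs, Z_mis, rng):
    """OLS predictions for donors plus posterior-draw predictions for targets."""
    n, q = Z_obs.shape
    gram = Z_obs.T @ Z_obs
    ridge = 1e-8 * np.trace(gram) / q * np.eye(q)
    gram_inv = np.linalg.inv(gram + ridge)
    beta_hat = gram_inv @ (Z_obs.T @ y_obs)
    resid = y_obs - Z_obs @ beta_hat
    df_resid = max(n - q, 1)
    sigma2 = float(resid @ resid) / max(rng.chisquare(df_resid), 1e-12)
    try:
        chol = np.linalg.cholesky(gram_inv)
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.clip(np.diag(gram_inv), 0, None)))
    beta_star = beta_hat + np.sqrt(sigma2) * (chol @ rng.standard_normal(q))
    return beta_hat, Z_obs @ beta_hat, Z_mis @ beta_star


def _pmm_draw(yhat_obs, y_obs, yhat_mis, n_donors, rng):
    """For each target prediction pick one of the ``n_donors`` observed values
    with nearest predicted means (window search on the sorted predictions)."""
    order = np.argsort(yhat_obs, kind="stable")
    sorted_pred = yhat_obs[order]
    sorted_y = y_obs[order]
    n = len(sorted_pred)
    d = min(n_donors, n)
    pos = np.searchsorted(sorted_pred, yhat_mis)
    # candidate window of 2d neighbours around the insertion point
    offsets = np.arange(-d, d)
    cand = np.clip(pos[:, None] + offsets[None, :], 0, n - 1)
    dist = np.abs(sorted_pred[cand] - yhat_mis[:, None])
    nearest = np.argpartition(dist, d - 1, axis=1)[:, :d]
    pick = nearest[np.arange(len(yhat_mis)), rng.integers(0, d, size=len(yhat_mis))]
    return sorted_y[cand[np.arange(len(yhat_mis)), pick]]


def impute_chained(parameters: pd.DataFrame, m: int = 5, iterations: int = 10,
                   seed: int | None = None, n_donors: int = 5) -> ImputationSet:
    """Functional wrapper over :class:`ChainedImputer`."""
    return ChainedImputer(m=m, iterations=iterations, n_donors=n_donors,
                          random_state=seed).fit_transform(parameters)


class ColumnStandardizer(TransformerMixin, BaseEstimator):
    """Column-wise z-standardization with the sample SD (n-1 denominator).

    A deliberate convention choice over :class:`sklearn.preprocessing.StandardScaler`
    (population SD); constants are kept for the inverse transform.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "ColumnStandardizer":
        X = pd.DataFrame(X).astype(float)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        bad = self.scale_[~(self.scale_ > 0)].index.tolist()
        if bad:
            raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (pd.DataFrame(X).astype(float) - self.mean_) / self.scale_

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X).astype(float) * self.scale_ + self.mean_


def z_standardize(imp: ImputationSet) -> ImputationSet:
    """Standardize every completed dataset; constants are stored per imputation."""
    completed, means, sds = [], [], []
    for df in imp.completed:
        scaler = ColumnStandardizer().fit(df)
        completed.append(scaler.transform(df))
        means.append(scaler.mean_)
        sds.append(scaler.scale_)
    return ImputationSet(completed=completed, iterations=imp.iterations,
                         seed=imp.seed, column_means=means, column_sds=sds)


def inverse_standardize(imp: ImputationSet) -> ImputationSet:
    """Undo :func:`z_standardize` using the stored constants."""
    if not imp.standardized:
        raise ValueError("imputation set carries no standardization constants")
    completed = [df * sd + mu for df, mu, sd in
                 zip(imp.completed, imp.column_means, imp.column_sds)]
    return ImputationSet(completed=completed, iterations=imp.iterations, seed=imp.seed)
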