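"""Variable-importance ranking and top-50% parameter selection.

Three complementary importance methods rank the candidate clustering
parameters:

* ``PimpImportance`` — random-forest Gini importance calibrated by permuting
  the outcome: the permuted-outcome ("null") importances are summarized by a
  parametric distribution (normal, log-normal or gamma, chosen by
  Kolmogorov–Smirnov fit), and each variable's p-value is the upper tail
  probability of its observed importance under that fitted null.
* ``CVPermutationImportance`` — out-of-fold permutation importance: the
  increase in held-out misclassification error after permuting a predictor,
  averaged over permutations and folds.
* ``GradientBoostGainImportance`` — fractional total split gain of each
  variable in a gradient-boosted tree ensemble.

The clustering pool is the intersection of the per-method top halves, with
parameters that are not standard laboratory measurements (insulin by
default) removed afterwards.

By default forests consider every feature at each split
(``max_features=None``); this makes importance scores invariant to the
column order of the input, at some cost in speed.  Pass
``rf_params={"max_features": "sqrt"}`` to trade that invariance away.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ImportanceReport",
    "SelectionResult",
    "GiniImportance",
    "PimpImportance",
    "CVPermutationImportance",
    "GradientBoostGainImportance",
    "rf_gini_importance",
    "pimp",
    "cvpvi",
    "gb_gain_importance",
    "select_parameters",
    "cluster_outcome_labels",
]


@dataclass
class ImportanceReport:
    """Per-variable scores (and, for PIMP, null summaries and p-values)."""

    method: str
    variable_scores: pd.Series
    ranks: pd.Series
    settings: dict = field(default_factory=dict)
    null_importances: pd.DataFrame | None = None
    fitted_null: dict | None = None
    p_values: pd.Series | None = None

    @property
    def variables(self) -> list[str]:
        return list(self.variable_scores.index)

    def top_set(self, top_fraction: float = 0.5) -> list[str]:
        """The best-ranked ``ceil(top_fraction * p)`` variables.

        Ties in score are broken by alphabetical name so the set is
        deterministic.
        """
        k = math.ceil(top_fraction * len(self.variable_scores))
        order = sorted(self.variable_scores.index,
                       key=lambda v: (-self.variable_scores[v], v))
        return order[:k]


@dataclass
class SelectionResult:
    """Outcome of the top-50% intersection rule."""

    selected: list[str]
    top_fraction: float
    excluded_nonstandard: list[str]
    per_method_top_sets: dict[str, list[str]]

    @property
    def clustering_pool(self) -> list[str]:
        """Selected variables minus the non-standard ones — what clustering uses."""
        drop = set(self.excluded_nonstandard)
        return [v for v in self.selected if v not in drop]


def _dense_ranks(scores: pd.Series) -> pd.Series:
    r = stats.rankdata(-scores.to_numpy(), method="dense")
    return pd.Series(r, index=scores.index, dtype=int)


def _validate_xy(X, y) -> tuple[pd.DataFrame, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must have the same number of rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("outcome must have at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every outcome class needs at least 2 members")
    return X, y


def _column_rng(seed, name: str) -> np.random.Generator:
    # per-column stream keyed by the column *name*, so importance does not
    # depend on column order
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(0 if seed is None else seed,
                                        zlib.crc32(str(name).encode()))))


class GiniImportance(BaseEstimator):
    """Mean-decrease-in-impurity importance from a random-forest classifier."""

    def __init__(self, n_trees: int = 500, random_state: int | None = None,
                 rf_params: dict | None = None):
        self.n_trees = n_trees
        self.random_state = random_state
        self.rf_params = rf_params

    def _forest(self, random_state):
        params = dict(max_features=None)
        params.update(self.rf_params or {})
        return RandomForestClassifier(n_estimators=self.n_trees, n_jobs=1,
                                      random_state=random_state, **params)

    def fit(self, X, y) -> "GiniImportance":
        X, y = _validate_xy(X, y)
        forest = self._forest(self.random_state).fit(X.to_numpy(), y)
        self.scores_ = pd.Series(forest.feature_importances_, index=X.columns)
        self.ranks_ = _dense_ranks(self.scores_)
        return self

    def to_report(self) -> ImportanceReport:
        return ImportanceReport(
            method="GINI", variable_scores=self.scores_, ranks=self.ranks_,
            settings={"n_trees": self.n_trees, "seed": self.random_state})


class PimpImportance(GiniImportance):
    """Permutation-calibrated random-forest importance (outcome permutation).

    For each of ``n_perm`` permutations of the outcome the forest is refit
    and its importances recorded as null importances.  Per variable, the
    candidate families normal / log-normal / gamma are fitted by maximum
    likelihood; the family with the largest Kolmogorov–Smirnov p-value is
    selected, and ``p = 1 - CDF(observed importance)``.  When no family
    reaches KS p >= ``ks_alpha`` (or the null is degenerate) the add-one
    empirical p-value ``(1 + #{null >= observed}) / (1 + n_perm)`` is used.
    """

    def __init__(self, n_trees: int = 500, n_perm: int = 100,
                 random_state: int | None = None, rf_params: dict | None = None,
                 ks_alpha: float = 0.05):
        super().__init__(n_trees=n_trees, random_state=random_state,
                         rf_params=rf_params)
        self.n_perm = n_perm
        self.ks_alpha = ks_alpha

    def fit(self, X, y) -> "PimpImportance":
        X, y = _validate_xy(X, y)
        if self.n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        Xa = X.to_numpy()
        rng = np.random.default_rng(self.random_state)
        forest_seed = int(rng.integers(2**31))
        forest = self._forest(forest_seed).fit(Xa, y)
        self.scores_ = pd.Series(forest.feature_importances_, index=X.columns)

        null = np.empty((self.n_perm, X.shape[1]))
        for b in range(self.n_perm):
            y_perm = rng.permutation(y)
            null[b] = self._forest(int(rng.integers(2**31))).fit(Xa, y_perm
                                                                 ).feature_importances_
        self.null_importances_ = pd.DataFrame(null, columns=X.columns)

        self.fitted_null_, pvals = {}, {}
        for col in X.columns:
            family, p = _null_pvalue(null_sample=self.null_importances_[col].to_numpy(),
                                     observed=float(self.scores_[col]),
                                     n_perm=self.n_perm, ks_alpha=self.ks_alpha)
            self.fitted_null_[col] = family
            pvals[col] = p
        self.p_values_ = pd.Series(pvals)
        self.ranks_ = _dense_ranks(self.scores_)
        return self

    def to_report(self) -> ImportanceReport:
        return ImportanceReport(
            method="PIMP", variable_scores=self.scores_, ranks=self.ranks_,
            null_importances=self.null_importances_, fitted_null=self.fitted_null_,
            p_values=self.p_values_,
            settings={"n_trees": self.n_trees, "n_perm": self.n_perm,
                      "seed": self.random_state})


def empirical_permutation_pvalue(null_sample: np.ndarray, observed: float) -> float:
    """Add-one empirical upper-tail p-value; never below 1/(1 + n_perm)."""
    null_sample = np.asarray(null_sample, float)
    return (1.0 + int((null_sample >= observed).sum())) / (1.0 + len(null_sample))


_NULL_FAMILIES = ("norm", "lognorm", "gamma")


def _null_pvalue(null_sample: np.ndarray, observed: float, n_perm: int,
                 ks_alpha: float) -> tuple[dict, float]:
    if np.ptp(null_sample) == 0:
        warnings.warn("degenerate null importances; using empirical p-value",
                      stacklevel=3)
        return ({"family": "empirical"},
                empirical_permutation_pvalue(null_sample, observed))
    candidates = []
    mu, sd = stats.norm.fit(null_sample)
    candidates.append(("norm", (mu, sd), stats.norm(mu, sd)))
    if null_sample.min() > 0:
        try:
            s, loc, sc = stats.lognorm.fit(null_sample, floc=0)
            candidates.append(("lognorm", (s, loc, sc), stats.lognorm(s, loc, sc)))
        except Exception:  # pragma: no cover - pathological samples
            pass
        try:
            a, loc, sc = stats.gamma.fit(null_sample, floc=0)
            candidates.append(("gamma", (a, loc, sc), stats.gamma(a, loc, sc)))
        except Exception:  # pragma: no cover
            pass
    best = max(((stats.kstest(null_sample, dist.cdf).pvalue, name, params, dist)
                for name, params, dist in candidates), key=lambda t: t[0])
    ks_p, name, params, dist = best
    if ks_p < ks_alpha:
        return ({"family": "empirical", "ks_p": float(ks_p)},
                empirical_permutation_pvalue(null_sample, observed))
    return ({"family": name, "params": tuple(map(float, params)),
             "ks_p": float(ks_p)},
            float(np.clip(dist.sf(observed), 0.0, 1.0)))


class CVPermutationImportance(BaseEstimator):
    """Cross-validated permutation importance on held-out folds.

    Per fold: a forest is trained on the training portion, the held-out
    misclassification error is measured, each predictor is permuted
    ``n_perm`` times in the held-out data and the mean error increase is
    recorded; scores average the increases over folds.  Permutation streams
    are keyed per column name, so scores do not depend on column order.
    """

    def __init__(self, n_folds: int = 10, n_trees: int = 1000, n_perm: int = 100,
                 random_state: int | None = None, rf_params: dict | None = None):
        self.n_folds = n_folds
        self.n_trees = n_trees
        self.n_perm = n_perm
        self.random_state = random_state
        self.rf_params = rf_params

    def fit(self, X, y) -> "CVPermutationImportance":
        X, y = _validate_xy(X, y)
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.n_folds:
            raise ValueError(
                "every class needs at least n_folds members for stratified folds")
        if len(X) // self.n_folds < 20:
            raise ValueError("folds would have fewer than 20 rows; reduce n_folds")
        Xa = X.to_numpy()
        params = dict(max_features=None)
        params.update(self.rf_params or {})
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.random_state)
        increases = np.zeros((self.n_folds, X.shape[1]))
        col_rngs = [_column_rng(self.random_state, c) for c in X.columns]
        for f, (train, test) in enumerate(skf.split(Xa, y)):
            forest = RandomForestClassifier(
                n_estimators=self.n_trees, n_jobs=1,
                random_state=self.random_state, **params).fit(Xa[train], y[train])
            base_err = float(np.mean(forest.predict(Xa[test]) != y[test]))
            X_test = Xa[test]
            for j, rng in enumerate(col_rngs):
                if np.ptp(X_test[:, j]) == 0:
                    continue  # permutation of a constant column is the identity
                err = 0.0
                X_perm = X_test.copy()
                for _ in range(self.n_perm):
                    X_perm[:, j] = rng.permutation(X_test[:, j])
                    err += float(np.mean(forest.predict(X_perm) != y[test]))
                increases[f, j] = err / self.n_perm - base_err
        self.fold_increases_ = pd.DataFrame(increases, columns=X.columns)
        self.scores_ = self.fold_increases_.mean(axis=0)
        self.ranks_ = _dense_ranks(self.scores_)
        return self

    def to_report(self) -> ImportanceReport:
        return ImportanceReport(
            method="CVPVI", variable_scores=self.scores_, ranks=self.ranks_,
            settings={"n_folds": self.n_folds, "n_trees": self.n_trees,
                      "n_perm": self.n_perm, "seed": self.random_state})


class GradientBoostGainImportance(BaseEstimator):
    """Fractional total split gain from a gradient-boosted tree ensemble."""

    def __init__(self, n_estimators: int = 100, random_state: int | None = None,
                 xgb_params: dict | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.xgb_params = xgb_params

    def fit(self, X, y) -> "GradientBoostGainImportance":
        from xgboost import XGBClassifier

        X, y = _validate_xy(X, y)
        _, y_codes = np.unique(y, return_inverse=True)
        params = dict(tree_method="exact", n_jobs=1, verbosity=0)
        params.update(self.xgb_params or {})
        model = XGBClassifier(n_estimators=self.n_estimators,
                              random_state=0 if self.random_state is None
                              else self.random_state, **params)
        model.fit(X.to_numpy(), y_codes)
        gains = model.get_booster().get_score(importance_type="total_gain")
        raw = np.array([gains.get(f"f{j}", 0.0) for j in range(X.shape[1])])
        total = raw.sum()
        self.scores_ = pd.Series(raw / total if total > 0 else raw, index=X.columns)
        self.ranks_ = _dense_ranks(self.scores_)
        return self

    def to_report(self) -> ImportanceReport:
        return ImportanceReport(
            method="GBGAIN", variable_scores=self.scores_, ranks=self.ranks_,
            settings={"n_estimators": self.n_estimators, "seed": self.random_state})


# -- functional wrappers ----------------------------------------------------

def rf_gini_importance(X, y, n_trees: int = 500, seed: int | None = None,
                       **kw) -> pd.Series:
    return GiniImportance(n_trees=n_trees, random_state=seed, **kw).fit(X, y).scores_


def pimp(X, y, n_trees: int = 500, n_perm: int = 100, seed: int | None = None,
         **kw) -> ImportanceReport:
    return PimpImportance(n_trees=n_trees, n_perm=n_perm, random_state=seed,
                          **kw).fit(X, y).to_report()


def cvpvi(X, y, n_folds: int = 10, n_trees: int = 1000, n_perm: int = 100,
          seed: int | None = None, **kw) -> ImportanceReport:
    return CVPermutationImportance(n_folds=n_folds, n_trees=n_trees,
                                   n_perm=n_perm, random_state=seed,
                                   **kw).fit(X, y).to_report()


def gb_gain_importance(X, y, seed: int | None = None, **kw) -> ImportanceReport:
    return GradientBoostGainImportance(random_state=seed, **kw).fit(X, y).to_report()


def cluster_outcome_labels(X: pd.DataFrame, k: int = 3,
                           random_state: int | None = None) -> np.ndarray:
    """Default supervised-importance outcome: k-means labels on all candidate
    parameters (standardized), making selection self-referential to the
    metabolic structure rather than to any disease endpoint."""
    km = KMeans(n_clusters=k, n_init=25, random_state=random_state)
    return km.fit_predict(np.asarray(X, dtype=float))


def select_parameters(reports: list[ImportanceReport], top_fraction: float = 0.5,
                      nonstandard: set[str] = frozenset({"insulin"}),
                      on_empty: str = "error") -> SelectionResult:
    """Intersect the per-method top fractions and drop non-standard variables.

    ``on_empty`` controls the empty-intersection case: ``"error"`` raises (the
    default), ``"vote"`` falls back to variables present in a majority of the
    per-method top sets.
    """
    if not reports:
        raise ValueError("at least one importance report is required")
    var_sets = [set(r.variables) for r in reports]
    if any(s != var_sets[0] for s in var_sets):
        raise ValueError("all reports must cover the same variable set")
    top_sets = {r.method: r.top_set(top_fraction) for r in reports}
    common = set.intersection(*(set(v) for v in top_sets.values()))
    if not common:
        if on_empty == "vote":
            votes = {v: sum(v in s for s in top_sets.values()) for v in var_sets[0]}
            need = len(reports) // 2 + 1
            common = {v for v, c in votes.items() if c >= need}
        if not common:
            raise ValueError(
                "per-method top sets have an empty intersection; consider the "
                "union-with-vote fallback (on_empty='vote')")
    # order by mean rank across methods, ties alphabetically
    mean_rank = {v: float(np.mean([r.ranks[v] for r in reports])) for v in common}
    selected = sorted(common, key=lambda v: (mean_rank[v], v))
    return SelectionResult(selected=selected, top_fraction=top_fraction,
                           excluded_nonstandard=sorted(nonstandard & common),
                           per_method_top_sets=top_sets)
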