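"""Metabotype clustering: consensus k-means over multiply imputed data,
cluster ordering by metabolic unfavorability, candidate-model enumeration,
admissibility filtering and incidence-based model ranking.

The central estimator is :class:`ConsensusKMeans`: k-means is run
independently on each completed (imputed) dataset, the per-imputation
cluster labels are aligned to the first imputation by the label permutation
that minimizes total squared centroid distance, and each participant's
consensus label is the majority vote across imputations.  Clusters are then
relabeled 1..k by a composite unfavorability score so that cluster 1 is the
metabolically most favorable ("healthy") metabotype and cluster k the least
favorable ("unfavorable") one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)

from .outcomes import followup_at_risk, followup_status
from .preprocess import ImputationSet

__all__ = [
    "DEFAULT_RISK_DIRECTIONS",
    "RiskDirection",
    "MetabotypeModel",
    "ModelRanking",
    "ConsensusKMeans",
    "kmeans_consensus",
    "order_clusters",
    "enumerate_models",
    "check_admissible",
    "rank_models",
    "choose_k",
]


@dataclass(frozen=True)
class RiskDirection:
    """Per-parameter sign giving the direction of metabolic unfavorability:
    +1 if higher values are less favorable, -1 if higher values are more
    favorable (HDL cholesterol)."""

    signs: dict[str, int]

    def __post_init__(self):
        bad = {k: v for k, v in self.signs.items() if v not in (-1, 1)}
        if bad:
            raise ValueError(f"risk direction signs must be +1 or -1, got {bad}")

    def __getitem__(self, name: str) -> int:
        return self.signs[name]


DEFAULT_RISK_DIRECTIONS = RiskDirection({
    "tg": 1, "bmi": 1, "uric_acid": 1, "glucose": 1, "insulin": 1,
    "hdlc": -1, "non_hdlc": 1, "hba1c": 1, "hscrp": 1, "ggt": 1, "got": 1,
    "gpt": 1, "ap": 1, "leukocytes": 1,
})


@dataclass
class MetabotypeModel:
    """A clustering solution for one parameter subset across all imputations."""

    model_id: int
    parameter_subset: tuple[str, ...]
    k: int
    per_imputation_centroids: np.ndarray  # (m, k, p), standardized scale
    per_imputation_labels: np.ndarray     # (m, n), labels 1..k, aligned
    consensus_assignment: np.ndarray      # (n,), labels 1..k
    centroids: np.ndarray                 # (k, p), mean of aligned centroids
    ordering_scores: np.ndarray | None = None  # per-cluster unfavorability
    admissible: bool | None = None

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.consensus_assignment, minlength=self.k + 1)[1:]

    @property
    def smallest_cluster_n(self) -> int:
        return int(self.cluster_sizes.min())


@dataclass
class ModelRanking:
    """Models ranked by cumulative incidence of an outcome in cluster k."""

    outcome: str
    table: pd.DataFrame  # model_id, n_cluster, at_risk, incident, incidence, rank
    best_model_id: int


class ConsensusKMeans(ClusterMixin, BaseEstimator):
    """K-means over multiply imputed datasets with consensus labeling.

    Parameters
    ----------
    n_clusters : number of clusters (three metabotypes by default).
    n_init : k-means++ restarts per imputation; the best within-cluster
        sum of squares wins.
    random_state : seed; the same seed is used for every imputation, so m
        identical matrices yield a consensus identical to a single k-means run.

    Attributes
    ----------
    labels_ : consensus cluster label per row, ``0..n_clusters-1``.
    cluster_centers_ : mean of the aligned per-imputation centroids.
    per_imputation_labels_ : aligned labels, shape ``(m, n)``.
    per_imputation_centers_ : aligned centroids, shape ``(m, k, p)``.
    """

    def __init__(self, n_clusters: int = 3, n_init: int = 25,
                 random_state: int | None = None, max_reseed: int = 10):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.random_state = random_state
        self.max_reseed = max_reseed

    def _single_fit(self, X: np.ndarray) -> KMeans:
        seed = self.random_state
        for attempt in range(self.max_reseed + 1):
            km = KMeans(n_clusters=self.n_clusters, n_init=self.n_init,
                        random_state=None if seed is None else seed + attempt)
            labels = km.fit_predict(X)
            if len(np.unique(labels)) == self.n_clusters:
                return km
        raise RuntimeError("k-means produced an empty cluster after re-seeding")

    def fit(self, X, y=None) -> "ConsensusKMeans":
        matrices = _as_matrices(X)
        n = matrices[0].shape[0]
        if any(m.shape != matrices[0].shape for m in matrices):
            raise ValueError("all imputed matrices must share one shape")

        fits = [self._single_fit(m) for m in matrices]
        ref_centers = fits[0].cluster_centers_
        aligned_labels = np.empty((len(matrices), n), dtype=int)
        aligned_centers = np.empty((len(matrices), self.n_clusters,
                                    matrices[0].shape[1]))
        for i, km in enumerate(fits):
            perm = _align_labels(ref_centers, km.cluster_centers_)
            # perm[c] = cluster of imputation i matching reference cluster c
            aligned_centers[i] = km.cluster_centers_[perm]
            inverse = np.empty(self.n_clusters, dtype=int)
            inverse[perm] = np.arange(self.n_clusters)
            aligned_labels[i] = inverse[km.labels_]

        mean_centers = aligned_centers.mean(axis=0)
        votes = np.stack([np.bincount(aligned_labels[:, j],
                                      minlength=self.n_clusters)
                          for j in range(n)])
        winners = votes.max(axis=1, keepdims=True) == votes
        labels = votes.argmax(axis=1)
        tied = winners.sum(axis=1) > 1
        if tied.any():
            # break ties by nearest mean-aligned centroid of the participant's
            # average imputed feature vector
            mean_X = np.mean(matrices, axis=0)
            d2 = ((mean_X[tied, None, :] - mean_centers[None, :, :]) ** 2).sum(-1)
            d2[~winners[tied]] = np.inf
            labels[tied] = d2.argmin(axis=1)

        self.labels_ = labels
        self.cluster_centers_ = mean_centers
        self.per_imputation_labels_ = aligned_labels
        self.per_imputation_centers_ = aligned_centers
        self.inertias_ = np.array([km.inertia_ for km in fits])
        self.n_features_in_ = matrices[0].shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


def _as_matrices(X) -> list[np.ndarray]:
    if isinstance(X, ImputationSet):
        return [df.to_numpy(dtype=float) for df in X.completed]
    if isinstance(X, (list, tuple)):
        return [np.asarray(m, dtype=float) for m in X]
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 3:
        return list(arr)
    return [arr]


def _align_labels(ref_centers: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` with ``centers[perm[c]]`` matching ``ref_centers[c]``,
    minimizing the total squared centroid distance.  Exhaustive for k <= 5,
    Hungarian assignment above."""
    k = len(ref_centers)
    cost = ((ref_centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    if k <= 5:
        best, best_perm = np.inf, None
        for perm in itertools.permutations(range(k)):
            c = cost[np.arange(k), perm].sum()
            if c < best:
                best, best_perm = c, perm
        return np.asarray(best_perm)
    _, cols = linear_sum_assignment(cost)
    return cols


def kmeans_consensus(imp: ImputationSet, subset: tuple[str, ...], k: int = 3,
                     seed: int | None = None, n_init: int = 25,
                     model_id: int = 0) -> MetabotypeModel:
    """Cluster the ``subset`` columns of every imputation; consensus labels 1..k."""
    if len(subset) < 2:
        raise ValueError("parameter subset must contain at least 2 parameters")
    sub = ImputationSet(completed=[df[list(subset)] for df in imp.completed],
                        iterations=imp.iterations, seed=imp.seed)
    est = ConsensusKMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(sub)
    return MetabotypeModel(
        model_id=model_id, parameter_subset=tuple(subset), k=k,
        per_imputation_centroids=est.per_imputation_centers_,
        per_imputation_labels=est.per_imputation_labels_ + 1,
        consensus_assignment=est.labels_ + 1,
        centroids=est.cluster_centers_)


def order_clusters(model: MetabotypeModel,
                   directions: RiskDirection = DEFAULT_RISK_DIRECTIONS,
                   ) -> MetabotypeModel:
    """Relabel clusters 1..k by ascending composite unfavorability.

    The composite is the mean over subset parameters of sign x (cluster mean
    of the standardized parameter).  Exact ties are broken by cluster mean
    glucose (when glucose is in the subset), then by descending cluster size.
    """
    signs = np.array([directions[p] for p in model.parameter_subset], dtype=float)
    composite = (model.centroids * signs).mean(axis=1)

    glucose = (model.centroids[:, model.parameter_subset.index("glucose")]
               if "glucose" in model.parameter_subset else np.zeros(model.k))
    sizes = model.cluster_sizes
    order = sorted(range(model.k),
                   key=lambda c: (composite[c], glucose[c], -sizes[c]))
    relabel = np.empty(model.k, dtype=int)
    relabel[order] = np.arange(model.k)  # old cluster -> new 0-based label

    return replace(
        model,
        per_imputation_centroids=model.per_imputation_centroids[:, order, :],
        per_imputation_labels=relabel[model.per_imputation_labels - 1] + 1,
        consensus_assignment=relabel[model.consensus_assignment - 1] + 1,
        centroids=model.centroids[order],
        ordering_scores=composite[order])


def enumerate_models(pool: tuple[str, ...], min_size: int = 3,
                     explicit: list[tuple[str, ...]] | None = None,
                     ) -> list[tuple[int, tuple[str, ...]]]:
    """Candidate parameter subsets with stable model ids.

    With ``explicit`` given, validates uniqueness and pool membership and
    returns the list verbatim; otherwise enumerates every subset of the pool
    with size in ``[min_size, len(pool)]`` in deterministic lexicographic
    order of (size, subset).
    """
    pool = tuple(pool)
    if not pool:
        raise ValueError("parameter pool is empty")
    if explicit is not None:
        seen = set()
        for subset in explicit:
            key = frozenset(subset)
            if key in seen:
                raise ValueError(f"duplicate subset in explicit list: {subset}")
            if len(key) != len(subset):
                raise ValueError(f"subset has repeated parameters: {subset}")
            seen.add(key)
            missing = set(subset) - set(pool)
            if missing:
                raise ValueError(f"subset parameters not in pool: {sorted(missing)}")
        return [(i + 1, tuple(s)) for i, s in enumerate(explicit)]
    if min_size > len(pool):
        raise ValueError("min_size exceeds pool size")
    subsets = []
    for size in range(min_size, len(pool) + 1):
        subsets.extend(itertools.combinations(pool, size))
    return [(i + 1, s) for i, s in enumerate(subsets)]


def check_admissible(model: MetabotypeModel, n_total: int,
                     min_fraction: float = 0.05, min_n: int = 150,
                     mode: str = "disjunctive") -> bool:
    """Smallest-cluster admissibility: at least ``min_fraction`` of the cohort
    or at least ``min_n`` participants (disjunctive by default)."""
    smallest = model.smallest_cluster_n
    by_fraction = smallest >= min_fraction * n_total
    by_count = smallest >= min_n
    if mode == "disjunctive":
        return bool(by_fraction or by_count)
    if mode == "conjunctive":
        return bool(by_fraction and by_count)
    raise ValueError("mode must be 'disjunctive' or 'conjunctive'")


def rank_models(models: list[MetabotypeModel], cohort: pd.DataFrame,
                outcome: str, cluster: int | None = None) -> ModelRanking:
    """Rank models by cumulative incidence of ``outcome`` in the unfavorable
    cluster (cluster k unless ``cluster`` is given).

    ``cohort`` must hold the retained participants in the same row order the
    models were fitted on.  Per model, the at-risk set is the cluster's
    members who are outcome-free at baseline, participate in the follow-up
    and have an observed follow-up status.  Ties are broken by larger
    incident count, then fewer parameters, then lexicographic subset.
    """
    if not models:
        raise ValueError("no models to rank")
    status_all = followup_status(cohort, outcome)
    rows = []
    for model in models:
        target = model.k if cluster is None else cluster
        in_cluster = model.consensus_assignment == target
        status = status_all[in_cluster]
        at_risk = int(status.notna().sum())
        if at_risk == 0:
            warnings.warn(f"model {model.model_id}: no at-risk participants in "
                          f"cluster {target}; excluded from ranking")
            continue
        incident = int((status == 1).sum())
        rows.append({"model_id": model.model_id,
                     "parameter_subset": model.parameter_subset,
                     "n_cluster": int(in_cluster.sum()),
                     "at_risk": at_risk, "incident": incident,
                     "incidence": incident / at_risk})
    if not rows:
        raise ValueError("all models were excluded (no at-risk participants)")
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(table)),
        key=lambda i: (-table.loc[i, "incidence"], -table.loc[i, "incident"],
                       len(table.loc[i, "parameter_subset"]),
                       table.loc[i, "parameter_subset"]))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table = table.sort_values("rank").reset_index(drop=True)
    return ModelRanking(outcome=outcome, table=table,
                        best_model_id=int(table.loc[0, "model_id"]))


# -- cluster-number diagnostics --------------------------------------------

def _inertia(X: np.ndarray, k: int, seed) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    return float(KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X).inertia_)


def choose_k(imp: ImputationSet | np.ndarray, subset: tuple[str, ...] | None = None,
             k_range: range = range(2, 9), seed: int | None = None,
             n_refs: int = 50) -> tuple[int, dict[str, int]]:
    """Majority vote over five cluster-number indices on the first imputation.

    Indices: Calinski-Harabasz (max), average silhouette (max),
    Davies-Bouldin (min), Hartigan's rule (first k with H(k) <= 10), and the
    gap statistic with ``n_refs`` uniform-box reference draws (smallest k with
    ``gap(k) >= gap(k+1) - s(k+1)``).  Diagnostic only — the metabotype models
    themselves fix k = 3.
    """
    if isinstance(imp, ImputationSet):
        df = imp.completed[0]
        X = (df[list(subset)] if subset else df).to_numpy(dtype=float)
    else:
        X = np.asarray(imp, dtype=float)
    n = X.shape[0]
    ks = list(k_range)
    if max(ks) > n / 10:
        raise ValueError("k_range exceeds n/10")

    labels = {}
    for k in ks:
        if k >= 2:
            labels[k] = KMeans(n_clusters=k, n_init=10,
                               random_state=seed).fit_predict(X)

    def argbest(score, best=max):
        vals = {k: score(k) for k in ks if k >= 2}
        target = best(vals.values())
        return min(k for k, v in vals.items() if v == target)

    votes = {
        "calinski_harabasz": argbest(lambda k: calinski_harabasz_score(X, labels[k])),
        "silhouette": argbest(lambda k: silhouette_score(X, labels[k])),
        "davies_bouldin": argbest(lambda k: davies_bouldin_score(X, labels[k]),
                                  best=min),
    }

    # Hartigan: H(k) = (W_k / W_{k+1} - 1) (n - k - 1); take the first k where
    # adding a cluster no longer pays (H <= 10), else the elbow of H (the k
    # with the largest drop H(k-1) - H(k); the classic threshold rarely fires
    # at cohort-scale n)
    W = {k: _inertia(X, k, seed) for k in range(min(ks + [2]) - 1, max(ks) + 2)
         if k >= 1}
    H = {k: (W[k] / W[k + 1] - 1.0) * (n - k - 1)
         for k in W if k + 1 in W}
    hartigan_vote = next((k for k in ks if H.get(k, np.inf) <= 10), None)
    if hartigan_vote is None:
        drops = {k: H[k - 1] - H[k] for k in ks if k - 1 in H and k in H}
        hartigan_vote = max(drops, key=drops.get) if drops else max(ks)
    votes["hartigan"] = hartigan_vote

    # gap statistic on a uniform box over the observed feature ranges
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    gap_ks = ks + [max(ks) + 1]
    log_W = {k: np.log(W[k]) for k in gap_ks}
    ref_log_W = {k: [] for k in gap_ks}
    for _ in range(n_refs):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in gap_ks:
            ref_log_W[k].append(np.log(_inertia(ref, k, seed)))
    gap = {k: float(np.mean(ref_log_W[k]) - log_W[k]) for k in gap_ks}
    s = {k: float(np.std(ref_log_W[k], ddof=0) * np.sqrt(1 + 1 / n_refs))
         for k in gap_ks}
    gap_vote = None
    for k in ks:
        if gap[k] >= gap[k + 1] - s[k + 1]:
            gap_vote = k
            break
    votes["gap"] = gap_vote if gap_vote is not None else max(ks)

    counts = pd.Series(list(votes.values())).value_counts()
    top = counts[counts == counts.max()].index.min()
    return int(top), votes
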