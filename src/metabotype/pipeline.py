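"""End-to-end metabotyping workflow.

Chains the stages: exclusions -> chained-equations imputation ->
z-standardization -> variable-importance ranking (three methods) -> top-50%
parameter selection (insulin removed as non-standard) -> candidate-model
enumeration -> consensus k-means per model -> unfavorability ordering ->
admissibility filter -> incidence-based ranking of the admissible models for
each composite outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cluster as mcluster
from . import importance as mimportance
from .preprocess import (ExclusionReport, ImputationSet, apply_exclusions,
                         impute_chained, z_standardize, DEFAULT_PARAMETER_POOL)

__all__ = ["StudyResult", "run_study", "DEFAULT_IMPORTANCE_SETTINGS"]

#: Reduced-size defaults for the supervised importance stage; the
#: full-scale analysis settings are n_trees=500/n_perm=100 (PIMP) and
#: n_folds=10/n_trees=1000/n_perm=100 (CVPVI).
DEFAULT_IMPORTANCE_SETTINGS = {
    "pimp": {"n_trees": 150, "n_perm": 30,
             "rf_params": {"max_features": "sqrt", "max_samples": 0.5}},
    "cvpvi": {"n_folds": 5, "n_trees": 150, "n_perm": 10,
              "rf_params": {"max_features": "sqrt", "max_samples": 0.5}},
    "gbgain": {"n_estimators": 100},
}


@dataclass
class StudyResult:
    retained: pd.DataFrame
    exclusions: ExclusionReport
    imputations: ImputationSet              # standardized
    importance_reports: list
    selection: mimportance.SelectionResult
    models: list                            # admissible, ordered MetabotypeModels
    inadmissible_ids: list[int]
    rankings: dict[str, mcluster.ModelRanking]
    extras: dict = field(default_factory=dict)


def run_study(cohort: pd.DataFrame, seed: int = 0,
              importance_settings: dict | None = None,
              parameters: tuple[str, ...] = DEFAULT_PARAMETER_POOL,
              m: int = 5, iterations: int = 10, k: int = 3,
              min_size: int = 3,
              explicit_subsets: list[tuple[str, ...]] | None = None,
              outcomes: tuple[str, ...] = ("any_metabolic", "any_cvd"),
              nonstandard: frozenset[str] = frozenset({"insulin"}),
              selection_on_empty: str = "vote",
              n_init: int = 25) -> StudyResult:
    """Run the whole metabotype-definition workflow on a cohort table."""
    settings = importance_settings or DEFAULT_IMPORTANCE_SETTINGS

    retained, report = apply_exclusions(cohort, parameters=parameters)
    raw = impute_chained(retained[list(parameters)], m=m, iterations=iterations,
                         seed=seed)
    imp = z_standardize(raw)

    X = imp.completed[0]
    y = mimportance.cluster_outcome_labels(X, k=k, random_state=seed)
    reports = [
        mimportance.PimpImportance(random_state=seed,
                                   **settings["pimp"]).fit(X, y).to_report(),
        mimportance.CVPermutationImportance(random_state=seed,
                                            **settings["cvpvi"]).fit(X, y).to_report(),
        mimportance.GradientBoostGainImportance(
            random_state=seed, **settings["gbgain"]).fit(X, y).to_report(),
    ]
    selection = mimportance.select_parameters(reports, nonstandard=nonstandard,
                                              on_empty=selection_on_empty)
    pool = tuple(selection.clustering_pool)

    models, inadmissible = [], []
    for model_id, subset in mcluster.enumerate_models(pool, min_size=min_size,
                                                      explicit=explicit_subsets):
        model = mcluster.kmeans_consensus(imp, subset, k=k, seed=seed,
                                          n_init=n_init, model_id=model_id)
        model = mcluster.order_clusters(model)
        model.admissible = mcluster.check_admissible(model, n_total=len(retained))
        if model.admissible:
            models.append(model)
        else:
            inadmissible.append(model_id)

    rankings = {outcome: mcluster.rank_models(models, retained, outcome)
                for outcome in outcomes}
    return StudyResult(retained=retained, exclusions=report, imputations=imp,
                       importance_reports=reports, selection=selection,
                       models=models, inadmissible_ids=inadmissible,
                       rankings=rankings)
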