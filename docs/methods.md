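# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic cohort generator does and does not emulate, and
the known limitations.

## Synthetic cohort model

The generator draws a two-wave cohort (baseline plus one follow-up) with a
latent three-group metabolic structure.  Each participant's group
(favorable / intermediate / unfavorable, default mixing proportions
0.40 / 0.48 / 0.12) determines:

* **Parameter locations.** Each of the 14 clinical parameters has a
  per-group arithmetic mean on the natural scale.  Right-skewed analytes
  (TG, insulin, hs-CRP, GGT, GOT, GPT) are drawn log-normally with
  σ² = log(1 + cv²) and μ = log(mean) − σ²/2, so the configured mean is the
  distribution mean; the rest are Gaussian with SD = cv × mean.  Default
  locations follow the cluster-median scale of middle-aged European cohort
  studies (e.g. fasting glucose 89 / 96 / 122 mg/dL, BMI 24.2 / 28.2 / 33.2
  kg/m²).  Default coefficients of variation (4.5%–70% depending on the
  analyte) describe within-group spread; they are deliberately on the
  homogeneous side so that the planted structure is recoverable — a design
  requirement for the recovery tests, not a claim about real biological
  spread.
* **Disease risk.** Six diseases (hypertension, type 2 diabetes,
  dyslipidemia, hyperuricemia/gout, myocardial infarction, stroke) are drawn
  from logistic models with a base log-odds plus additive group effects,
  once at baseline (prevalence) and once at follow-up for baseline-free
  participants (incidence).  Default coefficients produce prevalence and
  incidence gradients across groups on the scale seen in population cohorts
  (e.g. baseline hypertension ≈ 21/43/77% across groups; incident composite
  metabolic disease rising steeply in the unfavorable group).
* **Attrition.** Follow-up participation is Bernoulli per group (defaults
  0.75 / 0.71 / 0.55), giving ≈ 71% overall retention with the heaviest
  dropout in the unfavorable group.

Parameters are conditionally independent given the latent group; an optional
shared "adiposity" factor (`shared_factor_sd > 0`, loading on BMI, insulin,
TG, hs-CRP) adds common variance and is off by default, which keeps the
generator analytically checkable (group means, incidence and retention all
have closed forms).  Missingness is MCAR per parameter cell (default rate
5%, capped at 10%); an optional MAR mode doubles the rate in the top BMI
tertile while preserving the overall rate.  Sex shifts HDLc (−0.10 mmol/L)
and uric acid (+20 µmol/L) for men; age and the social covariates are
group-dependent set dressing and are never consumed by the pipeline.

What the generator does **not** emulate: realistic inter-parameter
correlation within group, survey sampling design, age stratification,
measurement error, informative (disease-dependent) dropout, or per-parameter
missingness patterns.  Tests passing on this generator therefore show that
the pipeline recovers planted group structure and honors its contracts, not
that it would yield the same clusters on real cohort data.

## Preprocessing conventions

* Exclusions run in a fixed order — non-fasting, missing fasting glucose,
  then >10% of the 14 parameters missing — so the report counts are
  well-defined when criteria overlap.
* Chained-equations imputation uses predictive mean matching: per
  incomplete column, a Bayesian linear regression on all other columns
  (flat prior; coefficients drawn from N(β̂, σ²(XᵀX)⁻¹) with σ² drawn from
  the scaled inverse-χ² posterior), prediction of the missing cells with
  the drawn coefficients, and donation of an observed value from one of the
  5 donors with nearest OLS-predicted means.  Columns are visited in order
  of increasing missingness; 10 sweeps per dataset, 5 datasets from
  independent RNG streams spawned from one seed.  Observed cells are never
  modified.  A tiny ridge (1e−8 × tr(XᵀX)/q) stabilizes the normal
  equations against collinearity.
* Standardization uses the sample SD (n−1 denominator), stated explicitly
  because both conventions are common; constants are stored per imputation
  for the inverse transform.

## Variable importance

* The supervised outcome for all three methods defaults to the labels of a
  3-cluster k-means on all 14 standardized parameters of the first
  imputation — selection is self-referential to metabolic structure and
  uses no disease endpoint.  Any label column can be supplied instead.
* PIMP: the permuted-outcome null importances are fitted per variable by
  maximum likelihood within {normal, log-normal, gamma} (the latter two
  with location fixed at 0, covering non-negative importance scores), the
  family with the largest Kolmogorov–Smirnov p-value wins, and
  p = 1 − F̂(observed).  If no family reaches KS p ≥ 0.05, or the null is
  degenerate, the add-one empirical p-value (1 + #{null ≥ obs})/(1 + B) is
  used; it is bounded below by 1/(1+B).
* CVPVI uses stratified folds, misclassification error on the held-out
  fold, and per-column permutation streams keyed by column *name* so that
  scores do not depend on column order.
* Gradient-boosted importance is the variable's total split gain divided by
  the summed gain (fractions sum to 1; variables never split on score 0).
* Importance is computed on the first imputed dataset only; averaging ranks
  across imputations is possible by calling the estimators per dataset.
* Top-half selection takes ⌈p/2⌉ best-ranked variables per method (score
  ties broken alphabetically for determinism), intersects the sets, orders
  the intersection by mean rank, and removes non-standard parameters
  (insulin by default) from the clustering pool while keeping them in the
  report.  An empty intersection raises by default; a majority-vote
  fallback is available via `on_empty="vote"`, and the end-to-end
  `run_study` pipeline opts into that fallback so a single discordant
  method cannot abort a whole study run.

**Limitation — column-order invariance.** Tree libraries break exact split
ties by feature position, so importance scores are not bit-identical under
column permutation (differences up to a few hundredths on small samples).
Forests default to `max_features=None` to remove feature-subsampling order
effects; the remaining tie-break sensitivity is inherent to the tree
implementations and is asserted only up to a tolerance in the tests.

## Consensus clustering and model selection

* k-means uses k-means++ with 25 restarts per imputation; the same seed is
  used for every imputation, so identical inputs give a consensus identical
  to a single run.  Labels of imputations 2..m are aligned to imputation 1
  by the label permutation minimizing total squared centroid distance
  (exhaustive over k! for k ≤ 5, Hungarian assignment above).  Consensus is
  the per-participant majority vote; ties go to the nearest mean-aligned
  centroid of the participant's average imputed vector.
* k is fixed at 3 for all candidate models.  `choose_k` is diagnostic only:
  a majority vote over Calinski–Harabasz, average silhouette,
  Davies–Bouldin, Hartigan's rule and the gap statistic (50 uniform-box
  references).  Hartigan's classic threshold (H ≤ 10) rarely fires at
  cohort-scale n, so the vote falls back to the elbow of H (largest drop);
  the gap statistic uses the "smallest k with gap(k) ≥ gap(k+1) − s(k+1)"
  rule and may vote k = 1 when the range allows it.
* Cluster ordering: composite unfavorability = mean over subset parameters
  of sign × standardized cluster mean, with HDLc signed −1 and every other
  parameter +1.  Exact composite ties are broken by cluster mean glucose,
  then by descending cluster size.
* Clustering always reuses the full-table standardization constants; subset
  columns are not re-standardized (this shifts centroids slightly but keeps
  all models on one scale).
* Admissibility reads "at least 5% or 150 participants in the smallest
  cluster" as a disjunction (either arm suffices); a conjunctive mode is
  available.  Model enumeration is exhaustive over subsets of size ≥ 3 by
  default, with an explicit-list escape hatch for externally specified
  models.
* Ranking: cumulative incidence of the outcome in cluster 3, at-risk =
  cluster-3 members free of every member disease at baseline, participating
  in follow-up, with observed follow-up status.  Ties break by larger
  incident count, then fewer parameters, then lexicographic subset.  Models
  with an empty at-risk cluster 3 are excluded with a warning.

## Evaluation conventions

* Pooled medians/IQRs are computed within each imputation and averaged.
* Continuous group comparisons: Kruskal–Wallis with tie correction, Dunn's
  pairwise z-tests on the pooled ranks (tie-corrected variance) with
  Bonferroni adjustment over the pairs.  Degenerate data (all values equal)
  returns p = 1 with a flag.
* Categorical comparisons: Pearson chi-square without continuity
  correction; when any expected cell is below 5 the test switches to an
  exact test — scipy's Fisher test for 2×2, full Freeman–Halton enumeration
  when the margin-constrained table space is small enough, and a seeded
  Monte Carlo version of the same test (20,000 tables drawn with fixed
  margins) for large tables.
* Composite outcomes ("any metabolic" = hypertension ∨ T2D ∨ dyslipidemia ∨
  hyperuricemia; "any cardiovascular" = MI ∨ stroke) are positive if any
  member is positive, negative if all members are observed negative, and
  missing otherwise.  Prevalence supports both denominator conventions
  (all participants, or complete cases) because they differ when flags are
  missing; denominators are always emitted.

## Problem sizes used in the test and acceptance runs

Simulation-based checks are scaled to run on one CPU: PIMP
calibration/power uses 10-tree forests on 30% subsamples (calibration is
invariant to ensemble size since true and null importances come from
identically configured forests) with 200 null replicates at n = 1000,
p = 14, 50 permutations; the default-cohort recovery check uses the full
n = 3001, m = 5 settings; the workflow's importance stage defaults to
reduced settings (150 trees / 30 permutations for PIMP; 5 folds,
150 trees, 10 permutations for CVPVI), with the full-scale analysis
settings (500 trees / 100 permutations; 10 folds / 1000 trees / 100
permutations) reachable through the estimator parameters.

## Known limitations

* The pipeline's clusters on synthetic data inherit the generator's
  simplifications; no claim is made about cluster composition on real data.
* PIMP's parametric null can be slightly anti-conservative when the chosen
  family misfits the extreme tail; the empirical fallback bounds p away
  from 0 at 1/(1+B).
* The Monte Carlo exact test returns a resampling p-value (add-one
  estimator), not the exact tail probability, on large sparse tables.
* Incidence is cumulative over a single follow-up wave; no time-to-event
  modeling, no age/sex adjustment, and no risk-prediction modeling.
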