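"""Consensus k-means, cluster ordering, model enumeration, admissibility
and incidence-based ranking."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from metabotype.cluster import (DEFAULT_RISK_DIRECTIONS, ConsensusKMeans,
                                MetabotypeModel, RiskDirection, check_admissible,
                                choose_k, enumerate_models, kmeans_consensus,
                                order_clusters, rank_models)
from metabotype.preprocess import (ImputationSet, apply_exclusions,
                                   impute_chained, z_standardize)
from metabotype.simulate import PARAMETERS, GeneratorConfig, generate_cohort

from conftest import planted_blobs


def _imp_set(matrices, cols=None):
    cols = cols or [f"x{j}" for j in range(matrices[0].shape[1])]
    return ImputationSet(completed=[pd.DataFrame(m, columns=cols)
                                    for m in matrices], iterations=0, seed=0)


def _model_from_labels(labels, k=3, model_id=1, subset=("glucose", "hdlc")):
    labels = np.asarray(labels)
    cents = np.zeros((k, len(subset)))
    return MetabotypeModel(model_id=model_id, parameter_subset=tuple(subset),
                           k=k, per_imputation_centroids=cents[None],
                           per_imputation_labels=labels[None],
                           consensus_assignment=labels, centroids=cents)


class TestConsensusKMeans:
    def test_identical_imputations_equal_single_run(self):
        X, _ = planted_blobs(seed=1)
        est = ConsensusKMeans(n_clusters=3, n_init=10, random_state=0)
        est.fit([X, X, X, X, X])
        single = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert np.array_equal(est.labels_, single.labels_)
        np.testing.assert_allclose(est.cluster_centers_, single.cluster_centers_)
        assert est.inertias_[0] == pytest.approx(single.inertia_)

    def test_consensus_partition_invariant_to_imputation_order(self):
        rng = np.random.default_rng(3)
        X, _ = planted_blobs(seed=2)
        mats = [X + rng.normal(0, 0.05, X.shape) for _ in range(5)]
        a = ConsensusKMeans(random_state=0).fit(mats).labels_
        b = ConsensusKMeans(random_state=0).fit(mats[::-1]).labels_
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_alignment_recovers_permuted_centroids(self):
        from metabotype.cluster import _align_labels
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(4, 3)) * 5
        perm = np.array([2, 0, 3, 1])
        centers = ref[perm]
        got = _align_labels(ref, centers)
        np.testing.assert_array_equal(centers[got], ref)

    def test_hungarian_alignment_for_many_clusters(self):
        from metabotype.cluster import _align_labels
        rng = np.random.default_rng(5)
        ref = rng.normal(size=(7, 3)) * 5
        perm = rng.permutation(7)
        got = _align_labels(ref, ref[perm])
        np.testing.assert_array_equal(ref[perm][got], ref)

    def test_planted_structure_recovered_with_missingness(self):
        cfg = GeneratorConfig(n_participants=900, seed=21)
        df = generate_cohort(cfg)
        retained, _ = apply_exclusions(df)
        imp = z_standardize(impute_chained(retained[list(PARAMETERS)], m=5,
                                           iterations=5, seed=1))
        model = kmeans_consensus(imp, PARAMETERS, k=3, seed=0)
        ari = adjusted_rand_score(retained["latent_group"],
                                  model.consensus_assignment)
        assert ari > 0.9

    def test_cluster_sizes_partition_participants(self):
        X, _ = planted_blobs(n_per=60, seed=6)
        model = kmeans_consensus(_imp_set([X, X]), subset=("x0", "x1"), k=3,
                                 seed=0)
        assert model.cluster_sizes.sum() == X.shape[0]
        assert set(np.unique(model.consensus_assignment)) == {1, 2, 3}

    def test_subset_must_have_two_parameters(self):
        X, _ = planted_blobs(n_per=30)
        with pytest.raises(ValueError, match="at least 2"):
            kmeans_consensus(_imp_set([X]), subset=("x0",))


class TestOrderClusters:
    def test_hand_computed_composites(self):
        model = _model_from_labels(np.array([1, 2, 3, 3]), subset=("glucose", "hdlc"))
        # (glucose, HDLc) standardized means per cluster
        model.centroids = np.array([[0.0, 0.0], [1.0, -1.0], [-1.0, 1.0]])
        ordered = order_clusters(model)
        np.testing.assert_allclose(ordered.ordering_scores, [-1.0, 0.0, 1.0])
        # old cluster 3 (composite -1) becomes 1; old 1 -> 2; old 2 -> 3
        np.testing.assert_array_equal(ordered.consensus_assignment, [2, 3, 1, 1])

    def test_ordering_invariant_to_input_relabeling(self):
        rng = np.random.default_rng(7)
        labels = rng.integers(1, 4, 50)
        model = _model_from_labels(labels)
        model.centroids = np.array([[0.5, -0.5], [-1.2, 1.1], [2.0, -1.5]])
        ordered = order_clusters(model)
        perm = np.array([3, 1, 2])  # relabel clusters before ordering
        relabeled = _model_from_labels(perm[labels - 1])
        relabeled.centroids = model.centroids[np.argsort(perm)]
        ordered2 = order_clusters(relabeled)
        np.testing.assert_array_equal(ordered.consensus_assignment,
                                      ordered2.consensus_assignment)
        np.testing.assert_allclose(ordered.ordering_scores, ordered2.ordering_scores)

    def test_recovered_unfavorable_cluster_has_high_glucose_low_hdl(self):
        cfg = GeneratorConfig(n_participants=800, seed=31, missing_rate=0.0,
                              nonfasting_rate=0.0)
        df = generate_cohort(cfg)
        imp = z_standardize(impute_chained(df[list(PARAMETERS)], m=1, seed=0))
        model = order_clusters(kmeans_consensus(imp, PARAMETERS, k=3, seed=0))
        gl = model.centroids[:, PARAMETERS.index("glucose")]
        hd = model.centroids[:, PARAMETERS.index("hdlc")]
        assert gl[2] == gl.max() and hd[2] == hd.min()

    def test_sign_vector_validation(self):
        with pytest.raises(ValueError):
            RiskDirection({"glucose": 2})
        assert DEFAULT_RISK_DIRECTIONS["hdlc"] == -1


class TestEnumeration:
    def test_pool_of_six_min_three_gives_42_subsets(self):
        pool = ("tg", "bmi", "uric_acid", "glucose", "hdlc", "non_hdlc")
        models = enumerate_models(pool, min_size=3)
        assert len(models) == 42  # 20 + 15 + 6 + 1
        assert len({mid for mid, _ in models}) == 42
        assert models == enumerate_models(pool, min_size=3)  # deterministic

    def test_explicit_subsets_returned_verbatim(self):
        pool = ("tg", "bmi", "uric_acid", "glucose", "hdlc", "non_hdlc")
        explicit = [("glucose", "bmi", "uric_acid", "hdlc", "non_hdlc"),
                    ("glucose", "tg", "hdlc", "non_hdlc")]
        models = enumerate_models(pool, explicit=explicit)
        assert models == [(1, explicit[0]), (2, explicit[1])]

    def test_duplicate_and_foreign_subsets_rejected(self):
        pool = ("a", "b", "c")
        with pytest.raises(ValueError, match="duplicate"):
            enumerate_models(pool, explicit=[("a", "b"), ("b", "a")])
        with pytest.raises(ValueError, match="not in pool"):
            enumerate_models(pool, explicit=[("a", "z")])

    def test_min_size_equal_pool_gives_single_subset(self):
        pool = ("a", "b", "c", "d")
        assert enumerate_models(pool, min_size=4) == [(1, pool)]


class TestAdmissibility:
    @pytest.mark.parametrize("sizes,n_total,expected", [
        ((1189, 1440, 372), 3001, True),    # 372 >= 150 and >= 5%
        ((1400, 1452, 149), 3001, False),   # fails both arms
        ((1000, 849, 151), 2000, True),     # 151 >= 150 even though > 5% too
        ((1860, 91, 49), 2000, False),
    ])
    def test_disjunctive_rule(self, sizes, n_total, expected):
        labels = np.repeat([1, 2, 3], sizes)
        model = _model_from_labels(labels)
        assert check_admissible(model, n_total=n_total) is expected

    def test_conjunctive_mode(self):
        labels = np.repeat([1, 2, 3], (1000, 849, 151))
        model = _model_from_labels(labels)
        assert check_admissible(model, n_total=3400, mode="conjunctive") is False
        assert check_admissible(model, n_total=3400) is True


def _ranking_cohort(n, cluster3_mask, incident_mask):
    """Cohort where everyone is at risk; ``incident_mask`` marks incident
    composite-metabolic cases (via hypertension)."""
    df = pd.DataFrame(index=range(n))
    df["in_followup"] = True
    for dz in ("hypertension", "t2d", "dyslipidemia", "hyperuricemia", "mi",
               "stroke"):
        df[f"baseline_{dz}"] = 0.0
        df[f"followup_{dz}"] = 0.0
    df.loc[incident_mask, "followup_hypertension"] = 1.0
    return df


class TestRanking:
    def test_rank_by_cluster3_incidence(self):
        n = 300
        labels_a = np.array([1] * 100 + [2] * 100 + [3] * 100)
        rng = np.random.default_rng(0)
        incident = np.zeros(n, bool)
        incident[200:262] = True  # 62% incidence in cluster 3 of model A
        cohort = _ranking_cohort(n, labels_a == 3, incident)
        model_a = _model_from_labels(labels_a, model_id=1)
        labels_b = np.roll(labels_a, 100)  # cluster 3 catches 30 cases only
        incident_b = (labels_b == 3) & incident
        model_b = _model_from_labels(labels_b, model_id=2)
        ranking = rank_models([model_a, model_b], cohort, "any_metabolic")
        assert ranking.best_model_id == 1
        tbl = ranking.table.set_index("model_id")
        assert tbl.loc[1, "rank"] == 1 and tbl.loc[2, "rank"] == 2
        assert tbl.loc[1, "incidence"] == pytest.approx(0.62)

    def test_tie_broken_by_fewer_parameters(self):
        n = 60
        labels = np.repeat([1, 2, 3], 20)
        incident = labels == 3
        cohort = _ranking_cohort(n, labels == 3, incident)
        big = _model_from_labels(labels, model_id=1,
                                 subset=("glucose", "hdlc", "tg"))
        small = _model_from_labels(labels, model_id=2, subset=("glucose", "hdlc"))
        ranking = rank_models([big, small], cohort, "any_metabolic")
        assert ranking.best_model_id == 2  # fewer parameters wins the tie

    def test_zero_at_risk_model_excluded_with_warning(self):
        n = 40
        labels = np.repeat([1, 2, 3], [15, 15, 10])
        cohort = _ranking_cohort(n, labels == 3, np.zeros(n, bool))
        cohort.loc[labels == 3, "baseline_t2d"] = 1.0  # cluster 3 never at risk
        good = _model_from_labels(np.repeat([1, 2, 3], [10, 15, 15]), model_id=7)
        bad = _model_from_labels(labels, model_id=8)
        with pytest.warns(UserWarning, match="model 8"):
            ranking = rank_models([good, bad], cohort, "any_metabolic")
        assert set(ranking.table["model_id"]) == {7}

    def test_structured_model_outranks_noise_model(self):
        """Clustering on the real parameters finds the high-risk latent group;
        clustering on pure noise cannot, so it ranks below."""
        wins = 0
        for seed in range(10):
            cfg = GeneratorConfig(n_participants=500, seed=seed,
                                  missing_rate=0.0, nonfasting_rate=0.0,
                                  disease_flag_missing_rate=0.0)
            df = generate_cohort(cfg)
            imp = z_standardize(impute_chained(df[list(PARAMETERS)], m=1, seed=seed))
            real = order_clusters(kmeans_consensus(imp, PARAMETERS, k=3,
                                                   seed=seed, model_id=1))
            rng = np.random.default_rng(seed + 1000)
            noise = pd.DataFrame(rng.normal(size=(len(df), 2)),
                                 columns=["n0", "n1"])
            noise_imp = ImputationSet(completed=[noise], iterations=0, seed=0)
            null = order_clusters(kmeans_consensus(noise_imp, ("n0", "n1"),
                                                   k=3, seed=seed, model_id=2),
                                  directions=RiskDirection({"n0": 1, "n1": 1}))
            ranking = rank_models([real, null], df, "any_metabolic")
            wins += ranking.best_model_id == 1
        assert wins >= 9


class TestChooseK:
    def test_three_separated_blobs_unanimous(self):
        X, _ = planted_blobs(n_per=120, sep=8.0, seed=8)
        k, votes = choose_k(X, k_range=range(2, 7), seed=0, n_refs=20)
        assert k == 3
        assert all(v == 3 for v in votes.values())

    def test_two_blobs_majority_two(self):
        X, _ = planted_blobs(n_per=150, k=2, sep=8.0, seed=9)
        k, votes = choose_k(X, k_range=range(2, 6), seed=0, n_refs=20)
        assert k == 2

    def test_single_blob_gap_votes_one_and_majority_stays_small(self):
        """Null structure: the gap statistic always votes k=1 when allowed,
        and the majority does not confidently favor many clusters."""
        rng = np.random.default_rng(10)
        small = 0
        for seed in range(3):
            X = rng.normal(size=(600, 4))
            k, votes = choose_k(X, k_range=range(1, 6), seed=seed, n_refs=15)
            assert votes["gap"] == 1
            small += k < 4
        assert small >= 2

    def test_k_range_guard(self):
        X, _ = planted_blobs(n_per=10)
        with pytest.raises(ValueError, match="n/10"):
            choose_k(X, k_range=range(2, 20), seed=0)
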