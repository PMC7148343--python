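"""Normalization, UPGMA, random-forest transfer, and direction overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alismoke import (
    ExpressionMatrix,
    bh_adjust,
    direction_overlap,
    fit_linear_de,
    join_and_cluster,
    minmax_normalize,
    rank_features_by_correlation,
    rf_classify_cv,
    select_signature,
    upgma_cluster,
)
from alismoke.expression import DEResult
from alismoke.transfer import ablate_and_reclassify


def expr(values: dict, ids=None, condition=None, donor=None):
    df = pd.DataFrame(values)
    if ids is not None:
        df.index = ids
    samples = list(df.columns)
    meta = pd.DataFrame(
        {
            "condition": condition or ["x"] * len(samples),
            "donor": donor or samples,
        },
        index=samples,
    )
    return ExpressionMatrix(values=df, metadata=meta)


class TestMinMaxNormalize:
    def test_hand_example(self):
        m = expr({"s1": [2.0], "s2": [4.0], "s3": [6.0]})
        norm = minmax_normalize(m)
        np.testing.assert_allclose(norm.values.iloc[0], [0.0, 0.5, 1.0])

    def test_constant_row_all_zero(self):
        m = expr({"s1": [3.0], "s2": [3.0]})
        norm = minmax_normalize(m)
        np.testing.assert_array_equal(norm.values.iloc[0], [0.0, 0.0])

    def test_idempotent_on_non_constant_rows(self):
        rng = np.random.default_rng(1)
        m = expr({f"s{i}": rng.normal(size=5) for i in range(6)})
        once = minmax_normalize(m)
        twice = minmax_normalize(ExpressionMatrix(once.values, m.metadata))
        pd.testing.assert_frame_equal(once.values, twice.values)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_order_preserved(self, row):
        m = expr({f"s{i}": [v] for i, v in enumerate(row)})
        norm = minmax_normalize(m).values.iloc[0]
        assert list(norm.index) == [f"s{i}" for i in range(len(row))]
        if len(set(row)) > 1:
            assert norm.min() == 0.0 and norm.max() == 1.0
        assert ((norm >= 0) & (norm <= 1)).all()


def naive_upgma(dist, labels):
    """Brute-force UPGMA: recompute average inter-cluster distances from
    scratch at every step; merge the closest pair (smallest index on ties)."""
    clusters = {i: [i] for i in range(len(labels))}
    heights = []
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((sorted(clusters[a] + clusters[b]), d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def correlation_distance(data):
    r = np.corrcoef(data)
    return 1.0 - r


class TestUPGMA:
    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=6)
        m = expr({"a": base, "b": base, "c": rng.normal(size=6), "d": rng.normal(size=6)})
        result = upgma_cluster(m.values, axis="columns")
        Z = result.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {result.labels[int(Z[0, 0])], result.labels[int(Z[0, 1])]}
        assert first == {"a", "b"}

    def test_anticorrelated_pair_distance_two(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = expr({"up": x, "down": -x, "noise": np.array([0.5, 3.0, 1.0, 2.0])})
        result = upgma_cluster(m.values, axis="columns")
        # up and down merge last: the root joins them at the maximum height
        Z = result.linkage_matrix
        assert Z[-1, 2] > Z[0, 2]
        i, j = int(Z[0, 0]), int(Z[0, 1])
        assert {result.labels[i], result.labels[j]} != {"up", "down"}

    @pytest.mark.parametrize("n_leaves", [3, 4, 5, 6])
    def test_matches_naive_oracle(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        data = rng.normal(size=(n_leaves, 12))
        labels = [f"L{i}" for i in range(n_leaves)]
        m = pd.DataFrame(data.T, columns=labels)
        result = upgma_cluster(m, axis="columns")
        dist = correlation_distance(data)
        np.fill_diagonal(dist, 0.0)
        expected = naive_upgma(dist, labels)
        Z = result.linkage_matrix
        # reconstruct member sets of every scipy merge
        members = {i: [i] for i in range(n_leaves)}
        for k in range(Z.shape[0]):
            a, b, height, _ = Z[k]
            merged = sorted(members[int(a)] + members[int(b)])
            members[n_leaves + k] = merged
            exp_members, exp_height = expected[k]
            assert merged == exp_members
            assert height == pytest.approx(exp_height, abs=1e-10)

    def test_zero_variance_leaf_warns_distance_one(self):
        m = expr({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0], "y": [3.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            result = upgma_cluster(m.values, axis="columns")
        assert result.linkage_matrix.shape == (2, 4)

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError, match="two leaves"):
            upgma_cluster(pd.DataFrame({"only": [1.0, 2.0]}), axis="columns")

    def test_newick_roundtrip_leaf_names(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(8, 4)), columns=["w", "x", "y", "z"])
        nwk = upgma_cluster(m, axis="columns").to_newick()
        for name in ("w", "x", "y", "z"):
            assert name in nwk


def de_from_table(ids, q, lfc):
    table = pd.DataFrame(
        {"log_fold_change": lfc, "p_value": q, "q_value": q,
         "direction": np.sign(lfc).astype(int)},
        index=pd.Index(ids),
    )
    return DEResult(table=table, contrast=("a", "b"))


class TestJoinAndCluster:
    def test_concordant_cohorts_cocluster_by_exposure(self, concordant_cohorts):
        invitro, invivo, _ = concordant_cohorts
        de_a = fit_linear_de(invitro, contrast=("smoke", "air"))
        de_b = fit_linear_de(invivo, contrast=("smoker", "nonsmoker"))
        joined, clustering = join_and_cluster(de_a, de_b, invitro, invivo, q_cut=0.05)
        from sklearn.metrics import adjusted_rand_score

        truth = [
            "exposed" if (s.endswith("_smoke") or ("_smoker" in s) or s.startswith("VV_smoker"))
            else "control"
            for s in joined.values.columns
        ]
        cut = clustering.cut(2)
        ari = adjusted_rand_score(truth, [cut[s] for s in joined.values.columns])
        assert ari > 0.8

    def test_per_dataset_normalization_removes_platform_shift(self, concordant_cohorts):
        invitro, invivo, _ = concordant_cohorts
        de_a = fit_linear_de(invitro, contrast=("smoke", "air"))
        de_b = fit_linear_de(invivo, contrast=("smoker", "nonsmoker"))
        joined, _ = join_and_cluster(de_a, de_b, invitro, invivo, q_cut=0.05)
        vals = joined.values.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_disjoint_significant_sets_rejected(self):
        de_a = de_from_table(["t1", "t2"], [0.01, 0.9], [1.0, 1.0])
        de_b = de_from_table(["t1", "t2"], [0.9, 0.01], [1.0, 1.0])
        m = expr({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, ids=["t1", "t2"])
        with pytest.raises(ValueError, match="no transcript"):
            join_and_cluster(de_a, de_b, m, m, q_cut=0.05)

    def test_single_shared_transcript_degenerate(self):
        de_a = de_from_table(["t1", "t2"], [0.01, 0.9], [1.0, 1.0])
        de_b = de_from_table(["t1", "t2"], [0.01, 0.9], [1.0, 1.0])
        m1 = expr({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, ids=["t1", "t2"])
        m2 = expr({"u1": [5.0, 0.0], "u2": [9.0, 1.0]}, ids=["t1", "t2"])
        joined, clustering = join_and_cluster(de_a, de_b, m1, m2, q_cut=0.05)
        assert joined.values.shape == (1, 4)
        assert clustering is None


def labeled_matrix(rng, n_samples=30, n_features=20, n_informative=0, shift=2.0):
    """Binary-labeled expression-like matrix; first n_informative rows separate."""
    labels = pd.Series(
        ["pos"] * (n_samples // 2) + ["neg"] * (n_samples - n_samples // 2),
        index=[f"s{i}" for i in range(n_samples)],
    )
    data = rng.normal(size=(n_features, n_samples))
    for i in range(n_informative):
        data[i, (labels == "pos").to_numpy()] += shift
    values = pd.DataFrame(data, index=[f"f{i:03d}" for i in range(n_features)],
                          columns=labels.index)
    return values, labels


class TestRandomForest:
    def test_permutation_null_auc_near_half(self):
        # label permutation destroys signal: mean out-of-fold AUC ~ 0.5
        rng = np.random.default_rng(0)
        values, labels = labeled_matrix(rng, n_samples=30, n_features=15, n_informative=5)
        aucs = []
        for rep in range(50):
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            rep_auc = rf_classify_cv(
                values, permuted, folds=5, n_trees=25, seed=1000 + rep
            ).auc
            aucs.append(rep_auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_separable_cohorts_auc_high(self):
        rng = np.random.default_rng(1)
        values, labels = labeled_matrix(rng, n_samples=40, n_features=30,
                                        n_informative=15, shift=3.0)
        report = rf_classify_cv(values, labels, folds=5, n_trees=50, seed=3)
        assert report.auc >= 0.95

    def test_single_perfect_feature_auc_one(self):
        labels = pd.Series(["a"] * 10 + ["b"] * 10, index=[f"s{i}" for i in range(20)])
        values = pd.DataFrame(
            {s: [1.0 if lab == "b" else 0.0] for s, lab in labels.items()},
            index=["oracle_feature"],
        )
        report = rf_classify_cv(values, labels, folds=5, n_trees=25, seed=0)
        assert report.auc == pytest.approx(1.0)

    def test_fold_degradation_to_leave_one_out(self):
        rng = np.random.default_rng(2)
        values, labels = labeled_matrix(rng, n_samples=12, n_features=5, n_informative=2)
        report = rf_classify_cv(values, labels, folds=50, n_trees=10, seed=0)
        assert "leave-one-out" in report.cv_scheme

    def test_one_class_rejected(self):
        rng = np.random.default_rng(3)
        values, labels = labeled_matrix(rng, n_samples=10, n_features=4)
        with pytest.raises(ValueError, match="two classes"):
            rf_classify_cv(values, pd.Series("same", index=labels.index), folds=3)

    def test_seeded_determinism_and_confusion_total(self):
        rng = np.random.default_rng(4)
        values, labels = labeled_matrix(rng, n_samples=24, n_features=10, n_informative=4)
        a = rf_classify_cv(values, labels, folds=4, n_trees=30, seed=11)
        b = rf_classify_cv(values, labels, folds=4, n_trees=30, seed=11)
        assert a.auc == b.auc
        np.testing.assert_array_equal(a.confusion_matrix, b.confusion_matrix)
        np.testing.assert_array_equal(a.roc_points, b.roc_points)
        assert a.confusion_matrix.sum() == 24


class TestFeatureRanking:
    def test_label_feature_ranks_first(self):
        labels = pd.Series(["n", "n", "p", "p"], index=["s1", "s2", "s3", "s4"])
        values = pd.DataFrame(
            {"s1": [0.0, 5.0], "s2": [0.0, 2.0], "s3": [1.0, 4.0], "s4": [1.0, 1.0]},
            index=["is_label", "noise"],
        )
        ranking = rank_features_by_correlation(values, labels)
        assert ranking.iloc[0]["feature"] == "is_label"
        assert ranking.iloc[0]["score"] == pytest.approx(1.0)

    def test_noise_feature_scores_low(self):
        rng = np.random.default_rng(5)
        values, labels = labeled_matrix(rng, n_samples=400, n_features=1)
        ranking = rank_features_by_correlation(values, labels)
        assert ranking["score"].iloc[0] < 0.15

    def test_duplicated_feature_tie_broken_by_id(self):
        labels = pd.Series(["n", "n", "p", "p"], index=["s1", "s2", "s3", "s4"])
        row = [0.1, 0.4, 0.9, 0.7]
        values = pd.DataFrame(
            [row, row], index=["zz_copy", "aa_copy"], columns=labels.index
        )
        ranking = rank_features_by_correlation(values, labels)
        assert list(ranking["feature"]) == ["aa_copy", "zz_copy"]


class TestAblation:
    def test_zero_removal_identical_report(self):
        rng = np.random.default_rng(6)
        values, labels = labeled_matrix(rng, n_samples=20, n_features=12, n_informative=4)
        sig = list(values.index)
        full, reduced = ablate_and_reclassify(
            values, labels, sig, k_remove=0, folds=4, n_trees=20, seed=5
        )
        assert full.auc == reduced.auc
        np.testing.assert_array_equal(full.confusion_matrix, reduced.confusion_matrix)

    def test_redundant_signal_robust_to_top10_removal(self):
        # signal spread over many correlated features: removing the top 10
        # barely moves the AUC
        rng = np.random.default_rng(7)
        values, labels = labeled_matrix(
            rng, n_samples=40, n_features=100, n_informative=100, shift=1.5
        )
        sig = list(values.index)
        full, reduced = ablate_and_reclassify(
            values, labels, sig, k_remove=10, folds=5, n_trees=50, seed=8
        )
        assert full.auc >= 0.95
        assert full.auc - reduced.auc < 0.05

    def test_concentrated_signal_collapses_after_removal(self):
        # all signal in exactly 10 features: removing them leaves noise
        rng = np.random.default_rng(8)
        values, labels = labeled_matrix(
            rng, n_samples=40, n_features=60, n_informative=10, shift=4.0
        )
        sig = list(values.index)
        full, reduced = ablate_and_reclassify(
            values, labels, sig, k_remove=10, folds=5, n_trees=50, seed=9
        )
        assert full.auc >= 0.95
        assert abs(reduced.auc - 0.5) < 0.2

    def test_removing_whole_signature_rejected(self):
        rng = np.random.default_rng(9)
        values, labels = labeled_matrix(rng, n_samples=10, n_features=5)
        with pytest.raises(ValueError, match="empty the signature"):
            ablate_and_reclassify(values, labels, list(values.index), k_remove=5)


class TestDirectionOverlap:
    def test_identical_tables_fully_consistent(self):
        de = de_from_table(["t1", "t2", "t3"], [0.01, 0.01, 0.2], [1.0, -2.0, 0.5])
        report = direction_overlap(de, de, q_cut=0.05)
        assert report.n_shared == 2
        assert report.consistent_fraction == pytest.approx(1.0)
        assert report.n_only_a == report.n_only_b == 0

    def test_truth_table_fraction_near_086(self, discordant_cohorts):
        invitro, invivo, truth = discordant_cohorts
        de_a = fit_linear_de(invitro, contrast=("smoke", "air"))
        de_b = fit_linear_de(invivo, contrast=("smoker", "nonsmoker"))
        report = direction_overlap(de_a, de_b, q_cut=0.05)
        assert report.n_shared >= 40
        assert report.consistent_fraction == pytest.approx(0.86, abs=0.05)

    def test_zero_lfc_counted_inconsistent_unless_both_zero(self):
        de_a = de_from_table(["t1", "t2"], [0.01, 0.01], [0.0, 0.0])
        de_b = de_from_table(["t1", "t2"], [0.01, 0.01], [1.0, 0.0])
        report = direction_overlap(de_a, de_b, q_cut=0.05)
        assert report.n_consistent == 1  # only the double-zero t2

    def test_no_shared_transcripts_fraction_nan(self):
        de_a = de_from_table(["t1"], [0.01], [1.0])
        de_b = de_from_table(["t2"], [0.01], [1.0])
        report = direction_overlap(de_a, de_b, q_cut=0.05)
        assert report.n_shared == 0
        assert np.isnan(report.consistent_fraction)
        assert report.n_only_a == 1 and report.n_only_b == 1

    def test_symmetry_under_swap(self, discordant_cohorts):
        invitro, invivo, _ = discordant_cohorts
        de_a = fit_linear_de(invitro, contrast=("smoke", "air"))
        de_b = fit_linear_de(invivo, contrast=("smoker", "nonsmoker"))
        ab = direction_overlap(de_a, de_b, q_cut=0.05)
        ba = direction_overlap(de_b, de_a, q_cut=0.05)
        assert ab.n_shared == ba.n_shared
        assert ab.n_consistent == ba.n_consistent
        assert ab.n_only_a == ba.n_only_b
        assert ab.n_only_b == ba.n_only_a
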