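"""Metric oracles: brute-force AMI/V-measure/LISI, exhaustive rank-sum U,
hand-computed GSEA running sums, and confusion-matrix accuracy arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from omicbridge.evaluation import (accuracy_from_confusion,
                                   adjusted_mutual_information,
                                   build_marker_sets, clustering_scores, lisi,
                                   nes_confusion_matrix, preranked_gsea,
                                   rank_features, stratified_split,
                                   NESConfusionMatrix, _enrichment_score)


# ---------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------

def brute_force_ami(a, b):
    """AMI from the exact expected-MI summation under the permutation model."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    cats_a, ai = np.unique(a, return_inverse=True)
    cats_b, bi = np.unique(b, return_inverse=True)
    R, C = len(cats_a), len(cats_b)
    cont = np.zeros((R, C))
    for i, j in zip(ai, bi):
        cont[i, j] += 1
    arow, bcol = cont.sum(1), cont.sum(0)

    def H(counts):
        p = counts[counts > 0] / n
        return -(p * np.log(p)).sum()

    mi = 0.0
    for i in range(R):
        for j in range(C):
            if cont[i, j] > 0:
                mi += cont[i, j] / n * math.log(n * cont[i, j] / (arow[i] * bcol[j]))

    emi = 0.0
    for i in range(R):
        for j in range(C):
            ai_, bj = int(arow[i]), int(bcol[j])
            lo, hi = max(ai_ + bj - n, 1), min(ai_, bj)
            for nij in range(lo, hi + 1):
                term = nij / n * math.log(n * nij / (ai_ * bj))
                lp = (math.lgamma(ai_ + 1) + math.lgamma(bj + 1)
                      + math.lgamma(n - ai_ + 1) + math.lgamma(n - bj + 1)
                      - math.lgamma(n + 1) - math.lgamma(nij + 1)
                      - math.lgamma(ai_ - nij + 1) - math.lgamma(bj - nij + 1)
                      - math.lgamma(n - ai_ - bj + nij + 1))
                emi += term * math.exp(lp)
    denom = 0.5 * (H(arow) + H(bcol)) - emi
    return (mi - emi) / denom if denom != 0 else 0.0


def brute_force_v(truth, pred):
    truth, pred = np.asarray(truth), np.asarray(pred)
    n = len(truth)

    def H(labels):
        _, c = np.unique(labels, return_counts=True)
        p = c / n
        return -(p * np.log(p)).sum()

    def H_cond(a, b):  # H(a | b)
        total = 0.0
        for vb in np.unique(b):
            mask = b == vb
            _, c = np.unique(a[mask], return_counts=True)
            p = c / mask.sum()
            total += mask.mean() * (-(p * np.log(p)).sum())
        return total

    h = 1.0 if H(truth) == 0 else 1 - H_cond(truth, pred) / H(truth)
    c = 1.0 if H(pred) == 0 else 1 - H_cond(pred, truth) / H(pred)
    v = 0.0 if h + c == 0 else 2 * h * c / (h + c)
    return h, c, v


def brute_force_lisi(embedding, labels, perplexity=30, tol=1e-8):
    """Dense per-cell Simpson index with a plain bisection bandwidth search."""
    n = len(labels)
    cats, codes = np.unique(labels, return_inverse=True)
    D2 = ((embedding[:, None, :] - embedding[None, :, :]) ** 2).sum(-1)
    out = np.empty(n)
    k = min(3 * perplexity, n - 1)
    for i in range(n):
        order = np.argsort(D2[i])
        nb = [j for j in order if j != i][:k]
        d2 = D2[i, nb] - min(D2[i, nb])
        lo, hi = 0.0, 1e12
        for _ in range(200):
            beta = (lo + hi) / 2
            w = np.exp(-beta * d2)
            p = w / w.sum()
            h = -(p[p > 0] * np.log(p[p > 0])).sum()
            if abs(h - np.log(perplexity)) < tol:
                break
            if h > np.log(perplexity):
                lo = beta
            else:
                hi = beta
        probs = np.zeros(len(cats))
        for j, pj in zip(nb, p):
            probs[codes[j]] += pj
        out[i] = 1.0 / (probs ** 2).sum()
    return out


def naive_enrichment_score(metric, membership):
    """Running-sum ES computed with an explicit loop (descending order given)."""
    w = np.abs(np.asarray(metric, dtype=float))
    hits = np.asarray(membership, dtype=bool)
    nh = hits.sum()
    total_w = w[hits].sum()
    running, best = 0.0, 0.0
    for wi, hit in zip(w, hits):
        running += wi / total_w if hit else -1.0 / (len(w) - nh)
        if abs(running) > abs(best):
            best = running
    return best


# ---------------------------------------------------------------------
# partition metrics
# ---------------------------------------------------------------------

class TestAMI:
    def test_identical_partitions_score_one(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        assert adjusted_mutual_information(a, a) == 1.0

    def test_constant_labeling_scores_zero(self):
        assert adjusted_mutual_information(
            np.zeros(6), np.array([1, 1, 2, 2, 3, 3])) == 0.0
        assert adjusted_mutual_information(np.zeros(4), np.zeros(4)) == 0.0

    def test_four_point_example_matches_exact_formula(self):
        a, b = np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2])
        assert np.isclose(adjusted_mutual_information(a, b),
                          brute_force_ami(a, b), atol=1e-8)

    def test_random_small_instances_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 30)
            a = rng.integers(0, 4, n)
            b = rng.integers(0, 3, n)
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            assert np.isclose(adjusted_mutual_information(a, b),
                              brute_force_ami(a, b), atol=1e-8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            adjusted_mutual_information([1, 2], [1, 2, 3])


class TestClusteringScores:
    def test_identical_labelings(self):
        a = np.array([0, 0, 1, 1])
        assert clustering_scores(a, a) == (1.0, 1.0, 1.0)

    def test_singletons_are_homogeneous_not_complete(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.arange(4)
        h, c, v = clustering_scores(truth, pred)
        assert h == pytest.approx(1.0) and c < 1.0

    def test_four_point_example_matches_hand_entropy(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        got = clustering_scores(truth, pred)
        assert np.allclose(got, brute_force_v(truth, pred), atol=1e-12)

    def test_random_small_instances_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(4, 30)
            truth = rng.integers(0, 3, n)
            pred = rng.integers(0, 4, n)
            assert np.allclose(clustering_scores(truth, pred),
                               brute_force_v(truth, pred), atol=1e-8)


class TestLISI:
    def test_single_label_is_exactly_one(self, rng):
        emb = rng.standard_normal((50, 3))
        per_cell, mean = lisi(emb, np.zeros(50))
        assert np.all(per_cell == 1.0) and mean == 1.0

    def test_separated_clouds_give_one(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 1, (200, 2)),
                         rng.normal([1000, 0], 1, (200, 2))])
        labels = np.array(["A"] * 200 + ["B"] * 200)
        _, mean = lisi(emb, labels, perplexity=30)
        assert abs(mean - 1.0) < 1e-6

    def test_interleaved_lattice_approaches_two(self):
        x = np.arange(300, dtype=float).reshape(-1, 1)
        labels = np.array(["a", "b"] * 150)
        _, mean = lisi(np.hstack([x, np.zeros_like(x)]), labels, perplexity=30)
        assert abs(mean - 2.0) < 0.05

    def test_small_instances_match_dense_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            emb = rng.standard_normal((25, 3))
            labels = rng.integers(0, 3, 25)
            per_cell, _ = lisi(emb, labels, perplexity=5)
            oracle = brute_force_lisi(emb, labels, perplexity=5)
            assert np.allclose(per_cell, oracle, atol=1e-6)

    def test_too_few_neighbors_warns_and_uses_all(self, rng):
        emb = rng.standard_normal((20, 2))
        labels = rng.integers(0, 2, 20)
        with pytest.warns(UserWarning, match="neighbors"):
            per_cell, _ = lisi(emb, labels, perplexity=30)
        assert np.all(np.isfinite(per_cell))

    def test_values_within_label_count_bound(self, rng):
        emb = rng.standard_normal((120, 4))
        labels = rng.integers(0, 3, 120)
        per_cell, _ = lisi(emb, labels, perplexity=10)
        assert per_cell.min() >= 1.0 - 1e-12
        assert per_cell.max() <= 3.0 + 1e-12

    def test_mixing_never_decreases_mean_lisi(self):
        x = np.arange(200, dtype=float).reshape(-1, 1)
        emb = np.hstack([x, np.zeros_like(x)])
        blocked = np.repeat(["a", "b"], 100)
        mixed = np.array(["a", "b"] * 100)
        _, m_block = lisi(emb, blocked, perplexity=10)
        _, m_mixed = lisi(emb, mixed, perplexity=10)
        assert m_mixed > m_block


# ---------------------------------------------------------------------
# marker detection
# ---------------------------------------------------------------------

class TestRankFeatures:
    def test_constant_feature_scores_null(self):
        X = np.ones((20, 1))
        labels = np.repeat(["a", "b"], 10)
        t = rank_features(X, labels)
        assert np.all(t["pval"] == 1.0) and np.all(t["lfc"] == 0.0)

    def test_planted_marker_ranks_first_and_significant(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(["a", "b"], 40)
        X = np.abs(rng.standard_normal((80, 20)))
        X[labels == "a", 7] += 5.0
        t = rank_features(X, labels)
        ta = t[t["group"] == "a"].sort_values("lfc", ascending=False)
        assert ta.iloc[0]["feature"] == "feature_7"
        assert ta.iloc[0]["padj"] < 5e-3

    def test_statistic_equals_exhaustive_u_on_ten_cells(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((10, 3))
        X[3] = X[8]  # inject ties across groups
        labels = np.array(["g1"] * 4 + ["g2"] * 6)
        t = rank_features(X, labels)
        for j in range(3):
            # brute-force U: count (in-group, rest) wins + half-ties
            for g, other in [("g1", "g2"), ("g2", "g1")]:
                xin = X[labels == g, j]
                xout = X[labels != g, j]
                u = sum((a > b) + 0.5 * (a == b)
                        for a, b in itertools.product(xin, xout))
                row = t[(t["group"] == g) & (t["feature"] == f"feature_{j}")]
                assert np.isclose(row["statistic"].iloc[0], u)

    def test_pvalues_match_scipy_on_toy(self):
        import scipy.stats
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 4))
        labels = np.repeat(["a", "b"], 15)
        t = rank_features(X, labels)
        for j in range(4):
            ref = scipy.stats.mannwhitneyu(
                X[labels == "a", j], X[labels == "b", j],
                alternative="two-sided", method="asymptotic",
                use_continuity=False)
            row = t[(t["group"] == "a") & (t["feature"] == f"feature_{j}")]
            assert np.isclose(row["pval"].iloc[0], ref.pvalue, atol=1e-10)

    def test_tiny_group_skipped_with_warning(self):
        X = np.random.default_rng(5).standard_normal((11, 2))
        labels = np.array(["a"] * 10 + ["b"])
        with pytest.warns(UserWarning, match="skipped"):
            t = rank_features(X, labels)
        assert set(t["group"]) == {"a"}


class TestMarkerSets:
    def _table(self, lfcs, padjs, group="t0"):
        return pd.DataFrame({
            "group": group,
            "feature": [f"f{i}" for i in range(len(lfcs))],
            "statistic": 0.0, "lfc": lfcs, "pval": padjs, "padj": padjs})

    def test_fewer_survivors_than_top_k_keeps_all(self):
        t = self._table([3.0, 2.0, 1.0], [1e-5, 1e-4, 0.5])
        sets = build_marker_sets(t, top_k=100)
        assert sets.sets["t0"] == ["f0", "f1"]

    def test_boundary_drops_lowest_fold_change(self):
        t = self._table([5.0, 4.0, 3.0, 2.0], [1e-5] * 4)
        sets = build_marker_sets(t, top_k=3)
        assert sets.sets["t0"] == ["f0", "f1", "f2"]

    def test_no_survivors_warns_and_records_empty(self):
        t = self._table([1.0, 2.0], [0.5, 0.9])
        with pytest.warns(UserWarning, match="no significant"):
            sets = build_marker_sets(t)
        assert sets.sets["t0"] == []

    def test_planted_fixture_sets_contain_only_strong_markers(self):
        from omicbridge.simulate import planted_marker_features
        labels = np.array(["t%d" % (i % 2) for i in range(200)])
        X, fids, mmap = planted_marker_features(
            labels, n_markers_per_type=30, n_background=200, effect=4.0, rng=0)
        t = rank_features(X, labels, feature_ids=fids)
        sets = build_marker_sets(t, top_k=30)
        for name in ("t0", "t1"):
            assert set(sets.sets[name]) == set(mmap[name])


class TestPrerankedGSEA:
    def _ranking(self, n=10, seed=0):
        metric = np.linspace(3, -3, n)
        return pd.Series(metric, index=[f"f{i}" for i in range(n)])

    def test_top_features_enrich_positively(self):
        r = self._ranking()
        es, nes, p = preranked_gsea(r, ["f0", "f1", "f2"], n_perm=500, rng=0)
        assert es > 0 and nes > 0

    def test_bottom_features_enrich_negatively(self):
        r = self._ranking()
        es, _, _ = preranked_gsea(r, ["f7", "f8", "f9"], n_perm=500, rng=0)
        assert es < 0

    def test_es_equals_hand_computed_running_sum(self):
        r = self._ranking()
        membership = np.isin(r.index, ["f0", "f3", "f4"])
        oracle = naive_enrichment_score(r.to_numpy(), membership)
        es, _, _ = preranked_gsea(r, ["f0", "f3", "f4"], n_perm=10, rng=0)
        assert es == pytest.approx(oracle, abs=1e-12)

    def test_nes_within_monte_carlo_error_of_high_rep_oracle(self):
        r = self._ranking()
        _, nes_a, _ = preranked_gsea(r, ["f0", "f1", "f4"], n_perm=1000, rng=0)
        _, nes_b, _ = preranked_gsea(r, ["f0", "f1", "f4"], n_perm=100_000, rng=1)
        assert abs(nes_a - nes_b) < 0.1

    def test_empty_intersection_yields_nan(self):
        es, nes, p = preranked_gsea(self._ranking(), ["zz"], n_perm=10, rng=0)
        assert np.isnan(es) and np.isnan(nes)

    def test_deterministic_given_seed(self):
        r = self._ranking()
        a = preranked_gsea(r, ["f0", "f2"], n_perm=200, rng=42)
        b = preranked_gsea(r, ["f0", "f2"], n_perm=200, rng=42)
        assert a == b


class TestConfusionMatrix:
    @pytest.fixture(scope="class")
    def planted(self):
        from omicbridge.simulate import planted_marker_features
        labels = np.array(["t%d" % (i % 3) for i in range(300)])
        X, fids, _ = planted_marker_features(labels, rng=1)
        table = rank_features(X, labels, feature_ids=fids)
        return table, build_marker_sets(table, top_k=100)

    def test_diagonal_strictly_positive_with_train_equals_test(self, planted):
        table, sets = planted
        conf = nes_confusion_matrix(table, sets, n_perm=300, rng=0)
        assert np.all(np.diag(conf.matrix.to_numpy()) > 0)

    def test_empty_marker_set_excluded_with_warning(self, planted):
        table, sets = planted
        from omicbridge.evaluation import MarkerSetCollection
        crippled = MarkerSetCollection(sets={**sets.sets, "t0": []})
        with pytest.warns(UserWarning, match="empty marker set"):
            conf = nes_confusion_matrix(table, crippled, n_perm=100, rng=0)
        assert "t0" not in conf.matrix.index

    def test_nan_free_invariant_enforced(self):
        with pytest.raises(ValueError, match="NaN-free"):
            NESConfusionMatrix(pd.DataFrame([[np.nan]]))


class TestAccuracy:
    def test_clean_diagonal_matrix_scores_one(self):
        m = NESConfusionMatrix(pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]]))
        w, u = accuracy_from_confusion(m)
        assert w == 1.0 and u == 1.0

    def test_zero_diagonal_all_positive_off_scores_zero(self):
        m = NESConfusionMatrix(pd.DataFrame([[0.0, 1.0], [1.0, 0.0]]))
        w, _ = accuracy_from_confusion(m)
        assert w == 0.0

    def test_uniform_positive_matrix_scores_half(self):
        m = NESConfusionMatrix(pd.DataFrame(np.ones((2, 2))))
        w, u = accuracy_from_confusion(m)
        assert w == 0.5 and u == 0.5

    def test_invariant_to_positive_column_scaling(self, rng):
        A = rng.standard_normal((4, 4))
        m1 = NESConfusionMatrix(pd.DataFrame(A))
        m2 = NESConfusionMatrix(pd.DataFrame(A * np.array([1.0, 7.0, 0.3, 2.5])))
        assert np.allclose(accuracy_from_confusion(m1),
                           accuracy_from_confusion(m2))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="square"):
            accuracy_from_confusion(NESConfusionMatrix(pd.DataFrame()))


class TestMarkerSetRoles:
    def test_role_tags_map_to_conventional_sizes(self):
        t = pd.DataFrame({
            "group": "t0", "feature": [f"f{i}" for i in range(600)],
            "statistic": 0.0, "lfc": np.linspace(5, 1, 600),
            "pval": 1e-6, "padj": 1e-6})
        assert len(build_marker_sets(t, top_k="expression").sets["t0"]) == 100
        assert len(build_marker_sets(t, top_k="regions").sets["t0"]) == 500
        with pytest.raises(ValueError, match="role"):
            build_marker_sets(t, top_k="proteins")


class TestLeidenClusters:
    def test_recovers_planted_populations(self, small_study):
        from omicbridge.evaluation import leiden_clusters
        v = small_study.modalities[0]
        clusters = leiden_clusters(v, seed=0)
        assert adjusted_mutual_information(clusters, v.cell_labels) > 0.8
        assert np.array_equal(clusters, leiden_clusters(v, seed=0))


class TestStratifiedSplit:
    def test_partition_is_disjoint_and_stratified(self):
        labels = np.repeat(["a", "b", "c"], 50)
        train, test = stratified_split(labels, test_fraction=0.3, rng=0)
        assert len(set(train) & set(test)) == 0
        assert len(train) + len(test) == 150
        for g in "abc":
            frac = np.isin(np.flatnonzero(labels == g), test).mean()
            assert abs(frac - 0.3) < 0.05

    def test_seeded_split_reproducible(self):
        labels = np.repeat(["a", "b"], 30)
        assert np.array_equal(stratified_split(labels, rng=7)[0],
                              stratified_split(labels, rng=7)[0])
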