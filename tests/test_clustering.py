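"""SNN graph, Louvain, gap-statistic refinement, merging, flags, dendrogram."""

import numpy as np
import pytest
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from conftest import make_count_matrix, nb_counts
from sctrails import clustering, preprocess, synthetic
from sctrails.clustering import (SNNGraph, build_snn_graph, cluster_dendrogram,
                                 flag_contaminant_clusters, flag_doublet_clusters,
                                 gap_statistic, linkage_to_newick, louvain_cluster,
                                 merge_similar_clusters, refine_cluster,
                                 spearman_distance, two_step_cluster)


class TestSNNGraph:
    def test_matches_exhaustive_jaccard(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (15, 2))
        k = 4
        g = build_snn_graph(X, k=k)
        # brute-force kNN sets (self included) by full distance sort
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        sets = [set(np.argsort(D[i], kind="stable")[:k]) for i in range(15)]
        expect = {}
        for i in range(15):
            for j in range(i + 1, 15):
                inter = len(sets[i] & sets[j])
                if inter:
                    expect[(i, j)] = inter / len(sets[i] | sets[j])
        got = {(int(u), int(v)): w for (u, v), w in
               zip(g.edges, g.weights)}
        assert got.keys() == expect.keys()
        for key in expect:
            assert got[key] == pytest.approx(expect[key])

    def test_identical_knn_sets_weight_one(self):
        # two coincident points in a tight pair far from a third blob
        X = np.array([[0, 0], [0, 0], [10, 10], [10, 11], [11, 10], [30, 30]],
                     dtype=float)
        g = build_snn_graph(X, k=2)
        w = {tuple(e): w for e, w in zip(map(tuple, g.edges), g.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)

    def test_no_cross_blob_edges(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, (30, 2))
        b = rng.normal(100, 0.1, (30, 2))
        g = build_snn_graph(np.vstack([a, b]), k=5)
        for (u, v) in g.edges:
            assert (u < 30) == (v < 30)


class TestLouvain:
    def test_disconnected_cliques(self):
        edges = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        edges += [(10 + i, 10 + j) for i in range(10) for j in range(i + 1, 10)]
        g = SNNGraph(n_nodes=20, k=5, edges=np.array(edges),
                     weights=np.ones(len(edges)))
        labels = louvain_cluster(g, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_modularity_nonnegative(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(8, 1, (40, 5))])
        g = build_snn_graph(X, k=10)
        labels = louvain_cluster(g, seed=0)
        ig = g.to_igraph()
        assert ig.modularity(labels, weights="weight") >= 0

    def test_planted_partition_recovery(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_per, k = 50, 4
            truth = np.repeat(np.arange(k), n_per)
            n = n_per * k
            edges, weights = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    p = 0.3 if truth[i] == truth[j] else 0.01
                    if rng.uniform() < p:
                        edges.append((i, j))
                        weights.append(1.0)
            g = SNNGraph(n_nodes=n, k=20, edges=np.array(edges),
                         weights=np.array(weights))
            labels = louvain_cluster(g, seed=seed)
            assert adjusted_rand_score(truth, labels) >= 0.95

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (100, 5))
        g = build_snn_graph(X, k=10)
        assert np.array_equal(louvain_cluster(g, seed=7), louvain_cluster(g, seed=7))


class TestGapStatistic:
    def test_single_blob_selects_one(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            k, _ = gap_statistic(rng.normal(0, 1, (60, 30)), k_max=6, B=50,
                                 seed=seed)
            ok += k == 1
        assert ok >= 9

    def test_three_separated_blobs_select_three(self):
        ok = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            # random per-feature centers, ~10 sigma pairwise separation
            centers = rng.normal(0, 1.35, (3, 30))
            X = np.vstack([rng.normal(c, 1.0, (20, 30)) for c in centers])
            k, _ = gap_statistic(X, k_max=6, B=50, seed=seed)
            ok += k == 3
        assert ok >= 9

    def test_wk_nonincreasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 20))
        _, table = gap_statistic(X, k_max=6, B=5, seed=0)
        assert (np.diff(table["log_w"]) <= 1e-12).all()


class TestRefine:
    def test_three_blobs_recovered(self):
        rng = np.random.default_rng(5)
        centers = rng.normal(0, 1.5, (3, 30))
        X = np.vstack([rng.normal(c, 1.0, (20, 30)) for c in centers])
        labels = refine_cluster(X, k_max=6, B=50, seed=0)
        truth = np.repeat(np.arange(3), 20)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tiny_subset_single_cluster(self):
        assert list(refine_cluster(np.zeros((2, 5)))) == [0, 0]

    def test_average_linkage_heights_monotone(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (40, 15))
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform
        Z = linkage(squareform(spearman_distance(X), checks=False), "average")
        assert (np.diff(Z[:, 2]) >= -1e-12).all()


class TestTwoStep:
    def test_coarse_only_data_rarely_splits(self):
        # homogeneous blobs: refinement should keep the coarse partition in
        # the clear majority of draws (the gap statistic's null behaviour)
        kept = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = np.vstack([rng.normal(0, 1, (60, 30)), rng.normal(12, 1, (60, 30))])
            ca = two_step_cluster(X, k=10, k_max=4, B=50, seed=0)
            kept += ca.cells["refined"].nunique() == ca.cells["coarse"].nunique()
        assert kept >= 4

    def test_partition_conservation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (80, 10))
        ca = two_step_cluster(X, k=10, k_max=3, B=10, seed=0)
        assert len(ca.cells) == 80
        assert ca.cells["final"].notna().all()


class TestMerge:
    @staticmethod
    def _population(rng, n=100, g=400, boost=None):
        base = rng.lognormal(0, 1.2, g)
        mu = base / base.sum() * 2000
        if boost is not None:
            mu = mu.copy()
            mu[:200] *= boost
        return nb_counts(rng, mu, n, phi=0.3), mu

    def test_null_split_is_merged(self):
        merged = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.lognormal(0, 1.2, 400)
            mu = base / base.sum() * 2000
            counts = np.vstack([nb_counts(rng, mu, 100, 0.3),
                                nb_counts(rng, mu, 100, 0.3)])
            sf = counts.sum(1) / counts.sum(1).mean()
            labels = np.array(["a"] * 100 + ["b"] * 100, object)
            final, _ = merge_similar_clusters(labels, counts, sf)
            merged += len(set(final)) == 1
        assert merged >= 9

    def test_distinct_populations_never_merged(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            base = rng.lognormal(0, 1.2, 400)
            mu = base / base.sum() * 2000
            mu2 = mu.copy()
            mu2[:200] *= 8.0  # 200 genes at |log2FC| = 3
            counts = np.vstack([nb_counts(rng, mu, 100, 0.3),
                                nb_counts(rng, mu2, 100, 0.3)])
            sf = counts.sum(1) / counts.sum(1).mean()
            labels = np.array(["a"] * 100 + ["b"] * 100, object)
            final, hist = merge_similar_clusters(labels, counts, sf)
            assert len(set(final)) == 2 and not hist

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(0, 1.2, 300)
        mu = base / base.sum() * 2000
        counts = np.vstack([nb_counts(rng, mu, 60, 0.3),
                            nb_counts(rng, mu, 60, 0.3),
                            nb_counts(rng, mu * np.where(np.arange(300) < 100, 8, 1),
                                      60, 0.3)])
        sf = counts.sum(1) / counts.sum(1).mean()
        labels = np.array(["a"] * 60 + ["b"] * 60 + ["c"] * 60, object)
        final, _ = merge_similar_clusters(labels, counts, sf)
        again, hist = merge_similar_clusters(final, counts, sf)
        assert np.array_equal(final, again) and not hist


class TestContaminantFlags:
    def test_planted_immune_cluster_flagged(self):
        rng = np.random.default_rng(10)
        g = 50
        gene_ids = [f"g{j}" for j in range(g - 3)] + ["Cd74", "Cd72", "Cd54"]
        base = np.abs(rng.normal(1, 0.2, g))
        expr_a = rng.normal(base, 0.1, (40, g))
        boost = base.copy()
        boost[-3:] += 3.0  # immune markers up 8x
        expr_b = rng.normal(boost, 0.1, (40, g))
        labels = np.array(["c0"] * 40 + ["c1"] * 40)
        for third in range(2, 5):  # several background clusters
            expr_a = np.vstack([expr_a, rng.normal(base, 0.1, (40, g))])
            labels = np.concatenate([labels, [f"c{third}"] * 40])
        expr = np.vstack([expr_a[:40], expr_b, expr_a[40:]])
        out = flag_contaminant_clusters(labels, expr, gene_ids,
                                        {"immune": ["Cd74", "Cd72", "Cd54"]})
        assert out.loc["c1", "contaminant"] == "immune"
        assert (out.drop("c1")["contaminant"] == "").all()

    def test_empty_marker_config_no_flags(self):
        out = flag_contaminant_clusters(np.array(["a", "b"]), np.ones((2, 3)),
                                        ["x", "y", "z"], {})
        assert (out["contaminant"] == "").all()

    def test_missing_markers_skipped(self, caplog):
        out = flag_contaminant_clusters(
            np.array(["a"] * 3 + ["b"] * 3), np.ones((6, 2)), ["x", "y"],
            {"immune": ["NotAGene"]})
        assert (out["contaminant"] == "").all()


class TestDoubletFlags:
    @staticmethod
    def _three_pop_counts(rng, n=(300, 300, 30), doublet=True, g=300):
        base = rng.lognormal(0, 1.2, g)
        mu1 = base / base.sum() * 3000
        mu2 = mu1.copy()
        mu2[:80] *= 6
        mu2 = mu1.sum() * mu2 / mu2.sum()
        mu3 = 0.5 * (mu1 + mu2) if doublet else np.roll(mu1, 150)
        counts = np.vstack([nb_counts(rng, m, k, 0.1)
                            for m, k in zip((mu1, mu2, mu3), n)])
        labels = np.array(["c1"] * n[0] + ["c2"] * n[1] + ["c3"] * n[2], object)
        return counts, labels

    def test_planted_doublet_flagged(self):
        rng = np.random.default_rng(11)
        counts, labels = self._three_pop_counts(rng)
        out = flag_doublet_clusters(labels, counts, np.array(["S1"] * len(labels)))
        assert out.loc["c3", "is_doublet"]
        assert set(out.loc["c3", ["parent1", "parent2"]]) == {"c1", "c2"}
        assert out.loc["c3", "rho_pair_mean"] > 0.95
        assert not out.loc[["c1", "c2"], "is_doublet"].any()

    def test_frequency_above_max_rate_never_flagged(self):
        rng = np.random.default_rng(12)
        counts, labels = self._three_pop_counts(rng, n=(300, 300, 80))
        out = flag_doublet_clusters(labels, counts, np.array(["S1"] * len(labels)))
        assert not out["is_doublet"].any()  # 80/680 = 11.8% > 7%

    def test_no_planted_doublets_no_flags(self):
        for seed in range(3):
            rng = np.random.default_rng(20 + seed)
            counts, labels = self._three_pop_counts(rng, doublet=False)
            out = flag_doublet_clusters(labels, counts,
                                        np.array(["S1"] * len(labels)))
            assert not out["is_doublet"].any()


class TestDendrogram:
    def test_identical_means_merge_at_zero(self):
        rng = np.random.default_rng(13)
        profile = rng.normal(2, 1, 100)
        expr = np.vstack([np.tile(profile, (20, 1)),
                          np.tile(profile, (20, 1)),
                          np.tile(rng.normal(2, 1, 100), (20, 1))])
        labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 20)
        Z, leaves, _ = cluster_dendrogram(labels, expr)
        assert Z[:, 2].min() == pytest.approx(0.0, abs=1e-12)

    def test_topology_matches_manual_agglomeration(self):
        rng = np.random.default_rng(14)
        p1 = rng.normal(0, 1, 60)
        p2 = p1 + rng.normal(0, 0.1, 60)   # close to p1
        p3 = rng.normal(0, 1, 60)          # unrelated
        expr = np.vstack([np.tile(p, (10, 1)) for p in (p1, p2, p3)])
        labels = np.array(sum([[f"c{i}"] * 10 for i in range(3)], []))
        Z, leaves, newick = cluster_dendrogram(labels, expr)
        # first merge must join c0 and c1
        assert set(Z[0, :2].astype(int)) == {0, 1}
        assert "c0" in newick and newick.endswith(";")

    def test_leaf_set_equals_cluster_set(self, small_sim):
        cm, truth = small_sim
        sf = preprocess.compute_size_factors(cm)
        nm = preprocess.log_normalize(cm, sf)
        labels = truth.cells["population"].to_numpy()
        Z, leaves, newick = cluster_dendrogram(labels, nm.logexpr)
        assert set(leaves) == set(np.unique(labels).astype(str))
        for leaf in leaves:
            assert leaf in newick
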