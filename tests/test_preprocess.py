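"""QC metrics, adaptive thresholds, size factors, normalisation, HVGs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from conftest import make_count_matrix
from sctrails import preprocess
from sctrails.preprocess import (apply_qc, compute_cell_qc, compute_size_factors,
                                 fit_mean_variance_trend, flag_shared_barcodes,
                                 log_normalize, mad_threshold, select_hvgs)


class TestCellQC:
    def test_direct_arithmetic(self):
        cm = make_count_matrix([[3, 1], [0, 0]], gene_ids=["geneA", "mt-1"])
        rep = compute_cell_qc(cm)
        row = rep.cells.iloc[0]
        assert row["total_umis"] == 4 and row["genes_detected"] == 2
        assert row["mito_fraction"] == pytest.approx(0.25)
        zero = rep.cells.iloc[1]
        assert zero["total_umis"] == 0 and zero["mito_fraction"] == 0

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, (50, 20))
        gene_ids = [f"mt-{j}" if j < 3 else f"g{j}" for j in range(20)]
        rep = compute_cell_qc(make_count_matrix(counts, gene_ids=gene_ids))
        for i in range(50):
            assert rep.cells["total_umis"].iloc[i] == counts[i].sum()
            assert rep.cells["genes_detected"].iloc[i] == (counts[i] > 0).sum()
            expect = counts[i, :3].sum() / counts[i].sum() if counts[i].sum() else 0
            assert rep.cells["mito_fraction"].iloc[i] == pytest.approx(expect)

    def test_unmatched_mito_pattern_warns(self, caplog):
        cm = make_count_matrix([[1, 2]], gene_ids=["a", "b"])
        rep = compute_cell_qc(cm, mito_pattern="^MT-")
        assert (rep.cells["mito_fraction"] == 0).all()


class TestMadThreshold:
    def test_zero_spread(self):
        assert mad_threshold([2000.0] * 20, 3, 1000) == 2000

    def test_floor_regime(self):
        # median - 3 MAD below the floor: the floor wins
        vals = np.array([500, 520, 540, 560, 580.0])
        assert mad_threshold(vals, 3, 500) == 500

    def test_bruteforce_oracle(self):
        vals = np.arange(1, 102, dtype=float)
        sorted_v = np.sort(vals)
        med = sorted_v[50]
        mad = np.sort(np.abs(vals - med))[50]
        expect = med - 3 * 1.4826 * mad
        assert mad_threshold(vals, 3, -np.inf) == pytest.approx(expect)
        assert expect == pytest.approx(51 - 3 * 1.4826 * 25)
        # with a floor of 0 the (negative) raw threshold is clipped
        assert mad_threshold(vals, 3, 0) == 0

    @settings(max_examples=30, derandomize=True)
    @given(hnp.arrays(float, st.integers(1, 50),
                      elements=st.floats(0, 1e6)),
           st.floats(0, 10), st.floats(0, 1000))
    def test_never_below_floor_never_above_median(self, vals, n_mads, floor):
        thr = mad_threshold(vals, n_mads, floor)
        assert thr >= floor
        assert thr <= max(float(np.median(vals)), floor) + 1e-9

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mad_threshold([], 3, 0)


class TestSharedBarcodes:
    def test_definition(self):
        cm = make_count_matrix(np.ones((3, 2)), samples=["NP1", "G1", "G1"],
                               barcodes=["AAAC", "AAAC", "TTTG"])
        assert list(flag_shared_barcodes(cm)) == [True, True, False]

    def test_all_unique(self):
        cm = make_count_matrix(np.ones((4, 2)), samples=["S1", "S1", "S2", "S2"])
        assert not flag_shared_barcodes(cm).any()


class TestApplyQC:
    def test_mito_cut_is_inclusive(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(40, (30, 50))
        counts[:, 0] = 0
        # cell 0: mito fraction exactly 0.05
        total = counts[0, 1:].sum()
        counts[0, 0] = int(round(total * 0.05 / 0.95))
        frac = counts[0, 0] / counts[0].sum()
        counts[0, 0] += 1 if frac < 0.05 else 0
        cm = make_count_matrix(counts, gene_ids=["mt-1"] + [f"g{j}" for j in range(49)])
        passed, rep = apply_qc(cm, gene_floor=0, umi_floor=0, n_mads=50)
        assert rep.cells["mito_fraction"].iloc[0] >= 0.05
        assert not rep.cells["pass"].iloc[0]
        assert "high_mito" in rep.cells["reasons"].iloc[0]

    def test_clean_tight_data_all_pass(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(20, (40, 60))
        cm = make_count_matrix(counts)
        passed, rep = apply_qc(cm, gene_floor=0, umi_floor=0)
        assert passed.n_cells == 40

    def test_idempotent_with_fixed_thresholds(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5, (60, 80))
        cm = make_count_matrix(counts)
        thr = pd.DataFrame({"gene_threshold": [30.0], "umi_threshold": [100.0]},
                           index=pd.Index(["S1"], name="sample"))
        once, _ = apply_qc(cm, fixed_thresholds=thr)
        twice, rep2 = apply_qc(once, fixed_thresholds=thr)
        assert twice.n_cells == once.n_cells
        assert rep2.cells["pass"].all()

    def test_small_sample_falls_back_to_floors(self, caplog):
        rng = np.random.default_rng(4)
        counts = rng.poisson(30, (5, 40))
        cm = make_count_matrix(counts)
        _, rep = apply_qc(cm, gene_floor=10, umi_floor=100)
        assert rep.sample_thresholds.loc["S1", "gene_threshold"] == 10
        assert rep.sample_thresholds.loc["S1", "umi_threshold"] == 100

    def test_planted_low_quality_recovered(self):
        from sctrails import synthetic
        cfg = synthetic.default_config(seed=21)
        cfg.n_cells_per_sample = 400
        cfg.n_genes = 600
        cfg.trajectory.n_shared_genes = 60
        cfg.trajectory.n_branch_genes = 120
        cfg.artifacts = synthetic.ArtifactSpec(
            low_quality_fraction=0.1, low_quality_scale=0.05, n_shared_barcodes=5)
        cm, truth = synthetic.simulate_dataset(cfg)
        # floors scaled to the 600-gene panel
        passed, _ = apply_qc(cm, gene_floor=150, umi_floor=500)
        kept = set(passed.cell_ids)
        planted = (truth.cells["is_low_quality"]
                   | truth.cells["shared_barcode"]).to_numpy()
        removed = ~truth.cells.index.isin(kept)
        assert (removed & planted).sum() / planted.sum() >= 0.9
        assert (removed & ~planted).sum() / (~planted).sum() <= 0.05


class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        counts = np.tile(np.arange(1, 41), (50, 1))
        sf = compute_size_factors(make_count_matrix(counts))
        np.testing.assert_allclose(sf, 1.0, atol=1e-6)

    def test_pure_scaling_recovered(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 50, 100)
        counts = np.vstack([np.tile(s * base, (20, 1)) for s in (1, 2, 4)])
        sf = compute_size_factors(make_count_matrix(counts))
        groups = sf.reshape(3, 20).mean(axis=1)
        np.testing.assert_allclose(groups / groups[0], [1, 2, 4], rtol=1e-3)
        assert sf.mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(3, (80, 120)) + 1
        sf1 = compute_size_factors(make_count_matrix(counts))
        sf2 = compute_size_factors(make_count_matrix(2 * counts))
        np.testing.assert_allclose(sf1, sf2, rtol=1e-6)

    def test_doubling_one_cell_doubles_its_factor(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(10, (60, 100)) + 1
        sf1 = compute_size_factors(make_count_matrix(counts))
        boosted = counts.copy()
        boosted[7] *= 2
        sf2 = compute_size_factors(make_count_matrix(boosted))
        rel1 = sf1[7] / np.delete(sf1, 7).mean()
        rel2 = sf2[7] / np.delete(sf2, 7).mean()
        assert rel2 / rel1 == pytest.approx(2.0, rel=0.05)

    def test_composition_robustness(self):
        """A third of the genes strongly up in one group must not distort
        the factors of the other genes' scale (the deconvolution median
        resists composition bias)."""
        rng = np.random.default_rng(8)
        mu = rng.lognormal(1, 1, 300)
        a = rng.poisson(np.tile(mu, (60, 1)))
        mu_b = mu.copy()
        mu_b[:100] *= 6
        b = rng.poisson(np.tile(mu_b, (60, 1)))
        sf = compute_size_factors(make_count_matrix(np.vstack([a, b])))
        # normalized null-gene means should agree between groups
        ya = (a / sf[:60, None])[:, 100:].mean()
        yb = (b / sf[60:, None])[:, 100:].mean()
        assert yb / ya == pytest.approx(1.0, abs=0.15)


class TestLogNormalize:
    def test_examples_and_oracle(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(2, (30, 40))
        counts[0, 0] = 0
        counts[0, 1] = 3
        cm = make_count_matrix(counts)
        sf = np.ones(30)
        sf[1] = 2.0
        sf = sf / sf.mean()
        nm = log_normalize(cm, sf)
        assert nm.logexpr[0, 0] == 0.0
        expect = np.log2(counts / sf[:, None] + 1)
        np.testing.assert_allclose(nm.logexpr, expect)

    def test_count3_factor1_gives_2(self):
        cm = make_count_matrix([[3]], gene_ids=["g"])
        nm = log_normalize(cm, np.array([1.0]))
        assert nm.logexpr[0, 0] == pytest.approx(2.0)


class TestTrendAndHVG:
    @staticmethod
    def _smooth_variance_data(rng, n=300, g=800):
        means = rng.uniform(0.5, 4.0, g)
        sds = np.sqrt(0.2 + 0.1 * means)  # variance lies on a smooth trend
        Y = rng.normal(means, sds, (n, g))
        return Y

    def test_planted_trend_gives_zero_bio(self):
        rng = np.random.default_rng(10)
        Y = self._smooth_variance_data(rng)
        from sctrails.containers import NormalizedMatrix
        nm = NormalizedMatrix(Y, np.ones(Y.shape[0]),
                              [f"c{i}" for i in range(Y.shape[0])],
                              [f"g{j}" for j in range(Y.shape[1])],
                              ["S1"] * Y.shape[0], ["S1"] * Y.shape[0])
        stats = fit_mean_variance_trend(nm)
        bio = stats["var"] - stats["trend"]
        assert np.median(np.abs(bio)) < 0.05

    def test_zero_variance_gene_has_nonpositive_bio(self):
        rng = np.random.default_rng(11)
        Y = self._smooth_variance_data(rng, g=200)
        Y[:, 0] = 1.0
        from sctrails.containers import NormalizedMatrix
        nm = NormalizedMatrix(Y, np.ones(Y.shape[0]),
                              [f"c{i}" for i in range(Y.shape[0])],
                              [f"g{j}" for j in range(Y.shape[1])],
                              ["S1"] * Y.shape[0], ["S1"] * Y.shape[0])
        stats = fit_mean_variance_trend(nm)
        assert stats["trend"].iloc[0] >= 0
        assert (stats["var"] - stats["trend"]).iloc[0] <= 0

    def test_trend_invariant_to_gene_order(self):
        rng = np.random.default_rng(12)
        Y = self._smooth_variance_data(rng, g=300)
        from sctrails.containers import NormalizedMatrix
        ids = np.array([f"g{j}" for j in range(300)], object)
        nm = NormalizedMatrix(Y, np.ones(300 * 0 + Y.shape[0]) * 1.0,
                              [f"c{i}" for i in range(Y.shape[0])], ids,
                              ["S1"] * Y.shape[0], ["S1"] * Y.shape[0])
        perm = rng.permutation(300)
        nm_p = NormalizedMatrix(Y[:, perm], nm.size_factors, nm.cell_ids,
                                ids[perm], nm.sample_of_cell, nm.timepoint_of_cell)
        s1 = fit_mean_variance_trend(nm).loc[ids]
        s2 = fit_mean_variance_trend(nm_p).loc[ids]
        np.testing.assert_allclose(s1["trend"], s2["trend"], rtol=1e-8)

    def test_min_bio_edge_excludes_significant_gene(self):
        stats = pd.DataFrame({"mean": [1.0], "var": [1.49], "trend": [1.0]},
                             index=["g0"])
        out = select_hvgs(stats, n_cells=100000, min_bio=0.5)
        assert out["p_adj"].iloc[0] < 1e-6  # overwhelmingly significant
        assert not out["is_hvg"].iloc[0]    # but bio = 0.49 < 0.5

    def test_hvg_recovery_sensitivity_and_fdr(self):
        from sctrails.containers import NormalizedMatrix
        hits = []
        fdrs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n, g = 250, 1050
            Y = rng.normal(2.0, 0.5, (n, g))
            # 50 planted high-variance genes: bimodal, amplitude 2 log2
            planted = np.arange(50)
            Y[:, planted] += np.where(rng.uniform(size=(n, 1)) < 0.5, -1.0, 1.0)
            nm = NormalizedMatrix(Y, np.ones(n), [f"c{i}" for i in range(n)],
                                  [f"g{j}" for j in range(g)], ["S1"] * n, ["S1"] * n)
            stats = fit_mean_variance_trend(nm)
            out = select_hvgs(stats, n_cells=n)
            called = set(np.flatnonzero(out["is_hvg"].to_numpy()))
            hits.append(len(called & set(planted)) / 50)
            fdrs.append(len(called - set(planted)) / max(len(called), 1))
        assert np.mean(hits) >= 0.9
        assert np.mean(fdrs) <= 0.1

    def test_hvg_null_calibration(self):
        from sctrails.containers import NormalizedMatrix
        rng = np.random.default_rng(200)
        n, g = 250, 1000
        Y = rng.normal(2.0, 0.5, (n, g))
        nm = NormalizedMatrix(Y, np.ones(n), [f"c{i}" for i in range(n)],
                              [f"g{j}" for j in range(g)], ["S1"] * n, ["S1"] * n)
        out = select_hvgs(fit_mean_variance_trend(nm), n_cells=n)
        assert out["is_hvg"].mean() <= 0.01

    def test_hvg_set_invariant_to_cell_permutation(self, small_sim):
        cm, _ = small_sim
        passed, _ = apply_qc(cm)
        sf = compute_size_factors(passed)
        nm = log_normalize(passed, sf)
        out1 = select_hvgs(fit_mean_variance_trend(nm), n_cells=nm.n_cells)
        rng = np.random.default_rng(13)
        perm = rng.permutation(nm.n_cells)
        from sctrails.containers import NormalizedMatrix
        nm_p = NormalizedMatrix(nm.logexpr[perm], nm.size_factors[perm],
                                nm.cell_ids[perm], nm.gene_ids,
                                nm.sample_of_cell[perm], nm.timepoint_of_cell[perm])
        out2 = select_hvgs(fit_mean_variance_trend(nm_p), n_cells=nm.n_cells)
        assert (out1["is_hvg"] == out2["is_hvg"]).all()


def test_few_genes_trend_refused():
    from sctrails.containers import NormalizedMatrix
    rng = np.random.default_rng(14)
    nm = NormalizedMatrix(rng.normal(1, 1, (30, 20)), np.ones(30),
                          [f"c{i}" for i in range(30)],
                          [f"g{j}" for j in range(20)], ["S1"] * 30, ["S1"] * 30)
    with pytest.raises(ValueError, match="genes"):
        fit_mean_variance_trend(nm)
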