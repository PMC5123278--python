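import numpy as np
import pandas as pd
import pytest
import skbio

from ampliconbench.core import CountTable, SampleMetadata, library_sizes
from ampliconbench import betadiv as bd


# Frozen cross-implementation oracle values for the 12x6 fixture table
# (tests/conftest.py), computed with edgeR::calcNormFactors (TMM), the
# DESeq2 median-of-ratios procedure with manual nonzero geometric means,
# vegan::adonis2 and phyloseq::UniFrac.
EDGER_TMM = [0.9679320731, 0.8803993559, 1.3537032374,
             1.0288145359, 1.2695358474, 0.6636970320]
DESEQ_SF_GM1 = [1.0230079242, 0.8309051846, 0.8567271227,
                0.7533439441, 1.3678746296, 1.3325619893]
VEGAN_R2 = 0.2989345713
VEGAN_F = 1.7056015551
PHYLOSEQ_UNIFRAC = {("S0", "S1"): 0.4238199849, ("S0", "S5"): 0.3541923215,
                    ("S2", "S4"): 0.3721910468}
PHYLOSEQ_WUNIFRAC = {("S0", "S1"): 0.2263426538, ("S0", "S5"): 0.1556813285,
                     ("S2", "S4"): 0.3505510731}


class TestSizeFactors:
    def test_matches_reference_implementation(self, oracle_table):
        assert np.allclose(bd.deseq_size_factors(oracle_table), DESEQ_SF_GM1,
                           atol=1e-9)

    def test_doubled_sample_hand_computation(self):
        t = CountTable(["a", "b", "c"], ["s1", "s2"],
                       np.array([[1, 2], [2, 4], [4, 8]]))
        f = bd.deseq_size_factors(t)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_equal_factors(self):
        t = CountTable(["a", "b"], ["s1", "s2", "s3"],
                       np.array([[3, 3, 3], [7, 7, 7]]))
        assert np.allclose(bd.deseq_size_factors(t), 1.0)


class TestTMM:
    def test_matches_edger(self, oracle_table):
        assert np.allclose(bd.tmm_factors(oracle_table), EDGER_TMM, atol=1e-9)

    def test_identical_samples_all_one(self):
        t = CountTable(["a", "b", "c"], ["s1", "s2"],
                       np.array([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(bd.tmm_factors(t), 1.0)

    def test_pure_depth_difference_absorbed(self):
        t = CountTable(["a", "b", "c"], ["s1", "s2"],
                       np.array([[5, 10], [9, 18], [2, 4]]))
        assert np.allclose(bd.tmm_factors(t), 1.0)

    def test_geometric_mean_one(self, oracle_table):
        f = bd.tmm_factors(oracle_table)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_infeasible_on_disjoint_support(self):
        counts = np.array([[5, 0], [7, 0], [0, 3], [0, 9]])
        t = CountTable(list("abcd"), ["s1", "s2"], counts)
        with pytest.raises(bd.NormalizationError, match="TMM"):
            bd.tmm_factors(t)


class TestCSS:
    def test_fixed_quantile_hand_computation(self):
        # nonzero counts of s1: [1,2,3,4,100]; median 3 -> sum<=3 is 6
        counts = np.array([[1, 2], [2, 2], [3, 2], [4, 2], [100, 2], [0, 2]])
        t = CountTable(list("abcdef"), ["s1", "s2"], counts)
        f = bd.css_factors(t, quantile=0.5)
        assert f[0] == pytest.approx(6 / 1000)

    def test_identical_samples_equal_factors(self, oracle_table):
        c = oracle_table.counts[:, [0]].repeat(3, axis=1)
        t = CountTable(list(oracle_table.otu_ids), ["x", "y", "z"], c)
        f = bd.css_factors(t)
        assert np.allclose(f, f[0])

    def test_data_driven_quantile_floor(self, oracle_table, small_synth):
        assert bd.css_quantile(oracle_table) >= 0.5
        assert 0.5 <= bd.css_quantile(small_synth) <= 1.0


class TestNormalize:
    def test_none_is_identity(self, oracle_table):
        out = bd.normalize(oracle_table, "none")
        assert np.array_equal(out.counts, oracle_table.counts)
        assert not out.is_raw

    def test_tss_columns_sum_to_one(self, oracle_table):
        out = bd.normalize(oracle_table, "tss")
        assert np.allclose(out.counts.sum(axis=0), 1.0)

    @pytest.mark.parametrize("kind", ["none", "tss", "css", "tmm", "deseq"])
    def test_identical_samples_stay_identical(self, kind):
        c = np.array([[4, 4, 4], [1, 1, 1], [9, 9, 9], [0, 0, 0], [3, 3, 3]])
        t = CountTable(list("abcde"), ["x", "y", "z"], c)
        out = bd.normalize(t, kind)
        assert np.allclose(out.counts[:, 0], out.counts[:, 1])
        assert np.allclose(out.counts[:, 0], out.counts[:, 2])

    @pytest.mark.parametrize("kind", ["tss", "css", "tmm", "deseq"])
    def test_within_sample_ratios_preserved(self, oracle_table, kind):
        """Normalization is per-sample scaling: TSS afterwards equals TSS
        alone, i.e. within-sample count ratios survive."""
        out = bd.normalize(oracle_table, kind)
        c = oracle_table.counts
        for j in range(oracle_table.n_samples):
            nz = c[:, j] > 0
            ratio = out.counts[nz, j] / c[nz, j]
            assert np.allclose(ratio, ratio[0])


class TestTransform:
    @pytest.mark.parametrize("c", [1.0, 0.01, 1e-4, 1e-5])
    def test_zero_maps_to_zero(self, c):
        t = CountTable(["a", "b"], ["s1", "s2"], np.array([[0, 3], [5, 0]]))
        out = bd.transform(bd.normalize(t, "none"),
                           bd.TransformSpec("log_pseudo", c))
        assert out.counts[0, 0] == 0.0
        assert out.counts[1, 1] == 0.0

    def test_log_closed_forms(self):
        t = CountTable(["a"], ["s1", "s2"], np.array([[1, 1]]))
        one = bd.transform(t.copy(is_raw=False), bd.TransformSpec("log_pseudo", 1.0))
        assert one.counts[0, 0] == pytest.approx(np.log(2))
        small = bd.transform(t.copy(is_raw=False), bd.TransformSpec("log_pseudo", 0.01))
        assert small.counts[0, 0] == pytest.approx(np.log(101))

    def test_roots(self):
        t = CountTable(["a"], ["s1", "s2"], np.array([[8, 9]])).copy(is_raw=False)
        assert bd.transform(t, "sqrt").counts[0, 1] == pytest.approx(3.0)
        assert bd.transform(t, "cbrt").counts[0, 0] == pytest.approx(2.0)

    def test_log_monotone_on_normalized_values(self, oracle_table):
        rel = bd.normalize(oracle_table, "tss")
        out = bd.transform(rel, bd.TransformSpec("log_pseudo", 0.01))
        order_in = np.argsort(rel.counts, axis=0)
        order_out = np.argsort(out.counts, axis=0)
        assert np.array_equal(order_in, order_out)


class TestDistances:
    def test_identical_samples_zero(self, oracle_table):
        c = oracle_table.counts[:, [0]].repeat(2, axis=1)
        t = CountTable(list(oracle_table.otu_ids), ["x", "y"], c)
        for metric in ("bray", "euclidean", "jsd"):
            assert bd.distance(t, metric)["x", "y"] == pytest.approx(0.0)

    def test_disjoint_support_maxima(self, oracle_tree):
        # O0-O4 and O5-O11 are the two clades under the root, so the
        # samples also share no tree branches below the root
        c = np.zeros((12, 2), dtype=int)
        c[:5, 0] = 5
        c[5:, 1] = 7
        t = CountTable([f"O{i}" for i in range(12)], ["x", "y"], c)
        assert bd.distance(t, "bray")["x", "y"] == pytest.approx(1.0)
        assert bd.distance(t, "jsd")["x", "y"] == pytest.approx(np.log(2))
        assert bd.distance(t, "unifrac", tree=oracle_tree)["x", "y"] == \
            pytest.approx(1.0)

    def test_hand_computed_bray_euclidean(self):
        t = CountTable(["a", "b", "c"], ["x", "y"],
                       np.array([[1, 0], [1, 1], [0, 1]]))
        assert bd.distance(t, "bray")["x", "y"] == pytest.approx(0.5)
        assert bd.distance(t, "euclidean")["x", "y"] == pytest.approx(np.sqrt(2))

    def test_unifrac_matches_phyloseq(self, oracle_table, oracle_tree):
        du = bd.distance(oracle_table, "unifrac", tree=oracle_tree)
        dw = bd.distance(oracle_table, "wunifrac", tree=oracle_tree)
        for (a, b), val in PHYLOSEQ_UNIFRAC.items():
            assert du[a, b] == pytest.approx(val, abs=1e-9)
        for (a, b), val in PHYLOSEQ_WUNIFRAC.items():
            assert dw[a, b] == pytest.approx(val, abs=1e-9)

    def test_distance_matrix_properties(self, oracle_table, oracle_tree):
        for metric in ("bray", "euclidean", "jsd", "unifrac", "wunifrac"):
            d = bd.distance(oracle_table, metric, tree=oracle_tree)
            m = np.asarray(d.data)
            assert np.allclose(m, m.T)
            assert np.allclose(np.diag(m), 0.0)
            assert (m >= 0).all()
            if metric in ("bray", "unifrac", "wunifrac"):
                assert (m <= 1 + 1e-12).all()

    def test_missing_tree_errors(self, oracle_table):
        with pytest.raises(ValueError, match="tree"):
            bd.distance(oracle_table, "unifrac")

    def test_tip_mismatch_lists_offenders(self, oracle_tree):
        t = CountTable(["O0", "NOT_IN_TREE"], ["x", "y"],
                       np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="NOT_IN_TREE"):
            bd.distance(t, "unifrac", tree=oracle_tree)


class TestPermanova:
    def test_matches_vegan_adonis(self, oracle_table):
        rel = bd.normalize(oracle_table, "tss")
        d = bd.distance(rel, "bray")
        res = bd.permanova(d, ["a", "a", "a", "b", "b", "b"], n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(VEGAN_R2, abs=1e-9)
        assert res.pseudo_f == pytest.approx(VEGAN_F, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_decomposition(self, seed):
        """R² against the direct double-loop sum-of-squares computation
        on random 8-sample distance matrices."""
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(8, 3))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = skbio.DistanceMatrix(m, ids=[f"s{i}" for i in range(8)])
        groups = np.array(["a", "a", "a", "b", "b", "b", "c", "c"])
        res = bd.permanova(d, groups, n_perm=9, seed=1)

        n = 8
        ss_t = sum(m[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
        ss_w = 0.0
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            ss_w += sum(m[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
        assert res.r_squared == pytest.approx((ss_t - ss_w) / ss_t, rel=1e-12)

    def test_r2_independent_of_seed(self, oracle_table):
        d = bd.distance(bd.normalize(oracle_table, "tss"), "bray")
        g = ["a", "a", "b", "b", "a", "b"]
        r = [bd.permanova(d, g, n_perm=49, seed=s).r_squared for s in (1, 2, 3)]
        assert r[0] == r[1] == r[2]

    def test_planted_separation_detected(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(2, 20, 4)) * 0.3
        base[1] += 3.0
        pts = base.reshape(40, 4)
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = skbio.DistanceMatrix(m, ids=[f"s{i}" for i in range(40)])
        groups = ["a"] * 20 + ["b"] * 20
        res = bd.permanova(d, groups, n_perm=199, seed=0)
        assert res.r_squared > 0.5
        assert res.p <= 0.01

    def test_strata_restrict_permutations(self):
        """When the design variable is constant within each stratum,
        within-stratum shuffles never change the statistic: p = 1."""
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(8, 2))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        d = skbio.DistanceMatrix(m, ids=[f"s{i}" for i in range(8)])
        groups = ["a", "a", "a", "a", "b", "b", "b", "b"]
        strata = groups
        res = bd.permanova(d, groups, strata=strata, n_perm=99, seed=1)
        assert res.p == 1.0

    def test_single_group_errors(self, oracle_table):
        d = bd.distance(bd.normalize(oracle_table, "tss"), "bray")
        with pytest.raises(ValueError):
            bd.permanova(d, ["a"] * 6)


class TestBetaGrid:
    @pytest.fixture(scope="class")
    def grid_inputs(self, ):
        rng = np.random.default_rng(12)
        counts = rng.negative_binomial(1, 0.02, size=(30, 12))
        counts[:10, 6:] = rng.negative_binomial(1, 0.005, size=(10, 6))
        counts[0] = 40  # keep depths positive
        t = CountTable([f"o{i}" for i in range(30)],
                       [f"s{j}" for j in range(12)], counts)
        meta = SampleMetadata(pd.DataFrame(
            {"group": ["x"] * 6 + ["y"] * 6}, index=t.sample_ids))
        return t, meta

    def test_factorial_row_count(self, grid_inputs):
        t, meta = grid_inputs
        res = bd.beta_grid(t, meta, "group",
                           normalizations=("none", "tss"),
                           transformations=[bd.TransformSpec("identity"),
                                            bd.TransformSpec("sqrt")],
                           metrics=("bray", "jsd"), n_perm=9, seed=0)
        assert len(res) == 8

    def test_invariant_metric_identical_across_normalizations(self, grid_inputs):
        t, meta = grid_inputs
        res = bd.beta_grid(t, meta, "group",
                           normalizations=("none", "tss", "deseq"),
                           transformations=[bd.TransformSpec("sqrt")],
                           metrics=("jsd", "bray"), n_perm=9, seed=0)
        jsd = res[res.metric == "jsd"]
        assert jsd["shared"].all()
        assert jsd["r2"].nunique() == 1
        bray = res[(res.metric == "bray") & (res.status == "ok")]
        assert bray["r2"].nunique() > 1

    def test_failing_cell_recorded_not_dropped(self, grid_inputs):
        t, meta = grid_inputs
        disjoint = np.zeros((4, 12), dtype=int)
        disjoint[0, :6] = 5
        disjoint[1, :6] = 9
        disjoint[2, 6:] = 4
        disjoint[3, 6:] = 7
        t2 = CountTable(list("abcd"), list(t.sample_ids), disjoint)
        res = bd.beta_grid(t2, meta, "group", normalizations=("tss", "tmm"),
                           transformations=[bd.TransformSpec("identity")],
                           metrics=("bray",), n_perm=9, seed=0)
        tmm_row = res[res.normalization == "tmm"].iloc[0]
        assert tmm_row["status"].startswith("error")
        assert (res[res.normalization == "tss"]["status"] == "ok").all()

    def test_best_cell_reports_triple(self, grid_inputs):
        t, meta = grid_inputs
        res = bd.beta_grid(t, meta, "group", normalizations=("none",),
                           transformations=[bd.TransformSpec("identity"),
                                            bd.TransformSpec("log_pseudo", 1.0)],
                           metrics=("bray", "euclidean"), n_perm=9, seed=0)
        best = bd.best_cell(res)
        assert best["r2"] == res[res.status == "ok"]["r2"].max()


class TestAgglomeration:
    def test_tiny_quantile_is_identity(self, oracle_table, oracle_tree):
        # restrict to tips with strictly positive pairwise distances:
        # the threshold then collapses onto the minimum distance and the
        # strict < comparison leaves every OTU alone
        sub = CountTable(oracle_table.otu_ids[:5], oracle_table.sample_ids,
                         oracle_table.counts[:5] + 1)
        out, merge_map = bd.agglomerate_otus(sub, oracle_tree, quantile=1e-9)
        assert out.n_otus == sub.n_otus
        assert all(len(v) == 1 for v in merge_map.values())

    def test_zero_distance_tips_merge_to_archetype(self, oracle_table, oracle_tree):
        # O5 and O6 are sibling tips with zero branch lengths
        out, merge_map = bd.agglomerate_otus(oracle_table, oracle_tree,
                                             quantile=0.02)
        merged = [k for k, v in merge_map.items() if set(v) >= {"O5", "O6"}]
        assert len(merged) == 1
        totals = oracle_table.counts.sum(axis=1)
        ids = oracle_table.otu_ids
        assert merged[0] == max(["O5", "O6"], key=lambda o: totals[ids.index(o)])

    def test_total_counts_conserved(self, oracle_table, oracle_tree):
        out, _ = bd.agglomerate_otus(oracle_table, oracle_tree, quantile=0.3)
        assert out.counts.sum() == oracle_table.counts.sum()
        assert np.array_equal(library_sizes(out), library_sizes(oracle_table))

    def test_invalid_quantile_errors(self, oracle_table, oracle_tree):
        with pytest.raises(ValueError):
            bd.agglomerate_otus(oracle_table, oracle_tree, quantile=1.5)
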