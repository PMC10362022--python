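import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rnachase.core_io import AnalysisConfig, CountMatrix
from rnachase.expression import (
    bh_adjust,
    cpm,
    nb_two_group_test,
    overlap_sets,
    regulon_enrichment,
    select_degs,
    tmm_factors,
)
from rnachase.simulate import ExpressionSimSpec, simulate_expression


def matrix_of(counts, library_sizes=None):
    counts = np.asarray(counts)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        counts=counts,
        library_sizes=library_sizes,
    )


class TestCpm:
    def test_zero_count_zero_cpm(self):
        m = matrix_of([[0, 10], [5, 10]])
        assert cpm(m).iloc[0, 0] == 0.0

    def test_direct_arithmetic(self):
        m = matrix_of([[100], [999_900]], library_sizes=np.array([1_000_000]))
        assert cpm(m).iloc[0, 0] == 100.0

    def test_columns_sum_to_million(self):
        m = matrix_of([[30], [70]])
        values = cpm(m)
        np.testing.assert_allclose(values["s0"], [3e5, 7e5])
        np.testing.assert_allclose(values.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_library_errors(self):
        with pytest.warns(UserWarning):
            m = matrix_of([[0, 1]])
        with pytest.raises(ValueError, match="library size"):
            cpm(m)


def brute_force_tmm(counts, lib, k, ref, m_trim=0.30, a_trim=0.05):
    """Straight re-computation of the trimmed weighted mean of M values."""
    yk, yr = counts[:, k].astype(float), counts[:, ref].astype(float)
    lk, lr = float(lib[k]), float(lib[ref])
    keep = (yk > 0) & (yr > 0)
    yk, yr = yk[keep], yr[keep]
    m = np.log2((yk / lk) / (yr / lr))
    a = 0.5 * np.log2((yk / lk) * (yr / lr))
    w = (lk - yk) / (lk * yk) + (lr - yr) / (lr * yr)
    n = m.size
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    kept = (
        (rank_m >= np.floor(n * m_trim) + 1) & (rank_m <= n - np.floor(n * m_trim))
        & (rank_a >= np.floor(n * a_trim) + 1) & (rank_a <= n - np.floor(n * a_trim))
    )
    return 2.0 ** (np.sum(m[kept] / w[kept]) / np.sum(1.0 / w[kept]))


class TestTmm:
    def test_identical_columns_factor_one(self):
        m = matrix_of(np.tile([[10], [20], [30], [40]], (1, 2)))
        f = tmm_factors(m)
        np.testing.assert_allclose(f.factors, 1.0)

    def test_pure_depth_difference_factor_one(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, size=50)
        m = matrix_of(np.column_stack([a, 2 * a]))
        f = tmm_factors(m)
        # M identical for every gene: depth absorbed by library size
        np.testing.assert_allclose(f.factors, 1.0, rtol=1e-12)

    def test_composition_shift_shrinks_factor(self):
        # one gene dominating sample B squeezes everything else's share
        counts = np.array([
            [100, 100], [200, 200], [300, 300], [400, 400], [1000, 100_000],
        ])
        m = matrix_of(counts)
        f = tmm_factors(m, reference_sample="s0")
        assert f.factors[1] / f.factors[0] < 1.0
        expected = brute_force_tmm(counts, m.library_sizes, 1, 0)
        ratio = f.factors[1] / f.factors[0]
        np.testing.assert_allclose(ratio, expected, rtol=1e-12)

    def test_brute_force_agreement_random(self):
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(5, 0.01, size=(300, 3))
        m = matrix_of(counts)
        f = tmm_factors(m, reference_sample="s0")
        for k in (1, 2):
            expected = brute_force_tmm(counts, m.library_sizes, k, 0)
            np.testing.assert_allclose(f.factors[k] / f.factors[0], expected,
                                       rtol=1e-10)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(50, size=(100, 3))
        m1 = matrix_of(counts)
        perm = rng.permutation(100)
        m2 = matrix_of(counts[perm])
        np.testing.assert_allclose(tmm_factors(m1, "s0").factors,
                                   tmm_factors(m2, "s0").factors, rtol=1e-12)

    def test_scaling_one_sample_leaves_factor(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(200, size=(80, 3))
        m1 = matrix_of(counts)
        scaled = counts.copy()
        scaled[:, 1] *= 7
        m2 = matrix_of(scaled)
        # M and A are exactly invariant; the precision weights depend on
        # absolute counts, so invariance is only near-exact
        np.testing.assert_allclose(tmm_factors(m1, "s0").factors,
                                   tmm_factors(m2, "s0").factors, rtol=1e-3)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(11)
        m = matrix_of(rng.poisson(100, size=(60, 4)))
        f = tmm_factors(m)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f.factors))), 1.0)

    def test_disjoint_support_errors(self):
        m = matrix_of([[5, 0], [7, 0], [0, 9]])
        with pytest.raises(ValueError, match="shares no expressed genes"):
            tmm_factors(m, reference_sample="s0")

    def test_single_sample_errors(self):
        m = matrix_of([[5], [7]])
        with pytest.raises(ValueError, match="two samples"):
            tmm_factors(m)


class TestNbTwoGroupTest:
    def test_identical_groups_null(self):
        counts = np.tile([[100], [200], [300]], (1, 4))
        m = matrix_of(counts)
        out = nb_two_group_test(m, ["s0", "s1"], ["s2", "s3"])
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)
        assert (out["pvalue"] > 0.5).all()

    def test_doubled_counts_log2fc_one(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(500, size=20)
        counts = np.column_stack([2 * a, 2 * a, a, a])
        lib = np.full(4, 1_000_000)
        m = matrix_of(counts, library_sizes=lib)
        out = nb_two_group_test(m, ["s0", "s1"], ["s2", "s3"])
        np.testing.assert_allclose(out["log2fc"], 1.0, atol=1e-12)

    def test_all_zero_gene(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 9, 11]])
        m = matrix_of(counts)
        out = nb_two_group_test(m, ["s0", "s1"], ["s2", "s3"])
        assert out.loc[0, "pvalue"] == 1.0
        assert out.loc[0, "log2fc"] == 0.0

    def test_needs_two_per_group(self):
        m = matrix_of(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="two samples per group"):
            nb_two_group_test(m, ["s0"], ["s1", "s2"])

    def test_null_calibration_small(self):
        # scaled-down version of the acceptance calibration check
        spec = ExpressionSimSpec(n_genes=400, strains=("a", "b"),
                                 deg_fraction=0.0, library_size=1_000_000, seed=2)
        matrix, sheet, _ = simulate_expression(spec)
        out = nb_two_group_test(matrix, sheet.samples_for(strain="a"),
                                sheet.samples_for(strain="b"))
        rate = (out["pvalue"] < 0.05).mean()
        assert 0.02 < rate < 0.08

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(9)
        base = rng.poisson(1000, size=(30, 6))
        base[0, :3] *= 8
        m = matrix_of(base)
        out = nb_two_group_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert out.loc[0, "pvalue"] < 1e-4
        assert out.loc[0, "log2fc"] > 2.0


class TestBhAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_stepup_by_hand(self):
        # p(i)*n/i then cumulative min from the right:
        # (0.03, 0.03, 0.03) derived by hand
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_statsmodels(self, pvalues):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvalues, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvalues), expected, atol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2,
                    max_size=20), st.randoms())
    def test_permutation_equivariance(self, pvalues, rnd):
        perm = list(range(len(pvalues)))
        rnd.shuffle(perm)
        direct = bh_adjust(pvalues)
        permuted = bh_adjust([pvalues[i] for i in perm])
        np.testing.assert_allclose([direct[i] for i in perm], permuted,
                                   atol=1e-12)


class TestSelectDegs:
    @pytest.mark.parametrize("fdr,lfc,expect_deg,expect_dir", [
        (0.005, 0.9, False, "none"),
        (0.005, -1.0, True, "down"),
        (0.02, 1.5, False, "none"),
        (0.005, 1.0, True, "up"),
    ])
    def test_threshold_predicate(self, fdr, lfc, expect_deg, expect_dir):
        table = pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc],
                              "pvalue": [fdr], "fdr": [fdr]})
        out = select_degs(table, AnalysisConfig())
        assert bool(out.loc[0, "is_deg"]) is expect_deg
        if expect_deg:
            assert out.loc[0, "direction"] == expect_dir

    def test_pure_predicate_reproducible(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(100)],
            "log2fc": rng.normal(0, 2, 100),
            "pvalue": rng.uniform(0, 1, 100),
            "fdr": rng.uniform(0, 1, 100),
        })
        out = select_degs(table, AnalysisConfig())
        manual = (table["fdr"] < 0.01) & (table["log2fc"].abs() >= 1.0)
        assert (out["is_deg"] == manual).all()


class TestOverlapSets:
    def test_disjoint(self):
        out = overlap_sets({"A": {"a"}, "B": {"b"}})
        both = out[(out["A"]) & (out["B"])]["count"].iloc[0]
        assert both == 0

    def test_identical(self):
        out = overlap_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out[(out["A"]) & (out["B"])]["count"].iloc[0] == 2
        assert out[(out["A"]) & (~out["B"])]["count"].iloc[0] == 0

    def test_three_sets_brute_force(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(60)]
        sets = {name: set(rng.choice(genes, size=20, replace=False))
                for name in ("A", "B", "C")}
        out = overlap_sets(sets)
        for _, row in out.iterrows():
            expected = sum(
                1 for g in genes
                if all((g in sets[n]) == row[n] for n in ("A", "B", "C"))
            )
            assert row["count"] == expected
        union = len(sets["A"] | sets["B"] | sets["C"])
        assert out["count"].sum() == union

    def test_needs_two_sets(self):
        with pytest.raises(ValueError):
            overlap_sets({"A": {"a"}})


class TestRegulonEnrichment:
    def test_disjoint_regulon_p_near_one(self):
        universe = [f"g{i}" for i in range(40)]
        out = regulon_enrichment(universe[:10], universe,
                                 {"reg": universe[20:30]})
        assert out["pvalue"].iloc[0] > 0.95

    def test_hypergeometric_by_hand(self):
        # 20-gene universe, 5-gene regulon entirely inside an 8-gene DEG set:
        # P(X >= 5) with X ~ Hypergeom(N=20, K=5, n=8)
        universe = [f"g{i}" for i in range(20)]
        regulon = universe[:5]
        degs = universe[:8]
        out = regulon_enrichment(degs, universe, {"reg": regulon})
        expected = stats.hypergeom.sf(4, 20, 5, 8)
        np.testing.assert_allclose(out["pvalue"].iloc[0], expected, rtol=1e-10)

    def test_empty_regulon_skipped_with_warning(self):
        universe = ["g1", "g2"]
        with pytest.warns(UserWarning, match="skipped"):
            out = regulon_enrichment(["g1"], universe, {"empty": ["zz"]})
        assert len(out) == 0

    def test_deg_set_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            regulon_enrichment(["gX"], ["g1"], {"r": ["g1"]})
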