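"""CV / Fano statistics, decile dynamic range, F-test and the inverse regression."""

import numpy as np
import pandas as pd
import pytest

from gbmdyn.plasticity import (
    average_replicates,
    compare_sets,
    decile_dynamic_range,
    intergenic_control,
    log2_fold_change,
    plasticity_stats,
    tissue_specificity_regression,
    variance_f_test,
)


def matrix_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=pd.Index(genes, name="gene_id"))


class TestPlasticityStats:
    def test_constant_vector_gives_zero_cv_and_fano(self):
        out = plasticity_stats(matrix_from([[5.0] * 8]))
        assert out.iloc[0]["cv"] == 0.0
        assert out.iloc[0]["fano"] == 0.0

    def test_poisson_counts_have_unit_fano(self):
        rng = np.random.default_rng(12)
        out = plasticity_stats(matrix_from([rng.poisson(10, size=10_000)]))
        assert out.iloc[0]["fano"] == pytest.approx(1.0, abs=0.05)

    def test_scaling_identities(self):
        rng = np.random.default_rng(5)
        m = matrix_from(rng.gamma(4.0, 2.0, size=(20, 15)))
        base = plasticity_stats(m)
        scaled = plasticity_stats(m * 2.0)
        assert np.allclose(scaled["cv"], base["cv"])
        assert np.allclose(scaled["fano"], 2.0 * base["fano"])

    def test_zero_mean_gene_flagged(self):
        out = plasticity_stats(matrix_from([[0.0] * 5]))
        assert bool(out.iloc[0]["zero_mean"])
        assert np.isnan(out.iloc[0]["cv"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            plasticity_stats(matrix_from([[1.0, -2.0]]))


def test_average_replicates_collapses_conditions():
    m = pd.DataFrame(
        [[2.0, 4.0, 10.0]], index=["g1"], columns=["s1", "s2", "s3"]
    )
    meta = pd.DataFrame(
        {"sample": ["s1", "s2", "s3"], "condition": ["c1", "c1", "c2"]}
    )
    out = average_replicates(m, meta)
    assert out.loc["g1", "c1"] == pytest.approx(3.0)
    assert out.loc["g1", "c2"] == pytest.approx(10.0)


class TestCompareSets:
    def test_exclusion_list_and_missing_counted(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.gamma(5, 2, size=(30, 10)))
        stats_table = plasticity_stats(m)
        sets = {"a": {"g0", "g1", "g2", "ghost"}, "b": {"g5", "g6"}}
        out = compare_sets(stats_table, sets, exclusion={"g2"})
        assert len(out["per_set"]["a"]) == 2  # g2 excluded, ghost missing
        assert out["n_missing"]["a"] == 1


class TestVarianceFTest:
    def test_equal_samples_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        f, p = variance_f_test(x, x.copy())
        assert f == 1.0
        assert p == pytest.approx(1.0)

    def test_detects_known_variance_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2.0, 500)
        y = rng.normal(0, 1.0, 500)
        f, p = variance_f_test(x, y)
        assert f == pytest.approx(4.0, rel=0.3)
        assert p < 1e-6


class TestDecileDynamicRange:
    def _universe(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(100, 20, n), index=[f"g{i}" for i in range(n)])

    def test_identical_genotypes_identical_report(self):
        wt = self._universe()
        rep = decile_dynamic_range(wt, wt.copy(), {f"g{i}" for i in range(100)})
        pd.testing.assert_series_equal(
            rep.proportions["wt"], rep.proportions["mut"], check_names=False
        )
        assert rep.sd_ratio == pytest.approx(1.0)
        assert rep.f_p == pytest.approx(1.0)

    def test_affine_shrinkage_gives_exact_sd_ratio(self):
        wt = self._universe()
        mut = wt.mean() + 0.7 * (wt - wt.mean())
        gene_set = {f"g{i}" for i in range(300)}
        rep = decile_dynamic_range(wt, mut, gene_set)
        assert rep.sd_ratio == pytest.approx(0.7)
        # shrinkage empties the extreme deciles for the mutant
        assert rep.proportions.loc[1, "mut"] <= rep.proportions.loc[1, "wt"]
        assert rep.proportions.loc[10, "mut"] <= rep.proportions.loc[10, "wt"]

    def test_wt_universe_occupies_deciles_uniformly(self):
        wt = self._universe()
        rep = decile_dynamic_range(wt, wt.copy(), set(wt.index))
        assert np.allclose(rep.proportions["wt"], 0.1, atol=0.01)

    def test_single_gene_set_flagged_degenerate(self):
        wt = self._universe(n=50)
        rep = decile_dynamic_range(wt, wt.copy(), {"g0"})
        assert any("degenerate" in f for f in rep.flags)

    def test_tiny_universe_rejected(self):
        wt = self._universe(n=5)
        with pytest.raises(ValueError):
            decile_dynamic_range(wt, wt.copy(), {"g0"})


class TestRegression:
    def test_total_plasticity_loss_gives_slope_minus_one(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        wt_focal = pd.Series(rng.uniform(50, 150, 50), index=genes)
        tissue_mean = pd.Series(100.0, index=genes)
        ref_fc = np.log2(wt_focal / tissue_mean)
        gen_fc = np.log2(tissue_mean / wt_focal)  # mutant sits exactly at the mean
        rep = tissue_specificity_regression(ref_fc, gen_fc)
        assert rep.slope == pytest.approx(-1.0, abs=1e-12)
        assert rep.r == pytest.approx(-1.0, abs=1e-12)

    def test_mutant_equal_wt_gives_flat_zero(self):
        genes = [f"g{i}" for i in range(10)]
        ref_fc = pd.Series(np.linspace(-2, 2, 10), index=genes)
        gen_fc = pd.Series(0.0, index=genes)
        rep = tissue_specificity_regression(ref_fc, gen_fc)
        assert rep.slope == 0.0
        assert rep.r2 == 0.0

    def test_partial_canalization_recovers_negative_slope(self):
        rng = np.random.default_rng(11)
        n = 400
        genes = [f"g{i}" for i in range(n)]
        m = 100.0
        e = rng.normal(0, 30, n)
        wt = pd.Series(m + e, index=genes)
        mut = pd.Series(m + 0.6 * rng.normal(0, 30, n), index=genes)
        ref_fc = np.log2(wt / m)
        gen_fc = np.log2(mut / wt)
        rep = tissue_specificity_regression(ref_fc, gen_fc)
        assert rep.slope < 0
        assert rep.p < 0.001

    def test_too_few_genes_rejected(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            tissue_specificity_regression(s, s)

    def test_log2_fold_change_aggregation(self):
        focal = pd.Series([3.0], index=["g"])
        others = pd.DataFrame([[1.0, 3.0]], index=["g"])
        assert log2_fold_change(focal, others, pseudocount=1.0).iloc[0] == pytest.approx(
            np.log2(4.0 / 3.0)
        )
        assert log2_fold_change(focal, others, agg="median", pseudocount=0.0).iloc[
            0
        ] == pytest.approx(np.log2(1.5))


class TestIntergenicControl:
    def _stats(self, n=200, seed=3, sd_scale=None):
        rng = np.random.default_rng(seed)
        base = rng.gamma(20, 5, size=(n, 12))
        if sd_scale is not None:
            dev = base - base.mean(axis=1, keepdims=True)
            base = base.mean(axis=1, keepdims=True) + dev * sd_scale[:, None]
        return plasticity_stats(matrix_from(np.clip(base, 0, None)))

    def _assoc(self, genes):
        return pd.DataFrame(
            {"gene_id": list(genes), "relation": "flank_2kb_upstream", "dmr_index": 0,
             "direction": "hyper"}
        )

    def test_null_flank_genes_show_no_cv_difference(self):
        st = self._stats()
        out = intergenic_control(self._assoc([f"g{i}" for i in range(0, 200, 4)]), st)
        p = out["pairwise"][("flank_dmr", "total")]["cv"]["p"]
        assert p > 0.05

    def test_doubled_spread_is_detected(self):
        scale = np.ones(200)
        scale[:50] = 2.0
        st = self._stats(sd_scale=scale)
        out = intergenic_control(self._assoc([f"g{i}" for i in range(50)]), st)
        p = out["pairwise"][("flank_dmr", "total")]["cv"]["p"]
        assert p < 0.01

    def test_empty_association_set_is_error(self):
        with pytest.raises(ValueError):
            intergenic_control(self._assoc([]), self._stats())
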