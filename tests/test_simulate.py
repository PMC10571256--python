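"""The synthetic-data generator: determinism, class structure, file dialects."""

import numpy as np
import pandas as pd
import pytest

from gbmdyn.io import pool_cg_dinucleotides, read_cytosine_report, read_gene_models
from gbmdyn.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_expression,
    simulate_methylomes,
    write_dataset,
)
from conftest import small_config


class TestDeterminism:
    def test_same_seed_identical_records_and_matrices(self):
        a = simulate_all(small_config(seed=3))
        b = simulate_all(small_config(seed=3))
        pd.testing.assert_frame_equal(a.wt.records, b.wt.records)
        pd.testing.assert_frame_equal(a.mut.records, b.mut.records)
        pd.testing.assert_frame_equal(a.expr_wt, b.expr_wt)
        pd.testing.assert_frame_equal(a.homologs, b.homologs)
        for name in a.chip_tracks:
            for chrom in a.chip_tracks[name]:
                assert np.array_equal(a.chip_tracks[name][chrom], b.chip_tracks[name][chrom])

    def test_different_seed_differs(self):
        a = simulate_all(small_config(seed=3))
        b = simulate_all(small_config(seed=4))
        assert not a.wt.records.equals(b.wt.records)


class TestConfigValidation:
    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(p_cell={"stable": (1.2, 0.9), "dynamic": (0.5, 0.9),
                                     "unmethylated": (0.0, 0.0)})

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_conditions=1)

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(coverage_mean=0)


class TestMethylomeStructure:
    def test_dynamic_sites_center_on_half_and_classify_heterogeneous(self, default_dataset):
        sites = pool_cg_dinucleotides(default_dataset.wt)
        truth = default_dataset.ground_truth
        dyn = truth[truth["epigenotype"] == "dynamic"]
        h = []
        for gene in dyn.itertuples():
            sub = sites[(sites["chrom"] == gene.chrom)
                        & (sites["start"] > gene.start) & (sites["start"] <= gene.end)]
            h.append(sub["h"].to_numpy())
        h = np.concatenate(h)
        assert abs(h.mean() - 0.5) < 0.02
        assert ((h > 0.10) & (h < 0.85)).mean() >= 0.90

    def test_unmethylated_sites_stay_below_cutoff(self, default_dataset):
        sites = pool_cg_dinucleotides(default_dataset.wt)
        truth = default_dataset.ground_truth
        unm = truth[truth["epigenotype"] == "unmethylated"]
        frac_low = []
        for gene in unm.itertuples():
            sub = sites[(sites["chrom"] == gene.chrom)
                        & (sites["start"] > gene.start) & (sites["start"] <= gene.end)]
            frac_low.append((sub["h"] <= 0.10).to_numpy())
        assert np.concatenate(frac_low).mean() >= 0.99

    def test_generated_files_pass_validators(self, tmp_path, small_dataset):
        paths = write_dataset(small_dataset, tmp_path)
        wt = read_cytosine_report(paths["wt"])
        pd.testing.assert_frame_equal(wt.records, small_dataset.wt.records)
        genes = read_gene_models(paths["genes"])
        pd.testing.assert_frame_equal(
            genes.reset_index(drop=True),
            small_dataset.genes.sort_values(["chrom", "start"]).reset_index(drop=True),
        )

    def test_control_contig_is_unmethylated(self, small_dataset):
        ctl = small_dataset.wt.subset(small_dataset.config.control_contig)
        frac = ctl["n_meth"].sum() / (ctl["n_meth"].sum() + ctl["n_unmeth"].sum())
        assert frac < 0.01


class TestExpression:
    def test_factor_one_matches_wt_spread(self):
        # a large dynamic set keeps the sd-ratio estimator's own spread small
        cfg = small_config(
            canalization_factor=1.0,
            n_expression_genes={"dynamic": 600, "stable": 60, "background": 80},
        )
        truth = pd.DataFrame(columns=["gene_id", "epigenotype"])
        wt, mut, _, et = simulate_expression(cfg, truth)
        dyn = et[et["expression_class"] == "dynamic"]["gene_id"]
        ratio = mut.loc[dyn, "cond00"].std() / wt.loc[dyn, "cond00"].std()
        assert ratio == pytest.approx(1.0, abs=0.2)

    def test_factor_shrinks_dynamic_class_only(self, default_dataset):
        et = default_dataset.expr_truth.set_index("gene_id")
        wt, mut = default_dataset.expr_wt, default_dataset.expr_mut
        dyn = et[et["expression_class"] == "dynamic"].index
        sta = et[et["expression_class"] == "stable"].index
        dyn_ratio = mut.loc[dyn, "cond00"].std() / wt.loc[dyn, "cond00"].std()
        sta_ratio = mut.loc[sta, "cond00"].std() / wt.loc[sta, "cond00"].std()
        assert dyn_ratio == pytest.approx(default_dataset.config.canalization_factor, abs=0.05)
        assert sta_ratio == pytest.approx(1.0, abs=0.05)

    def test_class_spread_ordering(self, default_dataset):
        et = default_dataset.expr_truth.set_index("gene_id")
        wt = default_dataset.expr_wt
        spreads = {
            cls: wt.loc[et[et["expression_class"] == cls].index].std(axis=1).median()
            for cls in ("dynamic", "background", "stable")
        }
        assert spreads["dynamic"] > spreads["background"] > spreads["stable"]


class TestConservationSim:
    def test_zero_filter_fractions_keep_all_pairs(self):
        cfg = small_config(frac_non_one_to_one=0.0, frac_high_noncg=0.0)
        ds = simulate_all(cfg)
        assert ds.homologs["one_to_one"].all()
        assert not ds.homologs["high_non_cg"].any()

    def test_non_one_to_one_fraction_marked(self, small_dataset):
        frac = (~small_dataset.homologs["one_to_one"]).mean()
        assert 0.0 < frac < 0.35  # configured 10 %, small-sample spread allowed


class TestChipSim:
    def test_states_partition_each_contig(self, small_dataset):
        for chrom, sub in small_dataset.states.groupby("chrom"):
            sub = sub.sort_values("start")
            assert sub.iloc[0]["start"] == 0
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_multiplier_paints_dynamic_bodies(self, small_dataset):
        truth = small_dataset.ground_truth.set_index("gene_id")
        track = small_dataset.chip_tracks["regulatory"]
        cfg = small_dataset.config
        dyn = truth[truth["epigenotype"] == "dynamic"].iloc[0]
        unm = truth[truth["epigenotype"] == "unmethylated"].iloc[0]
        mean_dyn = track[dyn["chrom"]][dyn["start"] + 30 : dyn["end"] - 30].mean()
        mean_unm = track[unm["chrom"]][unm["start"] + 30 : unm["end"] - 30].mean()
        assert mean_dyn / mean_unm == pytest.approx(cfg.chip_enrichment_multiplier, rel=0.25)
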