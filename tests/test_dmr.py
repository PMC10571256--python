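"""DMR calling against a brute-force all-window oracle, plus associations."""

import numpy as np
import pandas as pd
import pytest

from gbmdyn.dmr import (
    FLANK_DOWN,
    FLANK_UP,
    GENE_BODY,
    HYPER,
    HYPO,
    associate_dmrs,
    call_dmrs,
    differential_sites,
)
from conftest import make_sites


def oracle_dmrs(sites: pd.DataFrame, window_bp: int = 200, min_sites: int = 5) -> pd.DataFrame:
    """Independent enumerator: slide a window over every possible start.

    For each chromosome and direction, every window start position from
    min(pos) - window to max(pos) is tested; windows holding >= min_sites
    same-direction sites are trimmed to their member sites; trimmed intervals
    that overlap or touch are merged.
    """
    out = []
    work = sites.assign(direction=np.where(sites["delta"] > 0, HYPER, HYPO))
    for (chrom, direction), grp in work.groupby(["chrom", "direction"], sort=True):
        pos = np.sort(grp["start"].to_numpy())
        deltas = grp.sort_values("start")["delta"].to_numpy()
        candidates = []
        for w in range(int(pos.min()) - window_bp, int(pos.max()) + 1):
            inside = (pos >= w) & (pos < w + window_bp)
            if inside.sum() >= min_sites:
                member = pos[inside]
                candidates.append((member.min() - 1, member.max() + 1))
        merged = []
        for s, e in sorted(set(candidates)):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            member = (pos >= s + 1) & (pos <= e - 1)
            out.append(
                {
                    "chrom": chrom,
                    "start": int(s),
                    "end": int(e),
                    "n_diff_sites": int(member.sum()),
                    "mean_delta": float(deltas[member].mean()),
                    "direction": direction,
                }
            )
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_diff_sites", "mean_delta", "direction"])
    return (
        pd.DataFrame(out)
        .sort_values(["chrom", "start", "direction"], kind="stable")
        .reset_index(drop=True)
    )


def diff_frame(positions, deltas, chrom="Chr1"):
    return pd.DataFrame({"chrom": chrom, "start": positions, "delta": deltas})


class TestDifferentialSites:
    def test_threshold_inclusion_and_sign(self):
        a = make_sites([("Chr1", 100, 3, 10), ("Chr1", 200, 5, 10)])
        b = make_sites([("Chr1", 100, 6, 10), ("Chr1", 200, 6, 10)])
        diff = differential_sites(a, b, min_coverage=5, min_delta=20.0)
        assert diff["start"].tolist() == [100]
        assert diff["delta"].iloc[0] == pytest.approx(30.0)

    def test_identical_methylomes_give_no_sites(self):
        a = make_sites([("Chr1", 100, 3, 10)])
        assert differential_sites(a, a.copy()).empty

    def test_coverage_floor_applies_to_both_samples(self):
        a = make_sites([("Chr1", 100, 0, 4)])
        b = make_sites([("Chr1", 100, 10, 10)])
        assert differential_sites(a, b, min_coverage=5).empty

    def test_swapping_samples_negates_deltas(self):
        a = make_sites([("Chr1", 100, 2, 10), ("Chr1", 300, 9, 10)])
        b = make_sites([("Chr1", 100, 8, 10), ("Chr1", 300, 1, 10)])
        fwd = differential_sites(a, b)
        rev = differential_sites(b, a)
        assert np.allclose(fwd["delta"].to_numpy(), -rev["delta"].to_numpy())


class TestCallDmrs:
    def test_six_clustered_hyper_sites_give_one_dmr(self):
        sites = diff_frame([100, 130, 160, 190, 220, 250], [30.0] * 6)
        dmrs = call_dmrs(sites)
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["direction"] == HYPER
        assert row["n_diff_sites"] == 6
        pd.testing.assert_frame_equal(dmrs, oracle_dmrs(sites))

    def test_four_sites_below_threshold_give_none(self):
        sites = diff_frame([100, 150, 200, 250], [30.0] * 4)
        assert call_dmrs(sites, min_sites=5).empty

    def test_opposite_direction_clusters_yield_two_dmrs(self):
        sites = diff_frame(
            [100, 130, 160, 190, 220, 10100, 10130, 10160, 10190, 10220],
            [25.0] * 5 + [-25.0] * 5,
        )
        dmrs = call_dmrs(sites)
        assert sorted(dmrs["direction"]) == [HYPER, HYPO]
        pd.testing.assert_frame_equal(dmrs, oracle_dmrs(sites))

    def test_cluster_spanning_grid_boundary_is_found(self):
        # span 199 bp: fits in some 200-bp window but in no 100-bp-stepped one
        sites = diff_frame([990, 1040, 1090, 1140, 1189], [30.0] * 5)
        dmrs = call_dmrs(sites)
        assert len(dmrs) == 1
        pd.testing.assert_frame_equal(dmrs, oracle_dmrs(sites))

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 50))
            pos = np.sort(rng.choice(np.arange(100, 3000), size=n, replace=False))
            deltas = rng.choice([-30.0, 30.0], size=n)
            sites = diff_frame(pos, deltas)
            pd.testing.assert_frame_equal(call_dmrs(sites), oracle_dmrs(sites))

    def test_output_nonoverlapping_within_direction(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(np.arange(100, 2000), size=40, replace=False))
        dmrs = call_dmrs(diff_frame(pos, [25.0] * 40))
        for _, grp in dmrs.groupby("direction"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_empty_input(self):
        assert call_dmrs(diff_frame([], [])).empty


class TestAssociateDmrs:
    GENES = pd.DataFrame(
        [
            {"gene_id": "gPlus", "chrom": "Chr1", "start": 10000, "end": 12000, "strand": "+"},
            {"gene_id": "gMinus", "chrom": "Chr1", "start": 30000, "end": 32000, "strand": "-"},
        ]
    )

    def _dmr(self, start, end):
        return pd.DataFrame(
            [{"chrom": "Chr1", "start": start, "end": end, "n_diff_sites": 5,
              "mean_delta": 30.0, "direction": HYPER}]
        )

    def test_dmr_inside_gene_is_gene_body(self):
        assoc = associate_dmrs(self._dmr(10500, 10800), self.GENES)
        assert assoc.iloc[0]["relation"] == GENE_BODY

    def test_dmr_upstream_of_plus_gene_is_upstream_flank(self):
        assoc = associate_dmrs(self._dmr(9400, 9500), self.GENES)
        assert assoc.iloc[0][["gene_id", "relation"]].tolist() == ["gPlus", FLANK_UP]

    def test_strand_aware_flanks_for_minus_gene(self):
        assoc = associate_dmrs(self._dmr(32500, 32600), self.GENES)
        assert assoc.iloc[0][["gene_id", "relation"]].tolist() == ["gMinus", FLANK_UP]
        assoc = associate_dmrs(self._dmr(29500, 29600), self.GENES)
        assert assoc.iloc[0][["gene_id", "relation"]].tolist() == ["gMinus", FLANK_DOWN]

    def test_distant_dmr_has_no_association(self):
        assert associate_dmrs(self._dmr(20000, 20100), self.GENES).empty
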