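"""Gene classification: Dynamic GbM vs Stable GbM.

Dynamic GbM genes are the targets of active demethylation: in wild type their
gene-body CGs are methylated in only a subset of cells, and removing the
demethylase pathway ("eraser" mutant) drives them to full methylation. The
two-cutoff rule is

1. at least one hypermethylated wild-type-vs-mutant DMR overlaps the gene
   body, and
2. at least 5 CG dinucleotides (10 CG cytosines) inside the gene body gain
   more than 20 percentage points of methylation in the mutant.

Stable GbM genes show near-complete methylation of gene-body CGs in every
cell: a one-sided per-gene binomial test asks whether the count of fully
methylated CG sites exceeds the genome-background expectation
(Benjamini-Hochberg q < 0.05), with ceilings on gene-body CHG/CHH methylation
to exclude heterochromatin-like (teM) genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import dmr as dmr_mod
from .heterogeneity import (
    DEFAULT_MIN_COVERAGE,
    HeterogeneityCutoffs,
    METHYLATED,
    classify_sites,
)

DYNAMIC = "dynamic"
STABLE = "stable"
BOTH = "both"
NEITHER = "neither"


@dataclass(frozen=True)
class StableGbmTestConfig:
    """Parameters of the Stable-GbM binomial test.

    ``background_rate`` is the genome-wide fraction of callable CG sites in
    the fully methylated class; ``None`` means estimate it from the methylome
    under test. CHG/CHH ceilings (default 1 %) exclude genes carrying
    non-CG (de novo pathway) methylation.
    """

    background_rate: float | None = None
    min_sites: int = 10
    alpha: float = 0.05
    max_chg: float = 0.01
    max_chh: float = 0.01


def gaining_dinucleotides(
    wt_sites: pd.DataFrame,
    mut_sites: pd.DataFrame,
    min_gain: float = 0.20,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """CG dinucleotides with h_mut - h_wt strictly above ``min_gain``.

    Both samples must cover the site at ``min_coverage``; the gain is an
    absolute difference in the cell fraction (0.20 = 20 percentage points).
    """
    merged = wt_sites.merge(mut_sites, on=["chrom", "start"], suffixes=("_wt", "_mut"))
    merged = merged[
        (merged["n_total_wt"] >= min_coverage) & (merged["n_total_mut"] >= min_coverage)
    ]
    gain = merged["h_mut"] - merged["h_wt"]
    return merged.loc[gain > min_gain, ["chrom", "start"]].reset_index(drop=True)


def classify_dynamic_genes(
    genes: pd.DataFrame,
    wt_sites: pd.DataFrame,
    mut_sites: pd.DataFrame,
    dmrs: pd.DataFrame,
    min_gain: float = 0.20,
    min_gaining: int = 5,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Apply the two-cutoff Dynamic-GbM rule to every gene.

    Returns gene_id, has_genebody_dmr, n_gaining_dinucleotides, dynamic.
    Only hyper-direction DMRs count — the rule is about methylation *gain*
    in the eraser mutant.
    """
    hyper = dmrs[dmrs["direction"] == dmr_mod.HYPER]
    gainers = gaining_dinucleotides(wt_sites, mut_sites, min_gain, min_coverage)

    rows = []
    for chrom, chrom_genes in genes.groupby("chrom", sort=False):
        g = gainers[gainers["chrom"] == chrom]
        gpos0 = np.sort(g["start"].to_numpy() - 1)
        d = hyper[hyper["chrom"] == chrom]
        dstart = d["start"].to_numpy()
        dend = d["end"].to_numpy()
        for gene in chrom_genes.itertuples():
            n_gain = int(
                np.searchsorted(gpos0, gene.end) - np.searchsorted(gpos0, gene.start)
            )
            has_dmr = bool(np.any((dstart < gene.end) & (dend > gene.start)))
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "has_genebody_dmr": has_dmr,
                    "n_gaining_dinucleotides": n_gain,
                    "dynamic": has_dmr and n_gain >= min_gaining,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "has_genebody_dmr", "n_gaining_dinucleotides", "dynamic"])


def background_methylated_rate(
    sites: pd.DataFrame,
    cutoffs: HeterogeneityCutoffs = HeterogeneityCutoffs(),
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> float:
    """Genome-wide fraction of callable CG sites in the fully methylated class."""
    cls = classify_sites(sites, cutoffs, min_coverage)
    callable_cls = cls[cls != "uncallable"]
    if callable_cls.empty:
        raise ValueError("no callable CG sites to estimate a background rate from")
    return float((callable_cls == METHYLATED).mean())


def classify_stable_genes(
    profiles: pd.DataFrame,
    cfg: StableGbmTestConfig = StableGbmTestConfig(),
    background_rate: float | None = None,
) -> pd.DataFrame:
    """Per-gene binomial Stable-GbM test over gene profiles.

    ``profiles`` comes from :func:`gbmdyn.heterogeneity.gene_profiles` and must
    carry n_sites, n_methylated, chg, chh. A gene is Stable when the one-sided
    binomial tail P(X >= n_methylated | n_sites, background) survives BH FDR at
    ``cfg.alpha`` and both non-CG fractions sit below their ceilings.
    Genes with fewer than ``cfg.min_sites`` callable sites are not testable.
    """
    bg = background_rate if background_rate is not None else cfg.background_rate
    if bg is None:
        raise ValueError("background_rate must be supplied or set in the config")
    out = profiles[["gene_id", "n_sites", "n_methylated"]].copy()
    out["testable"] = out["n_sites"] >= cfg.min_sites
    # one-sided upper tail: P(X >= k) under Binomial(n, bg)
    k = out["n_methylated"].to_numpy()
    n = out["n_sites"].to_numpy()
    pvals = np.where(out["testable"], stats.binom.sf(k - 1, np.maximum(n, 1), bg), np.nan)
    out["p"] = pvals
    out["q"] = np.nan
    tested = out["testable"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = multipletests(pvals[tested], method="fdr_bh")[1]
    low_noncg = (profiles["chg"].to_numpy() < cfg.max_chg) & (
        profiles["chh"].to_numpy() < cfg.max_chh
    )
    out["low_non_cg"] = low_noncg
    out["stable"] = tested & (out["q"].to_numpy() < cfg.alpha) & low_noncg
    return out


def classify_genes(
    genes: pd.DataFrame,
    profiles_wt: pd.DataFrame,
    wt_sites: pd.DataFrame,
    mut_sites: pd.DataFrame,
    dmrs: pd.DataFrame,
    stable_cfg: StableGbmTestConfig = StableGbmTestConfig(),
    stable_list: set[str] | None = None,
    min_gain: float = 0.20,
    min_gaining: int = 5,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    cutoffs: HeterogeneityCutoffs = HeterogeneityCutoffs(),
) -> pd.DataFrame:
    """Joint classification table with labels dynamic / stable / both / neither.

    ``stable_list`` (when given) overrides the binomial test with a
    pre-computed Stable-GbM gene list.
    """
    dyn = classify_dynamic_genes(
        genes, wt_sites, mut_sites, dmrs, min_gain, min_gaining, min_coverage
    )
    table = dyn.merge(profiles_wt, on="gene_id", how="left")
    if stable_list is not None:
        table["stable"] = table["gene_id"].isin(stable_list)
        table["stable_q"] = np.nan
    else:
        bg = stable_cfg.background_rate
        if bg is None:
            bg = background_methylated_rate(wt_sites, cutoffs, min_coverage)
        stab = classify_stable_genes(profiles_wt, stable_cfg, background_rate=bg)
        table = table.merge(
            stab[["gene_id", "q", "stable"]].rename(columns={"q": "stable_q"}),
            on="gene_id",
            how="left",
        )
        table["stable"] = table["stable"].fillna(False).astype(bool)
    # genes with no callable data cannot carry either label
    no_data = table["no_data"].fillna(True).astype(bool)
    table.loc[no_data, ["dynamic", "stable"]] = False
    table["label"] = np.select(
        [
            table["dynamic"] & table["stable"],
            table["dynamic"],
            table["stable"],
        ],
        [BOTH, DYNAMIC, STABLE],
        default=NEITHER,
    )
    return table


def resolve_overlap(classifications: pd.DataFrame) -> dict:
    """Partition labelled genes and build the expression-analysis exclusion list.

    Genes labelled ``both`` stay in the Venn summary but are excluded from
    downstream set comparisons (the expression analysis removes genes found in
    both the Stable and Dynamic groups).
    """
    labels = classifications.set_index("gene_id")["label"]
    dynamic = set(labels.index[labels.isin([DYNAMIC, BOTH])])
    stable = set(labels.index[labels.isin([STABLE, BOTH])])
    excluded = set(labels.index[labels == BOTH])
    return {
        "dynamic": sorted(dynamic - excluded),
        "stable": sorted(stable - excluded),
        "excluded_overlap": sorted(excluded),
        "venn": {
            "n_dynamic": len(dynamic),
            "n_stable": len(stable),
            "n_overlap": len(excluded),
        },
    }
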