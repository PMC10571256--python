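"""Per-CG methylation heterogeneity and site / gene-body classification.

Each pooled CG dinucleotide carries a heterogeneity fraction h = methylated
reads / total reads; because deduplicated reads derive from independent cells,
h estimates the fraction of cells in which that CG is methylated. Sites are
classified with two cutoffs (defaults 10 % and 85 %):

* h <= low   -> unmethylated
* h >= high  -> fully methylated
* otherwise  -> heterogeneously methylated

Both boundaries leave the heterogeneous class, so the three classes partition
[0, 1] for any covered site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MethylomeTable

UNMETHYLATED = "unmethylated"
HETEROGENEOUS = "heterogeneous"
METHYLATED = "methylated"
UNCALLABLE = "uncallable"
SITE_CLASSES = (UNMETHYLATED, HETEROGENEOUS, METHYLATED)

DEFAULT_MIN_COVERAGE = 5


@dataclass(frozen=True)
class HeterogeneityCutoffs:
    low: float = 0.10
    high: float = 0.85

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high < 1.0):
            raise ValueError(f"cutoffs must satisfy 0 < low < high < 1, got {self}")


def classify_site(h: float, cutoffs: HeterogeneityCutoffs = HeterogeneityCutoffs()) -> str:
    """Classify a single heterogeneity fraction; total step function of h."""
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"h must lie in [0, 1], got {h}")
    if h <= cutoffs.low:
        return UNMETHYLATED
    if h >= cutoffs.high:
        return METHYLATED
    return HETEROGENEOUS


def classify_sites(
    sites: pd.DataFrame,
    cutoffs: HeterogeneityCutoffs = HeterogeneityCutoffs(),
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.Series:
    """Vectorized site classification; low-coverage sites become "uncallable"."""
    h = sites["h"].to_numpy(dtype=float)
    n = sites["n_total"].to_numpy()
    labels = np.where(
        h <= cutoffs.low, UNMETHYLATED, np.where(h >= cutoffs.high, METHYLATED, HETEROGENEOUS)
    )
    labels = np.where((n >= min_coverage) & ~np.isnan(h), labels, UNCALLABLE)
    return pd.Series(labels, index=sites.index, name="site_class")


def gene_profiles(
    genes: pd.DataFrame,
    sites: pd.DataFrame,
    methylome: MethylomeTable | None = None,
    cutoffs: HeterogeneityCutoffs = HeterogeneityCutoffs(),
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    methylated_domains_only: bool = False,
) -> pd.DataFrame:
    """Per-gene methylation profile over the gene body.

    A dinucleotide belongs to a gene when its + strand C position (1-based
    ``start``) falls inside the 0-based half-open gene interval. Columns:
    n_sites (callable), n_unmethylated / n_heterogeneous / n_methylated,
    mcg (coverage-weighted gene-body CG methylation: sum n_meth / sum n_total),
    non_cg (pooled CHG+CHH methylation fraction over gene-body cytosines),
    chg / chh (per-context fractions) and a ``no_data`` flag for genes with no
    callable CG site.

    ``methylated_domains_only`` restricts the profile to sites with h > low
    (used for cross-tissue comparisons of the methylated compartment).
    """
    sites = sites.copy()
    sites["site_class"] = classify_sites(sites, cutoffs, min_coverage)
    callable_sites = sites[sites["site_class"] != UNCALLABLE]
    if methylated_domains_only:
        callable_sites = callable_sites[callable_sites["h"] > cutoffs.low]

    noncg = None
    if methylome is not None:
        noncg = methylome.records[methylome.records["context"].isin(("CHG", "CHH"))]

    rows = []
    for chrom, chrom_genes in genes.groupby("chrom", sort=False):
        csites = callable_sites[callable_sites["chrom"] == chrom]
        # site start is 1-based; gene interval 0-based half-open
        pos0 = csites["start"].to_numpy() - 1
        order = np.argsort(pos0, kind="stable")
        pos0 = pos0[order]
        cls = csites["site_class"].to_numpy()[order]
        smeth = csites["n_meth"].to_numpy()[order]
        stot = csites["n_total"].to_numpy()[order]

        if noncg is not None:
            cn = noncg[noncg["chrom"] == chrom]
            npos0 = cn["pos"].to_numpy() - 1
            norder = np.argsort(npos0, kind="stable")
            npos0 = npos0[norder]
            n_meth_nc = cn["n_meth"].to_numpy()[norder]
            n_tot_nc = n_meth_nc + cn["n_unmeth"].to_numpy()[norder]
            n_ctx = cn["context"].to_numpy()[norder]

        for gene in chrom_genes.itertuples():
            lo, hi = np.searchsorted(pos0, [gene.start, gene.end])
            gcls = cls[lo:hi]
            n_sites = hi - lo
            tot = stot[lo:hi].sum()
            row = {
                "gene_id": gene.gene_id,
                "n_sites": int(n_sites),
                "n_unmethylated": int((gcls == UNMETHYLATED).sum()),
                "n_heterogeneous": int((gcls == HETEROGENEOUS).sum()),
                "n_methylated": int((gcls == METHYLATED).sum()),
                "mcg": float(smeth[lo:hi].sum() / tot) if tot > 0 else np.nan,
                "no_data": n_sites == 0,
            }
            if noncg is not None:
                nlo, nhi = np.searchsorted(npos0, [gene.start, gene.end])
                gm, gt = n_meth_nc[nlo:nhi], n_tot_nc[nlo:nhi]
                gctx = n_ctx[nlo:nhi]
                row["non_cg"] = float(gm.sum() / gt.sum()) if gt.sum() > 0 else 0.0
                chg = gctx == "CHG"
                chh = gctx == "CHH"
                row["chg"] = float(gm[chg].sum() / gt[chg].sum()) if gt[chg].sum() > 0 else 0.0
                row["chh"] = float(gm[chh].sum() / gt[chh].sum()) if gt[chh].sum() > 0 else 0.0
            rows.append(row)

    cols = [
        "gene_id",
        "n_sites",
        "n_unmethylated",
        "n_heterogeneous",
        "n_methylated",
        "mcg",
        "no_data",
    ] + (["non_cg", "chg", "chh"] if noncg is not None else [])
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


def heterogeneity_distribution(
    sites: pd.DataFrame,
    bins: int = 100,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of h over all covered CG sites (genome-wide violin input)."""
    covered = sites[(sites["n_total"] >= min_coverage) & sites["h"].notna()]
    return np.histogram(covered["h"].to_numpy(dtype=float), bins=bins, range=(0.0, 1.0))
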