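"""Gene-expression plasticity statistics.

Plasticity of a gene across tissues/conditions is summarized by the
coefficient of variation (CV = sd / mean, scale-free, can overstate lowly
expressed genes) and the Fano factor (variance / mean, the index of
dispersion, can overstate highly expressed genes); a robust class difference
should hold under both. The dynamic-range analysis compares where a gene set
sits in the genome-wide expression deciles in two genotypes, with a classical
two-tailed variance-ratio F-test, and the tissue-specificity regression asks
whether a mutant's expression changes run opposite to a gene's natural
tissue enrichment (the canalization signature: slope -> -1 for total loss of
plasticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DecileReport:
    decile_edges: np.ndarray
    proportions: pd.DataFrame  # rows deciles 1..10, columns genotypes
    sd: dict[str, float]
    sd_ratio: float  # mutant / wild type
    f_statistic: float
    f_p: float
    n_genes: int
    flags: list[str] = field(default_factory=list)


@dataclass
class RegressionReport:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n_genes: int


def plasticity_stats(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-gene mean, sd, CV and Fano factor across the matrix columns.

    Zero-mean genes get NaN CV/Fano and are flagged; constant genes get 0 for
    both. Unbiased (ddof=1) variance so that Poisson counts give Fano ~ 1.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("expression matrix contains negative values")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
        fano = np.where(mean > 0, sd**2 / mean, np.nan)
    return pd.DataFrame(
        {
            "gene_id": matrix.index,
            "mean": mean,
            "sd": sd,
            "cv": cv,
            "fano": fano,
            "zero_mean": mean == 0,
        }
    ).set_index("gene_id")


def average_replicates(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate samples to per-condition means.

    ``metadata`` has columns sample, condition (and optionally genotype,
    replicate); output columns are conditions.
    """
    cond = metadata.set_index("sample")["condition"]
    return matrix.T.groupby(cond.reindex(matrix.columns)).mean().T


def compare_sets(
    stats_table: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    exclusion: set[str] | None = None,
) -> dict:
    """Per-set CV/Fano distributions and pairwise two-tailed Welch t-tests.

    Genes on the exclusion list (Dynamic-Stable overlap) are removed from
    every set; genes absent from the matrix are counted, not errors.
    """
    exclusion = exclusion or set()
    per_set = {}
    missing = {}
    for name, members in gene_sets.items():
        members = set(members) - exclusion
        present = stats_table.index.intersection(members)
        missing[name] = len(members) - len(present)
        sub = stats_table.loc[present]
        sub = sub[~sub["zero_mean"]]
        per_set[name] = sub
    names = list(per_set)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = {}
            for metric in ("cv", "fano"):
                t = stats.ttest_ind(per_set[a][metric], per_set[b][metric], equal_var=False)
                res[metric] = {
                    "median_a": float(per_set[a][metric].median()),
                    "median_b": float(per_set[b][metric].median()),
                    "p": float(t.pvalue),
                }
            pairwise[(a, b)] = res
    return {"per_set": per_set, "pairwise": pairwise, "n_missing": missing}


def variance_f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Classical two-sample variance-ratio F-test, two-tailed."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0 and vx == 0:
        return 1.0, 1.0
    if vy == 0 or vx == 0:
        return np.inf, 0.0
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.sf(f, dfx, dfy), stats.f.cdf(f, dfx, dfy))
    return float(f), float(min(p, 1.0))


def decile_dynamic_range(
    wt_expr: pd.Series,
    mut_expr: pd.Series,
    gene_set: set[str],
) -> DecileReport:
    """Expression-decile occupancy and variance of a gene set in two genotypes.

    Decile edges come from the wild-type genome-wide distribution (so the WT
    universe occupies 10 % per decile by construction); the gene set's
    per-decile proportions are reported for each genotype, together with the
    per-genotype standard deviation of the set's expression and a two-tailed
    F-test for equality of variance.
    """
    universe = wt_expr.index.intersection(mut_expr.index)
    if len(universe) < 10:
        raise ValueError("need at least 10 genes in the shared universe")
    wt = wt_expr.loc[universe]
    mut = mut_expr.loc[universe]
    edges = np.quantile(wt.to_numpy(dtype=float), np.arange(0.1, 1.0, 0.1))

    members = [g for g in universe if g in gene_set]
    flags = []
    if len(members) < 2:
        flags.append("degenerate: fewer than 2 set genes in the universe")
    wt_set = wt.loc[members].to_numpy(dtype=float)
    mut_set = mut.loc[members].to_numpy(dtype=float)

    props = {}
    for name, vals in (("wt", wt_set), ("mut", mut_set)):
        deciles = np.digitize(vals, edges)  # 0..9
        counts = np.bincount(deciles, minlength=10)
        props[name] = counts / counts.sum() if counts.sum() else np.zeros(10)
    proportions = pd.DataFrame(props, index=pd.RangeIndex(1, 11, name="decile"))

    sd_wt = float(np.std(wt_set, ddof=1)) if len(members) >= 2 else np.nan
    sd_mut = float(np.std(mut_set, ddof=1)) if len(members) >= 2 else np.nan
    if len(members) >= 2:
        f, p = variance_f_test(wt_set, mut_set)
    else:
        f, p = np.nan, np.nan
    return DecileReport(
        decile_edges=edges,
        proportions=proportions,
        sd={"wt": sd_wt, "mut": sd_mut},
        sd_ratio=sd_mut / sd_wt if sd_wt else np.nan,
        f_statistic=f,
        f_p=p,
        n_genes=len(members),
        flags=flags,
    )


def log2_fold_change(
    focal: pd.Series,
    others: pd.DataFrame,
    agg: str = "mean",
    pseudocount: float = 1.0,
) -> pd.Series:
    """log2(focal / aggregate of other conditions) with a pseudocount.

    ``agg`` is "mean" (default) or "median" of the other-condition columns.
    """
    other = others.mean(axis=1) if agg == "mean" else others.median(axis=1)
    return np.log2((focal + pseudocount) / (other + pseudocount))


def tissue_specificity_regression(
    reference_fc: pd.Series,
    genotype_fc: pd.Series,
    gene_set: set[str] | None = None,
) -> RegressionReport:
    """OLS of mutant-vs-WT fold change on tissue-specificity fold change.

    ``reference_fc``: per-gene log2 FC of the focal tissue against the other
    tissues in wild type; ``genotype_fc``: per-gene log2 FC mutant vs wild
    type in the focal tissue. A negative slope means genes enriched in the
    focal tissue lose expression in the mutant (loss of plasticity). Genes
    missing from either series (e.g. zero coverage) are excluded upstream.
    """
    shared = reference_fc.index.intersection(genotype_fc.index)
    if gene_set is not None:
        shared = shared.intersection(pd.Index(sorted(gene_set)))
    x = reference_fc.loc[shared].to_numpy(dtype=float)
    y = genotype_fc.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("fewer than 3 genes after filtering")
    if np.allclose(y, y[0]):
        # degenerate flat response (e.g. mutant identical to wild type)
        return RegressionReport(slope=0.0, intercept=float(y[0]), r=0.0, r2=0.0, p=1.0, n_genes=len(x))
    res = stats.linregress(x, y)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n_genes=len(x),
    )


def intergenic_control(
    associations: pd.DataFrame,
    stats_table: pd.DataFrame,
    flank_relations: tuple[str, ...] = ("flank_2kb_upstream", "flank_2kb_downstream"),
) -> dict:
    """Plasticity of genes with flank (intergenic) DMRs vs all genes.

    Tests whether genes merely *near* a demethylase target share the elevated
    expression variance of genes whose bodies are targeted; under the model
    they should not.
    """
    flank_genes = set(associations.loc[associations["relation"].isin(flank_relations), "gene_id"])
    if not flank_genes:
        raise ValueError("empty flank-DMR association set")
    return compare_sets(
        stats_table,
        {"flank_dmr": flank_genes, "total": set(stats_table.index)},
    )
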