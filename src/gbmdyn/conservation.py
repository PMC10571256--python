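"""Cross-species conservation of the heterogeneously methylated state.

Homologs (one-to-one orthologs only) of Dynamic-GbM genes in a second species
are scored for gene-body CGs methylated in an intermediate fraction of cells
(low < h < high). Enrichment is measured against k random gene sets of the
same size drawn from the source-species universe, mapped through the same
homolog table and filters; both the per-gene count and the per-covered-CG
density are compared, with an unpaired two-tailed Welch t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .heterogeneity import DEFAULT_MIN_COVERAGE, HeterogeneityCutoffs

logger = logging.getLogger(__name__)

HOMOLOG_COLUMNS = ["source_gene", "target_gene", "one_to_one", "species"]


@dataclass
class EnrichmentResult:
    species: str
    n_target_genes: int
    mean_count: float
    mean_density: float
    random_mean_count: float
    random_mean_density: float
    random_set_mean_counts: list[float]
    fold_count: float
    fold_density: float
    p_count: float
    p_density: float
    k: int
    flags: list[str] = field(default_factory=list)


def read_homolog_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(HOMOLOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"homolog table missing columns: {sorted(missing)}")
    df["one_to_one"] = df["one_to_one"].astype(bool)
    if df.duplicated(["source_gene", "target_gene", "species"]).any():
        raise ValueError("duplicate homolog pairs")
    return df


def filter_homologs(
    pairs: pd.DataFrame,
    target_profiles: pd.DataFrame,
    max_non_cg: float = 0.01,
) -> pd.DataFrame:
    """Keep one-to-one pairs whose target gene body has <= 1 % non-CG methylation.

    Genes carrying more non-CG methylation are targets of de novo methylation
    pathways, which would confound CG heterogeneity. Pairs whose target gene is
    absent from the target-species profiles are dropped with a warning. The two
    filters commute (each is a per-pair predicate).
    """
    keep = pairs[pairs["one_to_one"]].copy()
    prof = target_profiles.set_index("gene_id")
    known = keep["target_gene"].isin(prof.index)
    if (~known).any():
        logger.warning(
            "%d homolog pairs dropped: target gene absent from gene models", int((~known).sum())
        )
    keep = keep[known]
    non_cg = prof.loc[keep["target_gene"], "non_cg"].to_numpy()
    return keep[non_cg <= max_non_cg].reset_index(drop=True)


def count_het_cgs(
    target_profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene count and density of heterogeneously methylated gene-body CGs.

    ``target_profiles`` comes from :func:`gbmdyn.heterogeneity.gene_profiles`
    (which already applied the low/high cutoffs); density is count per covered
    CG site. Genes with zero covered sites are excluded.
    """
    prof = target_profiles[target_profiles["n_sites"] > 0].copy()
    out = pd.DataFrame(
        {
            "gene_id": prof["gene_id"],
            "het_count": prof["n_heterogeneous"].astype(int),
            "het_density": prof["n_heterogeneous"] / prof["n_sites"],
        }
    )
    return out.reset_index(drop=True)


def _set_values(
    source_set: set[str],
    pairs: pd.DataFrame,
    het_table: pd.DataFrame,
) -> pd.DataFrame:
    targets = pairs.loc[pairs["source_gene"].isin(source_set), "target_gene"]
    return het_table[het_table["gene_id"].isin(set(targets))]


def enrichment_vs_random(
    target_set: set[str],
    universe: list[str],
    pairs: pd.DataFrame,
    het_table: pd.DataFrame,
    k: int = 10,
    seed: int | None = None,
    species: str = "",
    exclude_target_from_universe: bool = True,
) -> EnrichmentResult:
    """Heterogeneous-CG enrichment of a gene set over k random same-size sets.

    ``pairs`` must already be filtered (:func:`filter_homologs`). Random sets
    are drawn without replacement from the source-species ``universe``
    (excluding the target set by default), pushed through the homolog mapping
    and the same counting. Folds are mean(target) over the average of the k
    random-set means; p-values are unpaired two-tailed Welch t-tests of the
    target per-gene values against the pooled random per-gene values.
    """
    rng = np.random.default_rng(seed)
    flags: list[str] = []
    if k < 2:
        flags.append("low_confidence_baseline: k < 2 random sets")
    pool = [g for g in universe if g not in target_set] if exclude_target_from_universe else list(universe)
    if len(pool) < len(target_set):
        raise ValueError(
            f"universe ({len(pool)} genes) smaller than target set ({len(target_set)})"
        )

    tvals = _set_values(target_set, pairs, het_table)
    set_counts, set_dens, rand_counts, rand_dens = [], [], [], []
    for _ in range(k):
        draw = set(rng.choice(pool, size=len(target_set), replace=False))
        rvals = _set_values(draw, pairs, het_table)
        if rvals.empty:
            continue
        set_counts.append(rvals["het_count"].mean())
        set_dens.append(rvals["het_density"].mean())
        rand_counts.append(rvals["het_count"].to_numpy())
        rand_dens.append(rvals["het_density"].to_numpy())
    if not set_counts:
        raise ValueError("no random set produced any homolog-mapped genes")

    rand_count_pool = np.concatenate(rand_counts)
    rand_den_pool = np.concatenate(rand_dens)
    mean_count = float(tvals["het_count"].mean())
    mean_density = float(tvals["het_density"].mean())
    rmc = float(np.mean(set_counts))
    rmd = float(np.mean(set_dens))
    p_count = float(
        stats.ttest_ind(tvals["het_count"], rand_count_pool, equal_var=False).pvalue
    )
    p_density = float(
        stats.ttest_ind(tvals["het_density"], rand_den_pool, equal_var=False).pvalue
    )
    return EnrichmentResult(
        species=species,
        n_target_genes=int(len(tvals)),
        mean_count=mean_count,
        mean_density=mean_density,
        random_mean_count=rmc,
        random_mean_density=rmd,
        random_set_mean_counts=[float(x) for x in set_counts],
        fold_count=mean_count / rmc if rmc > 0 else np.nan,
        fold_density=mean_density / rmd if rmd > 0 else np.nan,
        p_count=p_count,
        p_density=p_density,
        k=k,
        flags=flags,
    )
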