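"""CG-context differentially methylated region (DMR) calling.

DMRs between two methylomes are called by threshold aggregation, not
hypothesis testing: CG dinucleotides covered in both samples whose
heterogeneity fractions differ by at least ``min_delta`` percentage points are
"differential", and a DMR is any maximal cluster in which some 200-bp window
contains at least ``min_sites`` differential sites of the same direction.

Window placement is exhaustive — every possible 200-bp window is considered,
which reduces to scanning runs of ``min_sites`` consecutive same-direction
sites with span < window. Merged clusters are trimmed to their outermost
member sites (window-edge spans would inflate downstream overlap statistics).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HYPER = "hyper"
HYPO = "hypo"

DMR_COLUMNS = ["chrom", "start", "end", "n_diff_sites", "mean_delta", "direction"]


def differential_sites(
    a_sites: pd.DataFrame,
    b_sites: pd.DataFrame,
    min_coverage: int = 5,
    min_delta: float = 20.0,
) -> pd.DataFrame:
    """CG dinucleotides whose methylation differs between methylomes a and b.

    ``delta`` is signed (b - a) in percentage points; only sites covered at
    least ``min_coverage`` in *both* samples are compared. Returns columns
    chrom, start (1-based dinucleotide position), delta, cov_a, cov_b.
    """
    merged = a_sites.merge(b_sites, on=["chrom", "start"], suffixes=("_a", "_b"))
    merged = merged[
        (merged["n_total_a"] >= min_coverage) & (merged["n_total_b"] >= min_coverage)
    ]
    if merged.empty:
        logger.warning("no shared covered CG sites between samples")
        return pd.DataFrame(columns=["chrom", "start", "delta", "cov_a", "cov_b"])
    delta = (merged["h_b"] - merged["h_a"]) * 100.0
    out = pd.DataFrame(
        {
            "chrom": merged["chrom"].to_numpy(),
            "start": merged["start"].to_numpy(),
            "delta": delta.to_numpy(),
            "cov_a": merged["n_total_a"].to_numpy(),
            "cov_b": merged["n_total_b"].to_numpy(),
        }
    )
    out = out[np.abs(out["delta"]) >= min_delta]
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def call_dmrs(
    sites: pd.DataFrame,
    window_bp: int = 200,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Aggregate differential CGs into DMRs.

    For each chromosome and direction independently, every run of
    ``min_sites`` consecutive differential sites spanning less than
    ``window_bp`` seeds a region trimmed to its member sites; overlapping or
    touching seeds merge. This is exactly equivalent to enumerating every
    possible ``window_bp`` window and keeping those with >= ``min_sites``
    same-direction sites. Output intervals are 0-based half-open covering both
    cytosines of the outermost member dinucleotides.
    """
    results = []
    if sites.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    for (chrom, direction), grp in sites.assign(
        direction=np.where(sites["delta"] > 0, HYPER, HYPO)
    ).groupby(["chrom", "direction"], sort=True):
        pos = np.sort(grp["start"].to_numpy())
        deltas = grp.sort_values("start")["delta"].to_numpy()
        n = len(pos)
        if n < min_sites:
            continue
        # seed run i..i+min_sites-1 if its span fits inside one window
        spans = pos[min_sites - 1 :] - pos[: n - min_sites + 1]
        seed_starts = np.flatnonzero(spans < window_bp)
        if seed_starts.size == 0:
            continue
        intervals = [[i, i + min_sites - 1] for i in seed_starts]
        merged = _merge_trimmed(intervals, pos)
        for lo, hi in merged:
            member = (pos >= pos[lo]) & (pos <= pos[hi])
            results.append(
                {
                    "chrom": chrom,
                    "start": int(pos[lo] - 1),  # 0-based, + strand C
                    "end": int(pos[hi] + 1),  # covers the - strand C
                    "n_diff_sites": int(member.sum()),
                    "mean_delta": float(deltas[member].mean()),
                    "direction": direction,
                }
            )
    if not results:
        return pd.DataFrame(columns=DMR_COLUMNS)
    return (
        pd.DataFrame(results)
        .sort_values(["chrom", "start", "direction"], kind="stable")
        .reset_index(drop=True)
    )


def _merge_trimmed(intervals: list[list[int]], pos: np.ndarray) -> list[tuple[int, int]]:
    """Merge seed site-index ranges whose genomic spans overlap or touch."""
    merged: list[list[int]] = []
    for i, j in intervals:
        if merged and pos[i] - 1 <= pos[merged[-1][1]] + 1:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [(i, j) for i, j in merged]


GENE_BODY = "gene_body"
FLANK_UP = "flank_2kb_upstream"
FLANK_DOWN = "flank_2kb_downstream"


def associate_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Associate DMRs with gene bodies or strand-aware 2-kb flanks.

    A DMR overlapping a gene body gives a ``gene_body`` association; otherwise
    overlap with the upstream/downstream flank (oriented by gene strand) gives
    a flank association. A DMR may associate with multiple genes. Columns:
    gene_id, relation, dmr_index (row index into ``dmrs``), direction.
    """
    rows = []
    for gene in genes.itertuples():
        if gene.strand == "-":
            up = (gene.end, gene.end + flank_bp)
            down = (max(0, gene.start - flank_bp), gene.start)
        else:
            up = (max(0, gene.start - flank_bp), gene.start)
            down = (gene.end, gene.end + flank_bp)
        cand = dmrs[dmrs["chrom"] == gene.chrom]
        for dmr in cand.itertuples():
            if dmr.start < gene.end and dmr.end > gene.start:
                relation = GENE_BODY
            elif dmr.start < up[1] and dmr.end > up[0]:
                relation = FLANK_UP
            elif dmr.start < down[1] and dmr.end > down[0]:
                relation = FLANK_DOWN
            else:
                continue
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "relation": relation,
                    "dmr_index": dmr.Index,
                    "direction": dmr.direction,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "relation", "dmr_index", "direction"])


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """BED6+ output: chrom, start, end, name, n_diff_sites, direction, mean_delta."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": [f"DMR_{i}" for i in range(len(dmrs))],
            "score": dmrs["n_diff_sites"],
            "strand": np.where(dmrs["direction"] == HYPER, "+", "-"),
            "direction": dmrs["direction"],
            "mean_delta": dmrs["mean_delta"].round(3),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
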