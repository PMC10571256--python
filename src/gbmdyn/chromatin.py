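"""ChIP-seq enrichment over genomic features and chromatin-state overlap.

Per-base coverage is normalized to log2 fold enrichment over the genomic
average; feature groups (e.g. exons of Dynamic vs Stable GbM genes) are then
compared by mean per-feature enrichment with Cohen's D as the effect size.
Chromatin states are taken as an input interval partition of the annotated
genome; overlap is plain interval intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class NormalizedTrack:
    """log2(depth / genome-wide mean depth) per base, one array per contig."""

    values: dict[str, np.ndarray]
    genomic_mean: float

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        return float(self.values[chrom][start:end].mean())


def read_bedgraph(path, contig_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a 4-column bedGraph into dense per-base depth arrays."""
    depth = {c: np.zeros(n, dtype=float) for c, n in contig_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples():
        if row.chrom in depth:
            depth[row.chrom][row.start : row.end] = row.value
    return depth


def normalize_track(depth: dict[str, np.ndarray], epsilon: float = 0.5) -> NormalizedTrack:
    """Normalize per-base depth to log2 fold enrichment over the genomic average.

    Zero-depth positions are floored at the pseudocount ``epsilon`` before the
    ratio so the log is defined; positive depths are used as-is, keeping exact
    identities (uniform track -> 0, a position at 4x the mean -> +2).
    """
    total = sum(float(a.sum()) for a in depth.values())
    nbases = sum(a.size for a in depth.values())
    if nbases == 0 or total == 0:
        raise ValueError("all-zero or empty coverage track cannot be normalized")
    mean = total / nbases
    values = {
        c: np.log2(np.maximum(a, epsilon) / mean).astype(float) for c, a in depth.items()
    }
    return NormalizedTrack(values=values, genomic_mean=mean)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """(mean_x - mean_y) / pooled standard deviation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    vx = x.var(ddof=1) if nx > 1 else 0.0
    vy = y.var(ddof=1) if ny > 1 else 0.0
    pooled = np.sqrt(((nx - 1) * vx + (ny - 1) * vy) / max(nx + ny - 2, 1))
    diff = x.mean() - y.mean()
    if pooled == 0 or not np.isfinite(pooled):
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def feature_enrichment(
    track: NormalizedTrack,
    groups: dict[str, pd.DataFrame],
) -> dict:
    """Mean normalized enrichment per feature, grouped, with pairwise Cohen's D.

    ``groups`` maps a group name to an interval frame (chrom, start, end).
    Returns per-group per-feature means, group summary means, and Cohen's D
    plus a two-tailed Welch t-test for every ordered group pair.
    """
    per_group: dict[str, np.ndarray] = {}
    for name, feats in groups.items():
        if feats.empty:
            raise ValueError(f"feature group {name!r} is empty")
        vals = [
            track.mean_over(f.chrom, int(f.start), int(f.end)) for f in feats.itertuples()
        ]
        per_group[name] = np.array(vals)
    names = list(per_group)
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            d = cohens_d(per_group[a], per_group[b])
            p = float(stats.ttest_ind(per_group[a], per_group[b], equal_var=False).pvalue)
            pairwise[(a, b)] = {"cohens_d": d, "p": p}
    return {
        "per_feature": per_group,
        "group_means": {k: float(v.mean()) for k, v in per_group.items()},
        "pairwise": pairwise,
    }


def length_binned_enrichment(
    track: NormalizedTrack,
    genes: pd.DataFrame,
    classes: dict[str, set[str]],
    bin_edges: list[float],
) -> pd.DataFrame:
    """Per-length-bin, per-class mean enrichment with a two-tailed t-test.

    Genes are grouped by body length into ``bin_edges`` bins; within each bin,
    each class's mean per-gene enrichment is reported, plus a Welch t-test
    between the first two classes. Empty (bin, class) combinations skip the
    bin with a warning.
    """
    genes = genes.copy()
    genes["length"] = genes["end"] - genes["start"]
    genes["bin"] = pd.cut(genes["length"], bins=bin_edges)
    class_names = list(classes)
    rows = []
    for bin_label, sub in genes.groupby("bin", observed=True):
        vals = {}
        for cname in class_names:
            members = sub[sub["gene_id"].isin(classes[cname])]
            if members.empty:
                vals = None
                break
            vals[cname] = np.array(
                [track.mean_over(g.chrom, int(g.start), int(g.end)) for g in members.itertuples()]
            )
        if vals is None:
            logger.warning("length bin %s skipped: empty class", bin_label)
            continue
        row = {"bin": str(bin_label)}
        for cname in class_names:
            row[f"mean_{cname}"] = float(vals[cname].mean())
            row[f"n_{cname}"] = len(vals[cname])
        if len(class_names) >= 2:
            a, b = class_names[0], class_names[1]
            if len(vals[a]) > 1 and len(vals[b]) > 1:
                row["p"] = float(stats.ttest_ind(vals[a], vals[b], equal_var=False).pvalue)
            else:
                row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _interval_overlap_bp(
    features: pd.DataFrame, states: pd.DataFrame, state_col: str = "state"
) -> pd.Series:
    """Total bp overlap between a feature set and each state's intervals."""
    totals: dict[str, int] = {}
    for chrom, fsub in features.groupby("chrom", sort=False):
        ssub = states[states["chrom"] == chrom]
        fs = fsub["start"].to_numpy()
        fe = fsub["end"].to_numpy()
        for srow in ssub.itertuples():
            ov = np.clip(np.minimum(fe, srow.end) - np.maximum(fs, srow.start), 0, None)
            key = getattr(srow, state_col)
            totals[key] = totals.get(key, 0) + int(ov.sum())
    return pd.Series(totals, dtype=np.int64)


def validate_state_partition(states: pd.DataFrame) -> None:
    """States must not overlap each other within a chromosome."""
    for chrom, sub in states.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping state intervals on {chrom}")


def state_overlap(
    gene_sets: dict[str, pd.DataFrame],
    states: pd.DataFrame,
) -> pd.DataFrame:
    """Percent and bp overlap of each gene set with each chromatin state.

    Percentages are of the gene set's base pairs that fall inside the state
    annotation, so they sum to 100 per gene set when states partition the
    annotated genome. Returns a long frame (gene_set, state, bp, percent).
    """
    validate_state_partition(states)
    all_states = sorted(states["state"].unique())
    rows = []
    for set_name, feats in gene_sets.items():
        bp = _interval_overlap_bp(feats, states)
        total = bp.sum()
        for state in all_states:
            v = int(bp.get(state, 0))
            rows.append(
                {
                    "gene_set": set_name,
                    "state": state,
                    "bp": v,
                    "percent": 100.0 * v / total if total > 0 else 0.0,
                }
            )
    return pd.DataFrame(rows)


# chromatin-state grouping used for reporting (state ids from the reference
# nine-state segmentation): gene body = 3+7, TSS promoter = 1,
# distal promoter = 2, other intergenic = 4+5+8+9.
STATE_GROUPS = {
    "gene_body": {"3", "7"},
    "promoter_tss": {"1"},
    "promoter_distal": {"2"},
    "other_intergenic": {"4", "5", "8", "9"},
}


def group_state_overlap(report: pd.DataFrame, groups: dict[str, set[str]] = STATE_GROUPS) -> pd.DataFrame:
    """Collapse a state_overlap report onto named state groups."""
    rows = []
    for set_name, sub in report.groupby("gene_set", sort=False):
        for gname, members in groups.items():
            m = sub[sub["state"].astype(str).isin(members)]
            rows.append(
                {
                    "gene_set": set_name,
                    "state_group": gname,
                    "bp": int(m["bp"].sum()),
                    "percent": float(m["percent"].sum()),
                }
            )
    return pd.DataFrame(rows)


def set_intersection_report(gene_set: set[str], enriched_genes: set[str]) -> dict:
    """Overlap between a gene list and an enriched-gene list (e.g. H2A.Z)."""
    inter = gene_set & enriched_genes
    return {
        "n_set": len(gene_set),
        "n_enriched": len(enriched_genes),
        "n_overlap": len(inter),
        "fraction_of_set": len(inter) / len(gene_set) if gene_set else 0.0,
    }
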