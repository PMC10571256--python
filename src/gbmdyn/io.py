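"""Reading and validation of per-cytosine methylation reports and gene models.

The central input is the tab-delimited per-cytosine report emitted by standard
bisulfite/EM-seq mappers (one row per covered cytosine)::

    chrom  pos  strand  count_methylated  count_unmethylated  context  trinucleotide

``pos`` is 1-based, ``context`` is one of the three plant contexts (CG, CHG, CHH).
Counts are deduplicated read counts; each deduplicated read is treated as an
independent cell of the source tissue, which is what makes the per-site
methylated-read fraction a cell-population heterogeneity measure.

Internally all genomic intervals are 0-based half-open; conversion from the
1-based report/GFF3 dialects happens only at the I/O boundary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")


class FormatError(ValueError):
    """The file does not parse as the expected dialect."""


class ValidationError(ValueError):
    """The file parses but violates a record invariant."""


@dataclass
class MethylomeTable:
    """A sample's per-cytosine methylation calls.

    ``records`` columns: chrom, pos (1-based), strand, n_meth, n_unmeth,
    context, trinucleotide. No duplicate (chrom, pos, strand) keys.
    """

    records: pd.DataFrame
    sample_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        if self.records.duplicated(["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) records")

    @property
    def contigs(self) -> list[str]:
        return sorted(self.records["chrom"].unique())

    def subset(self, contig: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == contig]


@dataclass
class ConversionQC:
    """Apparent methylation on an unmethylated control contig.

    conversion_rate = 1 - apparent_methylation; with EM-seq chemistry the
    expectation for a clean library is > 99.7 % conversion.
    """

    control_contig: str
    apparent_methylation: float
    conversion_rate: float
    n_calls: int
    threshold: float
    passed: bool
    warnings: list[str] = field(default_factory=list)


def read_cytosine_report(
    path: str | Path, sample_id: str = "", genotype: str = ""
) -> MethylomeTable:
    """Load a per-cytosine report (Bismark cytosine/CX dialect; gzip accepted).

    Malformed lines are reported with their 1-based line numbers. Negative
    counts or unknown strand/context values raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str, compression="infer"
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty cytosine report: %s", path)
        df = pd.DataFrame(columns=CX_COLUMNS)
        return MethylomeTable(_finalize_records(df), sample_id=sample_id, genotype=genotype)

    if df.shape[1] < len(CX_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(CX_COLUMNS)} tab-separated columns "
            f"(chrom, pos, strand, n_meth, n_unmeth, context, trinucleotide), "
            f"found {df.shape[1]}"
        )
    df = df.iloc[:, : len(CX_COLUMNS)].copy()
    df.columns = CX_COLUMNS

    numeric = {}
    bad_lines: set[int] = set()
    for col in ("pos", "n_meth", "n_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_lines.update((np.flatnonzero(vals.isna()) + 1).tolist())
        numeric[col] = vals
    if bad_lines:
        shown = sorted(bad_lines)[:10]
        raise FormatError(f"{path}: malformed lines (non-numeric fields) at {shown}")
    for col, vals in numeric.items():
        df[col] = vals.astype(np.int64)

    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
        lines = np.flatnonzero((df["n_meth"] < 0) | (df["n_unmeth"] < 0)) + 1
        raise ValidationError(f"{path}: negative counts at lines {lines[:10].tolist()}")
    if (df["pos"] < 1).any():
        lines = np.flatnonzero(df["pos"] < 1) + 1
        raise ValidationError(f"{path}: positions < 1 at lines {lines[:10].tolist()}")
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        lines = np.flatnonzero(bad_ctx) + 1
        raise ValidationError(f"{path}: unknown context at lines {lines[:10].tolist()}")
    bad_strand = ~df["strand"].isin(STRANDS)
    if bad_strand.any():
        lines = np.flatnonzero(bad_strand) + 1
        raise ValidationError(f"{path}: unknown strand at lines {lines[:10].tolist()}")

    return MethylomeTable(_finalize_records(df), sample_id=sample_id, genotype=genotype)


def _finalize_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.astype(
        {
            "chrom": str,
            "pos": np.int64,
            "strand": str,
            "n_meth": np.int64,
            "n_unmeth": np.int64,
            "context": str,
            "trinucleotide": str,
        }
    )
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def write_cytosine_report(methylome: MethylomeTable, path: str | Path) -> None:
    """Write records back in the report dialect (gzip if path ends with .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        methylome.records.to_csv(fh, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def pool_cg_dinucleotides(methylome: MethylomeTable) -> pd.DataFrame:
    """Pool symmetric CG cytosines into dinucleotide sites.

    The + strand C at 1-based position p pairs with the - strand C at p+1;
    counts are summed over both strands. A cytosine whose partner strand is
    uncovered still forms a (single-strand) site — dropping it would bias the
    heterogeneity fraction at low depth.

    Returns a frame with columns chrom, start (1-based + strand C position),
    n_meth, n_total and the heterogeneity fraction h = n_meth / n_total
    (NaN when n_total == 0).
    """
    cg = methylome.records[methylome.records["context"] == "CG"]
    if cg.empty:
        return pd.DataFrame(columns=["chrom", "start", "n_meth", "n_total", "h"])
    start = np.where(cg["strand"].to_numpy() == "+", cg["pos"].to_numpy(), cg["pos"].to_numpy() - 1)
    pooled = (
        pd.DataFrame(
            {
                "chrom": cg["chrom"].to_numpy(),
                "start": start,
                "n_meth": cg["n_meth"].to_numpy(),
                "n_total": cg["n_meth"].to_numpy() + cg["n_unmeth"].to_numpy(),
            }
        )
        .groupby(["chrom", "start"], as_index=False, sort=True)
        .sum()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled["h"] = np.where(
            pooled["n_total"] > 0, pooled["n_meth"] / pooled["n_total"], np.nan
        )
    return pooled


def conversion_qc(
    methylome: MethylomeTable, control_contig: str, threshold: float = 0.997
) -> ConversionQC:
    """Quantify apparent methylation on an unmethylated control contig.

    All contexts on the control contig (chloroplast for plant libraries) are
    pooled; the conversion rate is 1 minus the apparent methylation fraction.
    A warning is attached (and logged) if conversion falls below ``threshold``.
    """
    ctl = methylome.subset(control_contig)
    if ctl.empty:
        raise ValidationError(
            f"control contig {control_contig!r} absent; available: {methylome.contigs}"
        )
    n_meth = int(ctl["n_meth"].sum())
    n_total = int(ctl["n_meth"].sum() + ctl["n_unmeth"].sum())
    apparent = n_meth / n_total if n_total else 0.0
    conversion = 1.0 - apparent
    warnings = []
    if conversion < threshold:
        msg = (
            f"conversion rate {conversion:.4f} on {control_contig} below "
            f"threshold {threshold:.4f}"
        )
        warnings.append(msg)
        logger.warning(msg)
    return ConversionQC(
        control_contig=control_contig,
        apparent_methylation=apparent,
        conversion_rate=conversion,
        n_calls=n_total,
        threshold=threshold,
        passed=conversion >= threshold,
        warnings=warnings,
    )


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_models(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read gene models from BED6 (0-based half-open) or GFF3 (1-based inclusive).

    ``dialect`` is "bed" or "gff3"; by default it is inferred from the file
    extension and an error is raised when that is ambiguous. Output coordinates
    are uniformly 0-based half-open.
    """
    path = Path(path)
    if dialect is None:
        suffixes = {s.lower() for s in path.suffixes}
        if {".bed"} & suffixes:
            dialect = "bed"
        elif {".gff", ".gff3"} & suffixes:
            dialect = "gff3"
        else:
            raise FormatError(f"{path}: cannot infer dialect; pass dialect='bed' or 'gff3'")
    dialect = dialect.lower()
    if dialect == "bed":
        genes = _read_bed_genes(path)
    elif dialect == "gff3":
        genes = _read_gff3_genes(path)
    else:
        raise FormatError(f"unknown gene-model dialect {dialect!r}")
    if (genes["start"] >= genes["end"]).any():
        raise ValidationError(f"{path}: gene intervals with start >= end")
    if genes["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _read_bed_genes(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=GENE_COLUMNS)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: BED gene models need >= 4 columns (BED6 recommended)")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3],
            "chrom": df.iloc[:, 0],
            "start": pd.to_numeric(df.iloc[:, 1]).astype(np.int64),
            "end": pd.to_numeric(df.iloc[:, 2]).astype(np.int64),
            "strand": df.iloc[:, 5] if df.shape[1] >= 6 else "+",
        }
    )
    return out


def _read_gff3_genes(path: Path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # GFF3 is 1-based inclusive
                "end": feat.end,
                "strand": feat.strand if feat.strand in STRANDS else "+",
            }
        )
    if not rows:
        return pd.DataFrame(columns=GENE_COLUMNS)
    return pd.DataFrame(rows)


def write_gene_models_bed(genes: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"],
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": ".",
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)
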