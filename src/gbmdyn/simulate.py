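"""Synthetic genome / methylome / expression generator with known ground truth.

The generator emulates the data structure behind a read-level methylation
heterogeneity study: a small multi-gene genome with three gene epigenotypes
(Stable GbM: per-cell CG methylation probability ~0.95 in every genotype;
Dynamic GbM: ~0.50 in wild type rising to ~0.95 in the demethylase "eraser"
mutant; unmethylated: ~0.01), per-read binomial sampling where each
deduplicated read is an independent cell, a non-conversion error rate that
flips unmethylated cells to apparently methylated, a fully unmethylated
control contig for conversion QC, ChIP coverage tracks and a chromatin-state
partition, a second-species methylome with a homolog table for the
conservation analysis, and expression matrices in which Dynamic-class genes
explore a wider range of condition states and the mutant's range is shrunk by
a canalization factor.

All randomness flows from a single seed through spawned child generators, so
every artifact is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CX_COLUMNS, MethylomeTable, _finalize_records

STABLE = "stable"
DYNAMIC = "dynamic"
UNMETHYLATED = "unmethylated"
EPIGENOTYPES = (STABLE, DYNAMIC, UNMETHYLATED)


@dataclass
class SimulationConfig:
    seed: int = 17

    # genome / methylome
    n_genes: dict = field(
        default_factory=lambda: {STABLE: 100, DYNAMIC: 100, UNMETHYLATED: 100}
    )
    cgs_per_gene: tuple = (10, 30)
    cg_spacing_bp: int = 30
    gene_gap_bp: int = 500
    contig_names: tuple = ("Chr1", "Chr2")
    control_contig: str = "ChrC"
    control_contig_length: int = 10_000
    n_control_cytosines: int = 3000
    # per-cell methylation probability per epigenotype, (wild type, mutant)
    p_cell: dict = field(
        default_factory=lambda: {
            STABLE: (0.95, 0.95),
            DYNAMIC: (0.50, 0.95),
            UNMETHYLATED: (0.01, 0.01),
        }
    )
    coverage_mean: float = 30.0  # pooled reads per CG dinucleotide (Poisson)
    non_conversion_rate: float = 0.003
    # non-CG cytosines outnumber CGs several-fold in real gene bodies; a dense
    # complement keeps the per-gene non-CG fraction estimate well inside the
    # 1 % ceiling for genes that are genuinely unmethylated in CHG/CHH
    n_noncg_per_gene: int = 240
    p_noncg: float = 0.002
    # intergenic demethylase targets: unmethylated genes given an upstream
    # CG cluster that hypermethylates in the mutant (exercises flank DMRs)
    n_flank_dmr_genes: int = 20
    flank_dmr_offset_bp: int = 300
    flank_dmr_n_cgs: int = 8
    flank_dmr_p: tuple = (0.05, 0.95)

    # expression (paper-scale set sizes; BACKGROUND plays the "total genes" role)
    n_expression_genes: dict = field(
        default_factory=lambda: {DYNAMIC: 581, STABLE: 600, "background": 1000}
    )
    n_conditions: int = 20
    expression_base_mean: float = 500.0
    expression_gene_mean_sd: float = 10.0
    condition_sd: dict = field(
        default_factory=lambda: {DYNAMIC: 100.0, STABLE: 20.0, "background": 50.0}
    )
    expression_noise_sd: float = 5.0
    canalization_factor: float = 0.7

    # conservation
    conservation_species: str = "synthspecies"
    frac_non_one_to_one: float = 0.1
    frac_high_noncg: float = 0.1
    high_noncg_p: float = 0.05

    # ChIP / chromatin states
    chip_background_depth: float = 20.0
    chip_enrichment_multiplier: float = 4.0
    chip_tile_bp: int = 20

    def __post_init__(self) -> None:
        for cls, (p_wt, p_mut) in self.p_cell.items():
            if not (0.0 <= p_wt <= 1.0 and 0.0 <= p_mut <= 1.0):
                raise ValueError(f"per-cell probabilities for {cls} outside [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not (0.0 <= self.non_conversion_rate <= 1.0):
            raise ValueError("non_conversion_rate outside [0, 1]")
        if self.n_conditions < 2:
            raise ValueError("n_conditions must be >= 2")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    wt: MethylomeTable
    mut: MethylomeTable
    genes: pd.DataFrame
    ground_truth: pd.DataFrame
    contig_lengths: dict
    target: MethylomeTable
    target_genes: pd.DataFrame
    homologs: pd.DataFrame
    expr_wt: pd.DataFrame
    expr_mut: pd.DataFrame
    expr_truth: pd.DataFrame
    sample_metadata: pd.DataFrame
    chip_tracks: dict
    states: pd.DataFrame


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _apparent_p(p: float, non_conversion: float) -> float:
    # an unmethylated cell reads as methylated with the non-conversion rate
    return p + (1.0 - p) * non_conversion


def _emit_cg_dinucleotide(rows: list, chrom: str, plus_pos: int, p_app: float,
                          cov_mean: float, rng: np.random.Generator) -> None:
    for strand, pos, tri in (("+", plus_pos, "CGA"), ("-", plus_pos + 1, "CGT")):
        cov = int(rng.poisson(cov_mean / 2.0))
        meth = int(rng.binomial(cov, p_app)) if cov else 0
        rows.append((chrom, pos, strand, meth, cov - meth, "CG", tri))


def _emit_noncg(rows: list, chrom: str, start0: int, n_cgs: int, n_noncg: int,
                p_app: float, cfg: SimulationConfig, rng: np.random.Generator) -> None:
    """Interleave CHG/CHH cytosines between the CG dinucleotides.

    Slot j goes to offset 3 + (j // n_cgs) inside spacing block j % n_cgs,
    which never collides with the CG positions (offsets 0 and 1 of each block).
    """
    max_slots = n_cgs * (cfg.cg_spacing_bp - 5)
    n = min(n_noncg, max_slots)
    block = np.arange(n) % n_cgs
    slot = np.arange(n) // n_cgs
    pos = start0 + 1 + block * cfg.cg_spacing_bp + 3 + slot
    cov = rng.poisson(cfg.coverage_mean / 2.0, size=n)
    meth = rng.binomial(cov, p_app)
    for j in range(n):
        ctx = "CHG" if j % 2 == 0 else "CHH"
        rows.append(
            (chrom, int(pos[j]), "+", int(meth[j]), int(cov[j] - meth[j]), ctx, ctx[:2] + "A")
        )


def _layout_genes(cfg: SimulationConfig, rng: np.random.Generator):
    """Assign each gene a contig, interval and CG dinucleotide positions."""
    gene_ids, classes = [], []
    for cls in EPIGENOTYPES:
        for i in range(cfg.n_genes[cls]):
            gene_ids.append(f"G_{cls[:3].upper()}_{i:04d}")
            classes.append(cls)
    order = rng.permutation(len(gene_ids))
    genes = []
    cursor = {c: 1000 for c in cfg.contig_names}
    for idx, k in enumerate(order):
        contig = cfg.contig_names[idx % len(cfg.contig_names)]
        n_cgs = int(rng.integers(cfg.cgs_per_gene[0], cfg.cgs_per_gene[1] + 1))
        start0 = cursor[contig]
        end0 = start0 + n_cgs * cfg.cg_spacing_bp + 10
        cursor[contig] = end0 + cfg.gene_gap_bp
        genes.append(
            {
                "gene_id": gene_ids[k],
                "epigenotype": classes[k],
                "chrom": contig,
                "start": start0,
                "end": end0,
                "strand": "+" if idx % 2 == 0 else "-",
                "n_cgs": n_cgs,
            }
        )
    lengths = {c: cursor[c] + 1000 for c in cfg.contig_names}
    return pd.DataFrame(genes), lengths


def simulate_methylomes(cfg: SimulationConfig):
    """Generate wild-type and eraser-mutant cytosine reports plus gene models.

    Returns (wt, mut, genes, ground_truth, contig_lengths). Every CG
    dinucleotide emits both strand cytosines; each read is an independent
    cell, methylated with the epigenotype's per-cell probability and flipped
    to apparent-methylated with the non-conversion rate when unmethylated.
    """
    rng_layout, rng_wt, rng_mut = _rngs(cfg.seed, 3)
    genes, lengths = _layout_genes(cfg, rng_layout)

    flank_ids = (
        genes.loc[genes["epigenotype"] == UNMETHYLATED, "gene_id"]
        .head(cfg.n_flank_dmr_genes)
        .tolist()
    )

    tables = {}
    for name, rng, col in (("wt", rng_wt, 0), ("mut", rng_mut, 1)):
        rows: list = []
        for gene in genes.itertuples():
            p = cfg.p_cell[gene.epigenotype][col]
            p_app = _apparent_p(p, cfg.non_conversion_rate)
            for i in range(gene.n_cgs):
                plus_pos = gene.start + 1 + i * cfg.cg_spacing_bp  # 1-based
                _emit_cg_dinucleotide(rows, gene.chrom, plus_pos, p_app,
                                      cfg.coverage_mean, rng)
            # intra-genic non-CG cytosines (CHG/CHH), near-zero methylation
            p_nc = _apparent_p(cfg.p_noncg, cfg.non_conversion_rate)
            _emit_noncg(rows, gene.chrom, gene.start, gene.n_cgs,
                        cfg.n_noncg_per_gene, p_nc, cfg, rng)
            if gene.gene_id in flank_ids:
                p_flank = _apparent_p(cfg.flank_dmr_p[col], cfg.non_conversion_rate)
                for j in range(cfg.flank_dmr_n_cgs):
                    plus_pos = gene.start - cfg.flank_dmr_offset_bp + 1 + j * 20
                    _emit_cg_dinucleotide(rows, gene.chrom, plus_pos, p_flank,
                                          cfg.coverage_mean, rng)
        # fully unmethylated control contig across all contexts
        p_ctl = cfg.non_conversion_rate
        step = max(1, cfg.control_contig_length // cfg.n_control_cytosines)
        ctl_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 97, col]).generate_state(1)[0]
        )
        for i in range(cfg.n_control_cytosines):
            pos = 1 + i * step
            ctx = ("CG", "CHG", "CHH")[i % 3]
            cov = int(ctl_rng.poisson(cfg.coverage_mean / 2.0))
            meth = int(ctl_rng.binomial(cov, p_ctl)) if cov else 0
            rows.append((cfg.control_contig, pos, "+", meth, cov - meth, ctx, ctx[:2] + "A"))
        df = pd.DataFrame(rows, columns=CX_COLUMNS)
        tables[name] = MethylomeTable(
            _finalize_records(df), sample_id=f"sim_{name}", genotype=name
        )

    truth = genes[["gene_id", "epigenotype", "chrom", "start", "end"]].copy()
    truth["p_wt"] = [cfg.p_cell[c][0] for c in genes["epigenotype"]]
    truth["p_mut"] = [cfg.p_cell[c][1] for c in genes["epigenotype"]]
    truth["flank_dmr"] = truth["gene_id"].isin(flank_ids)
    lengths = dict(lengths)
    lengths[cfg.control_contig] = cfg.control_contig_length
    gene_models = genes[["gene_id", "chrom", "start", "end", "strand"]].copy()
    return tables["wt"], tables["mut"], gene_models, truth, lengths


def simulate_expression(cfg: SimulationConfig, ground_truth: pd.DataFrame):
    """Expression matrices (genes x conditions) for wild type and mutant.

    The gene universe is the methylome genes plus extra genes per class up to
    the configured set sizes (the plasticity analyses of the source study run
    on ~581 Dynamic and ~600 Stable genes). Each gene has a latent mean and
    per-condition effects with class-dependent spread (dynamic > background >
    stable); the mutant redraws condition effects with the dynamic-class
    spread multiplied by the canalization factor, i.e. it explores a
    proportionally narrower range around the same mean. Condition 0 is the
    focal ("leaf") tissue used by the decile and regression analyses.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]).generate_state(1)[0])
    class_of: dict[str, str] = {}
    for row in ground_truth.itertuples():
        cls = row.epigenotype if row.epigenotype in (DYNAMIC, STABLE) else "background"
        class_of[row.gene_id] = cls
    counts = {DYNAMIC: 0, STABLE: 0, "background": 0}
    for cls in class_of.values():
        counts[cls] += 1
    for cls, total in cfg.n_expression_genes.items():
        for i in range(max(0, total - counts[cls])):
            class_of[f"X_{cls[:3].upper()}_{i:04d}"] = cls

    gene_ids = list(class_of)
    classes = np.array([class_of[g] for g in gene_ids])
    n_genes, n_cond = len(gene_ids), cfg.n_conditions

    m = rng.normal(cfg.expression_base_mean, cfg.expression_gene_mean_sd, size=n_genes)
    sd = np.array([cfg.condition_sd[c] for c in classes])
    effects_wt = rng.normal(0.0, 1.0, size=(n_genes, n_cond)) * sd[:, None]
    wt = m[:, None] + effects_wt + rng.normal(0.0, cfg.expression_noise_sd, size=(n_genes, n_cond))
    # methylation turnover decouples the dynamic-class condition response: the
    # mutant's condition effects are redrawn with the spread scaled by the
    # canalization factor; other classes keep the wild-type response and
    # differ only by measurement noise
    effects_mut_dyn = (
        rng.normal(0.0, 1.0, size=(n_genes, n_cond)) * sd[:, None] * cfg.canalization_factor
    )
    effects_mut = np.where((classes == DYNAMIC)[:, None], effects_mut_dyn, effects_wt)
    mut = m[:, None] + effects_mut + rng.normal(0.0, cfg.expression_noise_sd, size=(n_genes, n_cond))
    wt = np.clip(wt, 0.0, None)
    mut = np.clip(mut, 0.0, None)

    conditions = [f"cond{i:02d}" for i in range(n_cond)]
    expr_wt = pd.DataFrame(wt, index=pd.Index(gene_ids, name="gene_id"), columns=conditions)
    expr_mut = pd.DataFrame(mut, index=pd.Index(gene_ids, name="gene_id"), columns=conditions)
    metadata = pd.DataFrame(
        {
            "sample": conditions * 2,
            "condition": conditions * 2,
            "genotype": ["wt"] * n_cond + ["mut"] * n_cond,
            "replicate": 1,
        }
    )
    expr_truth = pd.DataFrame({"gene_id": gene_ids, "expression_class": classes})
    return expr_wt, expr_mut, metadata, expr_truth


def simulate_conservation(cfg: SimulationConfig, ground_truth: pd.DataFrame):
    """Second-species methylome, gene models and homolog table.

    Homologs of dynamic-class genes carry heterogeneous per-cell methylation
    (p = 0.5); homologs of stable / unmethylated genes sit near 1 / 0.
    Configured fractions of pairs are flagged non-one-to-one or given > 1 %
    non-CG methylation to exercise the homolog filters.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]).generate_state(1)[0])
    contig = "ChrT1"
    rows: list = []
    genes, pairs = [], []
    cursor = 1000
    n = len(ground_truth)
    non_oto = rng.random(n) < cfg.frac_non_one_to_one
    high_nc = rng.random(n) < cfg.frac_high_noncg
    for i, src in enumerate(ground_truth.itertuples()):
        tgt_id = f"T_{src.gene_id}"
        n_cgs = int(rng.integers(cfg.cgs_per_gene[0], cfg.cgs_per_gene[1] + 1))
        start0 = cursor
        end0 = start0 + n_cgs * cfg.cg_spacing_bp + 10
        cursor = end0 + cfg.gene_gap_bp
        p = cfg.p_cell[src.epigenotype][0]
        p_app = _apparent_p(p, cfg.non_conversion_rate)
        for j in range(n_cgs):
            _emit_cg_dinucleotide(rows, contig, start0 + 1 + j * cfg.cg_spacing_bp,
                                  p_app, cfg.coverage_mean, rng)
        p_nc = cfg.high_noncg_p if high_nc[i] else cfg.p_noncg
        p_nc = _apparent_p(p_nc, cfg.non_conversion_rate)
        _emit_noncg(rows, contig, start0, n_cgs, cfg.n_noncg_per_gene, p_nc, cfg, rng)
        genes.append(
            {"gene_id": tgt_id, "chrom": contig, "start": start0, "end": end0, "strand": "+"}
        )
        pairs.append(
            {
                "source_gene": src.gene_id,
                "target_gene": tgt_id,
                "one_to_one": not non_oto[i],
                "species": cfg.conservation_species,
                "high_non_cg": bool(high_nc[i]),
            }
        )
    target = MethylomeTable(
        _finalize_records(pd.DataFrame(rows, columns=CX_COLUMNS)),
        sample_id="sim_target",
        genotype="wt",
    )
    return target, pd.DataFrame(genes), pd.DataFrame(pairs)


def simulate_chip(cfg: SimulationConfig, genes: pd.DataFrame, ground_truth: pd.DataFrame,
                  contig_lengths: dict):
    """ChIP coverage tracks and a chromatin-state partition.

    The "regulatory" track paints the enrichment multiplier over dynamic gene
    bodies (promoter-like marks inside the gene body); the "genebody" track
    paints it over stable gene bodies. Depth is Poisson per tile. States:
    "1" = 200-bp promoters, "2" = dynamic gene bodies (distal-promoter-like),
    "3" = stable / unmethylated gene bodies, "4" = the rest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]).generate_state(1)[0])
    cls = ground_truth.set_index("gene_id")["epigenotype"]
    main = {c: int(length) for c, length in contig_lengths.items() if c != cfg.control_contig}

    def _paint(target_class: str) -> dict[str, np.ndarray]:
        track = {}
        for chrom, length in main.items():
            ntiles = length // cfg.chip_tile_bp + 1
            mult = np.ones(ntiles)
            sub = genes[genes["chrom"] == chrom]
            for g in sub.itertuples():
                if cls[g.gene_id] == target_class:
                    mult[g.start // cfg.chip_tile_bp : g.end // cfg.chip_tile_bp] = (
                        cfg.chip_enrichment_multiplier
                    )
            tiles = rng.poisson(cfg.chip_background_depth * mult).astype(float)
            track[chrom] = np.repeat(tiles, cfg.chip_tile_bp)[:length]
        return track

    tracks = {"regulatory": _paint(DYNAMIC), "genebody": _paint(STABLE)}

    state_rows = []
    for chrom, length in main.items():
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        cursor = 0
        for g in sub.itertuples():
            promoter_start = max(cursor, g.start - 200)
            if promoter_start > cursor:
                state_rows.append((chrom, cursor, promoter_start, "4"))
            state_rows.append((chrom, promoter_start, g.start, "1"))
            body_state = "2" if cls[g.gene_id] == DYNAMIC else "3"
            state_rows.append((chrom, g.start, g.end, body_state))
            cursor = g.end
        if cursor < length:
            state_rows.append((chrom, cursor, length, "4"))
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])
    return tracks, states


def simulate_all(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    cfg = cfg or SimulationConfig()
    wt, mut, genes, truth, lengths = simulate_methylomes(cfg)
    expr_wt, expr_mut, metadata, expr_truth = simulate_expression(cfg, truth)
    target, target_genes, homologs = simulate_conservation(cfg, truth)
    tracks, states = simulate_chip(cfg, genes, truth, lengths)
    return SyntheticDataset(
        config=cfg,
        wt=wt,
        mut=mut,
        genes=genes,
        ground_truth=truth,
        contig_lengths=lengths,
        target=target,
        target_genes=target_genes,
        homologs=homologs,
        expr_wt=expr_wt,
        expr_mut=expr_mut,
        expr_truth=expr_truth,
        sample_metadata=metadata,
        chip_tracks=tracks,
        states=states,
    )


def write_bedgraph(depth: dict[str, np.ndarray], path) -> None:
    """Run-length-encode per-base depth arrays into a 4-column bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(depth):
            a = depth[chrom]
            if a.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(a)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [a.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{a[s]:g}\n")


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write every artifact in the dialects the analysis modules consume."""
    from .io import write_cytosine_report, write_gene_models_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wt": outdir / "wt.cx.tsv",
        "mut": outdir / "mut.cx.tsv",
        "genes": outdir / "genes.bed",
        "target": outdir / "target.cx.tsv",
        "target_genes": outdir / "target_genes.bed",
        "homologs": outdir / "homologs.tsv",
        "expr_wt": outdir / "expr_wt.tsv",
        "expr_mut": outdir / "expr_mut.tsv",
        "samples": outdir / "samples.tsv",
        "states": outdir / "states.bed",
        "ground_truth": outdir / "ground_truth.tsv",
        "expr_truth": outdir / "expression_truth.tsv",
        "config": outdir / "config.yaml",
    }
    write_cytosine_report(ds.wt, paths["wt"])
    write_cytosine_report(ds.mut, paths["mut"])
    write_gene_models_bed(ds.genes, paths["genes"])
    write_cytosine_report(ds.target, paths["target"])
    write_gene_models_bed(ds.target_genes, paths["target_genes"])
    ds.homologs.to_csv(paths["homologs"], sep="\t", index=False)
    ds.expr_wt.to_csv(paths["expr_wt"], sep="\t")
    ds.expr_mut.to_csv(paths["expr_mut"], sep="\t")
    ds.sample_metadata.to_csv(paths["samples"], sep="\t", index=False)
    ds.states.to_csv(paths["states"], sep="\t", header=False, index=False)
    ds.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    ds.expr_truth.to_csv(paths["expr_truth"], sep="\t", index=False)
    for name, track in ds.chip_tracks.items():
        p = outdir / f"chip_{name}.bedgraph"
        paths[f"chip_{name}"] = p
        write_bedgraph(track, p)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(_plain(asdict(ds.config)), fh, sort_keys=True)
    return paths


def _plain(obj):
    """Recursively convert tuples to lists so YAML's safe dumper accepts them."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
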