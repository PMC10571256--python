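"""End-to-end orchestration: io -> heterogeneity -> DMRs -> classification ->
{conservation, chromatin, plasticity}, with a machine-readable results bundle.

Every threshold actually applied is echoed into ``run_meta.json`` together
with a hash of the configuration and input checksums; deterministic stages
regenerate bit-identical outputs from the same config and inputs, and an
up-to-date bundle (matching hash, all outputs present) is not recomputed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromatin as chrom_mod
from . import classify as classify_mod
from . import conservation as cons_mod
from . import dmr as dmr_mod
from . import plasticity as plast_mod
from .heterogeneity import HeterogeneityCutoffs, gene_profiles
from .io import (
    conversion_qc,
    pool_cg_dinucleotides,
    read_cytosine_report,
    read_gene_models,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters; defaults encode the analysis constants
    (10 % / 85 % heterogeneity cutoffs, 200-bp windows, >= 5 gaining
    dinucleotides, 20-pp gain, 2-kb flanks, 10 random conservation sets)."""

    # inputs (absent optional paths skip the corresponding stage)
    wt_methylome: str = ""
    mut_methylome: str = ""
    genes: str = ""
    control_contig: str | None = None
    stable_list: str | None = None
    target_methylome: str | None = None
    target_genes: str | None = None
    homologs: str | None = None
    expr_wt: str | None = None
    expr_mut: str | None = None
    dynamic_set: str | None = None  # optional supplementary gene-set lists
    stable_set: str | None = None
    chip_tracks: dict = field(default_factory=dict)  # name -> bedGraph path
    states: str | None = None

    # parameters
    min_coverage: int = 5
    low: float = 0.10
    high: float = 0.85
    window_bp: int = 200
    min_dmr_sites: int = 5
    min_delta_pp: float = 20.0
    min_gain: float = 0.20
    min_gaining: int = 5
    flank_bp: int = 2000
    conversion_threshold: float = 0.997
    k_random_sets: int = 10
    seed: int = 17
    focal_condition: str | None = None  # default: first column of the matrix


_PATH_FIELDS = {
    "wt_methylome", "mut_methylome", "genes", "stable_list", "target_methylome",
    "target_genes", "homologs", "expr_wt", "expr_mut", "dynamic_set", "stable_set",
    "states", "chip_tracks",
}


def config_hash(cfg: PipelineConfig) -> str:
    """Hash of all parameters plus the *contents* of every input file.

    Paths themselves are excluded so relocating a run does not change the
    hash; any parameter or input edit does.
    """
    params = {k: v for k, v in asdict(cfg).items() if k not in _PATH_FIELDS}
    h = hashlib.sha256(yaml.safe_dump(params, sort_keys=True).encode())
    for p in _input_paths(cfg):
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _input_paths(cfg: PipelineConfig) -> list[str]:
    paths = [
        cfg.wt_methylome,
        cfg.mut_methylome,
        cfg.genes,
        cfg.stable_list,
        cfg.target_methylome,
        cfg.target_genes,
        cfg.homologs,
        cfg.expr_wt,
        cfg.expr_mut,
        cfg.dynamic_set,
        cfg.stable_set,
        cfg.states,
        *cfg.chip_tracks.values(),
    ]
    return [p for p in paths if p]


def _read_gene_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


BUNDLE_FILES = ("classification.tsv", "dmrs.bed", "run_meta.json")


def run_pipeline(cfg: PipelineConfig, outdir: str | Path, force: bool = False) -> dict:
    """Run all configured stages; returns the results bundle as a dict.

    Stage failures raise with the stage name; a rerun with an unchanged
    config and inputs returns the existing bundle without recomputation.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    meta_path = outdir / "run_meta.json"
    if not force and meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if meta.get("config_hash") == chash and all(
            (outdir / f).exists() for f in BUNDLE_FILES
        ):
            logger.info("bundle up to date (hash %s); skipping", chash[:12])
            return json.loads((outdir / "bundle.json").read_text())

    bundle: dict = {"config_hash": chash}
    cutoffs = HeterogeneityCutoffs(cfg.low, cfg.high)

    # --- io ---
    stage = "io"
    try:
        wt = read_cytosine_report(cfg.wt_methylome, sample_id="wt", genotype="wt")
        mut = read_cytosine_report(cfg.mut_methylome, sample_id="mut", genotype="mut")
        genes = read_gene_models(cfg.genes)
        if cfg.control_contig:
            qc = {
                g.sample_id: conversion_qc(g, cfg.control_contig, cfg.conversion_threshold)
                for g in (wt, mut)
            }
            bundle["qc"] = {
                k: {
                    "conversion_rate": v.conversion_rate,
                    "apparent_methylation": v.apparent_methylation,
                    "n_calls": v.n_calls,
                    "passed": v.passed,
                }
                for k, v in qc.items()
            }

        # --- heterogeneity ---
        stage = "heterogeneity"
        wt_sites = pool_cg_dinucleotides(wt)
        mut_sites = pool_cg_dinucleotides(mut)
        prof_wt = gene_profiles(genes, wt_sites, wt, cutoffs, cfg.min_coverage)
        prof_mut = gene_profiles(genes, mut_sites, mut, cutoffs, cfg.min_coverage)
        bundle["global_mcg"] = {
            "wt": _global_mcg(wt_sites, cfg.min_coverage),
            "mut": _global_mcg(mut_sites, cfg.min_coverage),
        }

        # --- dmr ---
        stage = "dmr"
        diff = dmr_mod.differential_sites(
            wt_sites, mut_sites, cfg.min_coverage, cfg.min_delta_pp
        )
        dmrs = dmr_mod.call_dmrs(diff, cfg.window_bp, cfg.min_dmr_sites)
        dmr_mod.write_dmrs_bed(dmrs, outdir / "dmrs.bed")
        assoc = dmr_mod.associate_dmrs(dmrs, genes, cfg.flank_bp)
        assoc.to_csv(outdir / "dmr_gene_associations.tsv", sep="\t", index=False)

        # --- classification ---
        stage = "classify"
        stable_list = _read_gene_list(cfg.stable_list) if cfg.stable_list else None
        table = classify_mod.classify_genes(
            genes,
            prof_wt,
            wt_sites,
            mut_sites,
            dmrs,
            stable_list=stable_list,
            min_gain=cfg.min_gain,
            min_gaining=cfg.min_gaining,
            min_coverage=cfg.min_coverage,
            cutoffs=cutoffs,
        )
        table = table.merge(
            prof_mut[["gene_id", "mcg", "n_sites", "n_methylated"]].rename(
                columns={"mcg": "mcg_mut", "n_sites": "n_sites_mut", "n_methylated": "n_methylated_mut"}
            ),
            on="gene_id",
            how="left",
        ).rename(columns={"mcg": "mcg_wt"})
        table.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        partition = classify_mod.resolve_overlap(table)
        bundle["venn"] = partition["venn"]
        bundle["n_dmrs"] = int(len(dmrs))
        dynamic_set = set(partition["dynamic"])
        stable_set = set(partition["stable"])
        excluded = set(partition["excluded_overlap"])
        if cfg.dynamic_set:
            dynamic_set |= _read_gene_list(cfg.dynamic_set)
        if cfg.stable_set:
            stable_set |= _read_gene_list(cfg.stable_set)

        # --- conservation ---
        if cfg.homologs and cfg.target_methylome and cfg.target_genes:
            stage = "conservation"
            pairs = cons_mod.read_homolog_table(cfg.homologs)
            tgt = read_cytosine_report(cfg.target_methylome, sample_id="target")
            tgenes = read_gene_models(cfg.target_genes)
            tsites = pool_cg_dinucleotides(tgt)
            tprof = gene_profiles(tgenes, tsites, tgt, cutoffs, cfg.min_coverage)
            filtered = cons_mod.filter_homologs(pairs, tprof)
            het = cons_mod.count_het_cgs(tprof)
            universe = sorted(set(pairs["source_gene"]))
            result = cons_mod.enrichment_vs_random(
                dynamic_set & set(universe),
                universe,
                filtered,
                het,
                k=cfg.k_random_sets,
                seed=cfg.seed,
                species=str(pairs["species"].iloc[0]) if len(pairs) else "",
            )
            bundle["conservation"] = {
                "species": result.species,
                "n_target_genes": result.n_target_genes,
                "fold_count": result.fold_count,
                "fold_density": result.fold_density,
                "p_count": result.p_count,
                "p_density": result.p_density,
                "k": result.k,
            }

        # --- chromatin ---
        if cfg.chip_tracks and cfg.states:
            stage = "chromatin"
            states = pd.read_csv(
                cfg.states, sep="\t", header=None, names=["chrom", "start", "end", "state"],
                dtype={"state": str},
            )
            lengths = states.groupby("chrom")["end"].max().to_dict()
            dyn_bodies = genes[genes["gene_id"].isin(dynamic_set)]
            sta_bodies = genes[genes["gene_id"].isin(stable_set)]
            groups = {"dynamic": dyn_bodies, "stable": sta_bodies, "total": genes}
            chrom_report: dict = {"tracks": {}}
            for name, path in cfg.chip_tracks.items():
                depth = chrom_mod.read_bedgraph(path, {c: int(n) for c, n in lengths.items()})
                track = chrom_mod.normalize_track(depth)
                enr = chrom_mod.feature_enrichment(track, groups)
                chrom_report["tracks"][name] = {
                    "group_means": enr["group_means"],
                    "cohens_d": {
                        f"{a}_vs_{b}": v["cohens_d"] for (a, b), v in enr["pairwise"].items()
                    },
                }
            overlap = chrom_mod.state_overlap({"dynamic": dyn_bodies, "stable": sta_bodies}, states)
            chrom_report["state_overlap"] = overlap.to_dict(orient="records")
            bundle["chromatin"] = chrom_report

        # --- plasticity ---
        if cfg.expr_wt and cfg.expr_mut:
            stage = "plasticity"
            ewt = pd.read_csv(cfg.expr_wt, sep="\t", index_col=0)
            emut = pd.read_csv(cfg.expr_mut, sep="\t", index_col=0)
            stats_table = plast_mod.plasticity_stats(ewt)
            comparison = plast_mod.compare_sets(
                stats_table,
                {"dynamic": dynamic_set, "stable": stable_set, "total": set(ewt.index)},
                exclusion=excluded,
            )
            focal = cfg.focal_condition or ewt.columns[0]
            others = [c for c in ewt.columns if c != focal]
            decile_dyn = plast_mod.decile_dynamic_range(
                ewt[focal], emut[focal], dynamic_set - excluded
            )
            decile_sta = plast_mod.decile_dynamic_range(
                ewt[focal], emut[focal], stable_set - excluded
            )
            ref_fc = plast_mod.log2_fold_change(ewt[focal], ewt[others])
            gen_fc = np.log2((emut[focal] + 1.0) / (ewt[focal] + 1.0))
            reg_dyn = plast_mod.tissue_specificity_regression(ref_fc, gen_fc, dynamic_set - excluded)
            reg_sta = plast_mod.tissue_specificity_regression(ref_fc, gen_fc, stable_set - excluded)
            bundle["plasticity"] = {
                "set_medians": {
                    name: {
                        "cv": float(sub["cv"].median()),
                        "fano": float(sub["fano"].median()),
                        "n": int(len(sub)),
                    }
                    for name, sub in comparison["per_set"].items()
                },
                "pairwise_p": {
                    f"{a}_vs_{b}": {m: v[m]["p"] for m in ("cv", "fano")}
                    for (a, b), v in comparison["pairwise"].items()
                },
                "decile": {
                    "dynamic": _decile_dict(decile_dyn),
                    "stable": _decile_dict(decile_sta),
                },
                "regression": {
                    "dynamic": asdict(reg_dyn),
                    "stable": asdict(reg_sta),
                },
            }
            flank = assoc[assoc["relation"].str.startswith("flank")]
            if not flank.empty:
                ic = plast_mod.intergenic_control(assoc, stats_table)
                bundle["plasticity"]["intergenic_control_p"] = {
                    f"{a}_vs_{b}": v["cv"]["p"] for (a, b), v in ic["pairwise"].items()
                }
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    meta = {
        "config_hash": chash,
        "parameters": {
            k: v
            for k, v in asdict(cfg).items()
            if not isinstance(v, (dict,)) and k not in _PATH_FIELDS
        },
        "inputs": sorted(Path(p).name for p in _input_paths(cfg)),
    }
    (outdir / "bundle.json").write_text(json.dumps(_jsonable(bundle), indent=2, sort_keys=True))
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return bundle


def _global_mcg(sites: pd.DataFrame, min_coverage: int) -> float:
    covered = sites[sites["n_total"] >= min_coverage]
    tot = covered["n_total"].sum()
    return float(covered["n_meth"].sum() / tot) if tot else float("nan")


def _decile_dict(report) -> dict:
    return {
        "sd_wt": report.sd["wt"],
        "sd_mut": report.sd["mut"],
        "sd_ratio": report.sd_ratio,
        "f_statistic": report.f_statistic,
        "f_p": report.f_p,
        "n_genes": report.n_genes,
        "proportions_wt": report.proportions["wt"].tolist(),
        "proportions_mut": report.proportions["mut"].tolist(),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def run_synthetic(sim_cfg=None, outdir: str | Path = "gbmdyn_run", seed: int | None = None,
                  force: bool = False) -> dict:
    """Generate the default synthetic dataset, write it to disk and run the
    full pipeline on the written files (exercising every I/O dialect)."""
    from .simulate import SimulationConfig, simulate_all, write_dataset

    sim_cfg = sim_cfg or SimulationConfig()
    if seed is not None:
        sim_cfg.seed = seed
    outdir = Path(outdir)
    data_dir = outdir / "data"
    ds = simulate_all(sim_cfg)
    paths = write_dataset(ds, data_dir)

    # gene-set lists for the expression stage: generated classes of the
    # expression-only genes supplement the classification-derived sets
    dyn_extra = ds.expr_truth[
        ds.expr_truth["expression_class"].eq("dynamic")
        & ds.expr_truth["gene_id"].str.startswith("X_")
    ]["gene_id"]
    sta_extra = ds.expr_truth[
        ds.expr_truth["expression_class"].eq("stable")
        & ds.expr_truth["gene_id"].str.startswith("X_")
    ]["gene_id"]
    dyn_path = data_dir / "dynamic_extra.txt"
    sta_path = data_dir / "stable_extra.txt"
    dyn_path.write_text("\n".join(dyn_extra) + "\n")
    sta_path.write_text("\n".join(sta_extra) + "\n")

    cfg = PipelineConfig(
        wt_methylome=str(paths["wt"]),
        mut_methylome=str(paths["mut"]),
        genes=str(paths["genes"]),
        control_contig=sim_cfg.control_contig,
        target_methylome=str(paths["target"]),
        target_genes=str(paths["target_genes"]),
        homologs=str(paths["homologs"]),
        expr_wt=str(paths["expr_wt"]),
        expr_mut=str(paths["expr_mut"]),
        dynamic_set=str(dyn_path),
        stable_set=str(sta_path),
        chip_tracks={name: str(paths[f"chip_{name}"]) for name in ds.chip_tracks},
        states=str(paths["states"]),
        seed=sim_cfg.seed,
    )
    return run_pipeline(cfg, outdir / "results", force=force)
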