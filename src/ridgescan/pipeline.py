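"""End-to-end orchestration: simulate/load -> map -> call -> permute -> features -> breaks.

One YAML config drives a full run; every stage logs its inputs and
record counts, the final summary.json collects all statistics, and a
rerun with the same config and inputs is bit-identical for the
deterministic stages (the permutation stage is deterministic given its
seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import core_io
from .features import (
    FEATURE_NAMES,
    align_genes_to_map,
    build_feature_track,
    compare_region_features,
    map_feature_correlation,
)
from .maps import (
    build_map,
    build_strand_maps,
    chromosome_summaries,
    expression_length_correlation,
    export_map_tsv,
)
from .permutation import permute_and_count
from .regions import (
    ANTIRIDGE,
    RIDGE,
    CallerConfig,
    call_regions,
    coverage,
    genomic_median,
    regions_to_bed,
    resolve_config,
)
from .simulate import SimulationConfig, simulate_expression, simulate_genome, simulate_synteny
from .synteny import (
    blocks_to_breakpoints,
    breakpoint_enrichment,
    classify_cross_species,
    homolog_region_overlap,
)

log = logging.getLogger("ridgescan")

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_run_config", "SummaryModel"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the exit message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class RunConfig(BaseModel):
    """One-file description of a pipeline run (CLI flags override fields)."""

    out_dir: Path = Path("ridgescan_out")
    # inputs (ignored when simulate=true)
    genes: Path | None = None
    expr: Path | None = None
    blocks: Path | None = None
    homologs: Path | None = None
    genes_b: Path | None = None
    expr_b: Path | None = None
    simulate: bool = False
    sim: dict[str, Any] = Field(default_factory=dict)
    # caller parameters
    window: int = 39
    min_run: int = 10
    ridge_multiplier: float = 1.19
    antiridge_multiplier: float = 0.78
    target_coverage: float | None = None
    # stages
    n_perm: int = 0
    per_strand: bool = False
    per_tissue: bool = False
    conservative_p: bool = False
    features: bool = True
    seed: int = 0


class SummaryModel(BaseModel):
    """Shape of summary.json (the shipped schema is generated from this model)."""

    seed: int
    parameters: dict[str, Any]
    map: dict[str, Any]
    regions: dict[str, Any]
    chromosomes: dict[str, Any]
    permutation: dict[str, Any] | None = None
    tissue_correlations: dict[str, float] | None = None
    features: dict[str, Any] | None = None
    breaks: dict[str, Any] | None = None
    stages: list[str]


def load_run_config(path: str | Path) -> RunConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _caller_config(cfg: RunConfig) -> CallerConfig:
    return CallerConfig(
        window=cfg.window,
        min_run=cfg.min_run,
        ridge_multiplier=cfg.ridge_multiplier,
        antiridge_multiplier=cfg.antiridge_multiplier,
        target_coverage=cfg.target_coverage,
    )


def _check_inputs(cfg: RunConfig) -> None:
    if cfg.simulate:
        return
    for name in ("genes", "expr"):
        p = getattr(cfg, name)
        if p is None:
            raise StageError("map", f"config requires {name!r} unless simulate is true")
        if not Path(p).exists():
            raise StageError("map", f"input file not found: {p}")
    for name in ("blocks", "homologs", "genes_b", "expr_b"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            raise StageError("breaks", f"input file not found: {p}")


def run_pipeline(cfg: RunConfig, dry_run: bool = False) -> dict[str, Any]:
    """Run the requested stages; write outputs under ``cfg.out_dir``.

    Returns the summary dictionary (also written as summary.json).  On a
    stage failure the partial summary is kept as summary.json.partial
    and a :class:`StageError` naming the stage is raised.
    """
    _check_inputs(cfg)
    if dry_run:
        log.info("dry run: config and input headers validated")
        if not cfg.simulate:
            core_io.read_gene_table(cfg.genes)
            core_io.read_expression(cfg.expr)
        return {"dry_run": True}

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": cfg.seed,
        "parameters": cfg.model_dump(mode="json"),
        "stages": [],
    }
    try:
        return _run_stages(cfg, out_dir, summary)
    except StageError:
        (out_dir / "summary.json.partial").write_text(json.dumps(summary, indent=2))
        raise
    except Exception as exc:  # wrap with the current stage for the exit message
        stage = summary["stages"][-1] if summary["stages"] else "setup"
        (out_dir / "summary.json.partial").write_text(json.dumps(summary, indent=2))
        raise StageError(stage, str(exc)) from exc


def _run_stages(cfg: RunConfig, out_dir: Path, summary: dict[str, Any]) -> dict[str, Any]:
    sim_result = None
    truth = None
    if cfg.simulate:
        summary["stages"].append("simulate")
        sim_cfg = SimulationConfig(**{"seed": cfg.seed, **cfg.sim})
        genes, truth = simulate_genome(sim_cfg, min_genes=cfg.window)
        expr = simulate_expression(genes, truth, sim_cfg)
        sim_result = simulate_synteny(genes, truth, sim_cfg)
        core_io.write_gene_table(genes, out_dir / "genes.tsv")
        core_io.write_expression(expr, out_dir / "expr.tsv")
        core_io.write_synteny(sim_result.blocks, out_dir / "blocks.tsv")
        core_io.write_homologs(sim_result.pairs, out_dir / "homologs.tsv")
        (out_dir / "truth.json").write_text(
            json.dumps(
                {
                    "chrom_lengths": truth.chrom_lengths,
                    "high_intervals": truth.high_intervals,
                    "low_intervals": truth.low_intervals,
                },
                indent=2,
            )
        )
        log.info("simulate: %d genes, %d blocks", len(genes), len(sim_result.blocks))
    else:
        genes = core_io.read_gene_table(cfg.genes)
        expr = core_io.read_expression(cfg.expr)

    summary["stages"].append("map")
    tmap = build_map(genes, expr, window=cfg.window)
    export_map_tsv(tmap, out_dir / "map.tsv")
    summary["map"] = {
        "label": tmap.label,
        "window": tmap.window,
        "n_genes": tmap.n_genes,
        "n_chromosomes": len(tmap.profiles),
        "dropped_genes": tmap.dropped_genes,
        "excluded_chromosomes": tmap.excluded_chromosomes,
        "genomic_median": genomic_median(tmap),
        "analyzed_length": tmap.analyzed_length(),
    }
    log.info("map: %d genes on %d chromosomes", tmap.n_genes, len(tmap.profiles))

    if cfg.per_strand:
        plus, minus = build_strand_maps(genes, expr)
        export_map_tsv(plus, out_dir / "map_plus.tsv")
        export_map_tsv(minus, out_dir / "map_minus.tsv")
        summary["map"]["per_strand_genes"] = {"+": plus.n_genes, "-": minus.n_genes}

    summary["stages"].append("call")
    caller = resolve_config(tmap, _caller_config(cfg))
    regions = call_regions(tmap, caller)
    regions_to_bed(regions, out_dir / "regions.bed")
    glen = tmap.analyzed_length()
    ridges = [r for r in regions if r.kind == RIDGE]
    antis = [r for r in regions if r.kind == ANTIRIDGE]
    summary["regions"] = {
        "ridge_multiplier": caller.ridge_multiplier,
        "antiridge_multiplier": caller.antiridge_multiplier,
        "min_run": caller.min_run,
        "n_ridges": len(ridges),
        "n_antiridges": len(antis),
        "n_ridge_genes": sum(r.n_genes for r in ridges),
        "n_antiridge_genes": sum(r.n_genes for r in antis),
        "ridge_coverage": coverage(ridges, glen),
        "antiridge_coverage": coverage(antis, glen),
    }
    log.info("call: %d RIDGEs, %d anti-RIDGEs", len(ridges), len(antis))

    summaries = chromosome_summaries(tmap)
    chrom_block: dict[str, Any] = {
        s.chrom: {
            "length": s.length,
            "n_genes": s.n_genes,
            "median_expression": s.median_expression,
        }
        for s in summaries
    }
    if len(summaries) >= 3:
        r, p = expression_length_correlation(summaries)
        chrom_block["expression_length_pearson"] = {"r": r, "p": p}
    summary["chromosomes"] = chrom_block

    if cfg.per_tissue:
        summary["stages"].append("tissue_maps")
        cors = {}
        for tissue in expr.tissue_names:
            tissue_map = build_map(genes, expr, window=cfg.window, value_source=tissue)
            rep = map_correlation_between(tmap, tissue_map)
            cors[tissue] = rep
        summary["tissue_correlations"] = cors

    if cfg.n_perm > 0:
        summary["stages"].append("permtest")
        res = permute_and_count(
            genes, expr, _caller_config(cfg), cfg.n_perm, cfg.seed,
            conservative=cfg.conservative_p,
        )
        hist = np.bincount(res.null_counts)
        perm_block = {
            "observed": res.observed_count,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "seed": res.seed,
            "null_histogram": {str(i): int(c) for i, c in enumerate(hist) if c},
        }
        summary["permutation"] = perm_block
        (out_dir / "perm.json").write_text(json.dumps(perm_block, indent=2))
        log.info("permtest: observed %d, p = %.4g", res.observed_count, res.p_value)

    has_features = any(g.gc_fraction is not None for g in genes)
    if cfg.features and has_features:
        summary["stages"].append("features")
        aligned = align_genes_to_map(genes, tmap)
        feat_block: dict[str, Any] = {"correlations": {}, "region_tests": {}}
        for name in FEATURE_NAMES:
            track = build_feature_track(aligned, name, smooth_window=cfg.window)
            rep = map_feature_correlation(tmap, track)
            feat_block["correlations"][name] = {
                "rho": rep.rho, "p": rep.p_value, "n": rep.n,
            }
            try:
                cmp_rep = compare_region_features(aligned, regions, name)
                feat_block["region_tests"][name] = {
                    "medians": cmp_rep.medians,
                    "n": cmp_rep.n,
                    "p_values": cmp_rep.p_values,
                }
            except ValueError as exc:
                feat_block["region_tests"][name] = {"skipped": str(exc)}
        summary["features"] = feat_block

    blocks = pairs = genes_b = expr_b = None
    if cfg.simulate and sim_result is not None:
        blocks = sim_result.blocks
        pairs = sim_result.pairs
        genes_b = sim_result.genes_b
        # homologs inherit genome-A expression
        expr_b = expr.rename_genes({p.gene_id_a: p.gene_id_b for p in pairs})
    else:
        if cfg.blocks:
            blocks = core_io.read_synteny(cfg.blocks)
        if cfg.homologs:
            pairs = core_io.read_homologs(cfg.homologs)
        if cfg.genes_b:
            genes_b = core_io.read_gene_table(cfg.genes_b)
        if cfg.expr_b:
            expr_b = core_io.read_expression(cfg.expr_b)

    if blocks:
        summary["stages"].append("breaks")
        bps = blocks_to_breakpoints(blocks)
        breaks_block: dict[str, Any] = {"n_blocks": len(blocks), "n_breakpoints": len(bps)}
        for kind, regs in ((RIDGE, ridges), (ANTIRIDGE, antis)):
            if regs:
                rep = breakpoint_enrichment(bps, regs, glen)
                breaks_block[f"enrichment_{kind}"] = dataclasses.asdict(rep)
        regions_b = None
        if genes_b is not None and expr_b is not None:
            tmap_b = build_map(genes_b, expr_b, window=cfg.window)
            caller_b = resolve_config(tmap_b, _caller_config(cfg))
            regions_b = call_regions(tmap_b, caller_b)
            regions_to_bed(regions_b, out_dir / "regions_b.bed")
        if regions_b:
            cs = classify_cross_species(bps, regions, regions_b)
            breaks_block["cross_species"] = {
                "ridge_to_ridge": cs.ridge_to_ridge,
                "antiridge_to_antiridge": cs.antiridge_to_antiridge,
                "ridge_expected": cs.ridge_expected,
                "ridge_chi_square": cs.ridge_chi_square,
                "ridge_p": cs.ridge_p_value,
                "antiridge_expected": cs.antiridge_expected,
                "antiridge_chi_square": cs.antiridge_chi_square,
                "antiridge_p": cs.antiridge_p_value,
            }
            if pairs and genes_b is not None:
                rep = homolog_region_overlap(pairs, regions, regions_b, list(genes), genes_b)
                breaks_block["homolog_overlap"] = dataclasses.asdict(rep)
        summary["breaks"] = breaks_block
        (out_dir / "breaks.json").write_text(json.dumps(breaks_block, indent=2, default=str))

    SummaryModel.model_validate(summary)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def map_correlation_between(map_a, map_b) -> float:
    """Spearman correlation between two maps' smoothed values on shared genes."""
    from scipy import stats

    xs, ys = [], []
    for chrom, pa in map_a.profiles.items():
        pb = map_b.profiles.get(chrom)
        if pb is None or pa.gene_ids != pb.gene_ids:
            continue
        xs.append(pa.smoothed)
        ys.append(pb.smoothed)
    if not xs:
        raise ValueError("maps share no identically ordered chromosome")
    rho = stats.spearmanr(np.concatenate(xs), np.concatenate(ys)).statistic
    return float(rho)
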