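"""Synthetic genomes with planted expression domains and known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a karyotype of chromosomes of widely varying size; genes placed by a
Poisson process; non-overlapping planted "high" and "low" expression
blocks each covering ~10% of the genome; log2 expression over a tissue
panel with a regime shift inside planted blocks; sequence features
coupled to the regime (higher GC, higher gene density, shorter genes
and shorter introns inside high blocks, the opposite inside low
blocks); and a rearranged second genome whose synteny-block endpoints
are preferentially placed inside high blocks.

Every component draws from its own named random stream derived from one
global seed, so adding draws to one component does not perturb the
others.  Defaults are scaled to ~5,000 genes on 10 chromosomes for fast
iteration; :meth:`SimulationConfig.full_scale` emits ~11,400 genes on
27 chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import ExpressionTable, GeneRecord, HomologPair, SyntenyBlock

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntenySimulation",
    "simulate_genome",
    "simulate_expression",
    "simulate_synteny",
]

# study panel; reused for any 8-tissue simulation
_TISSUES = ("brain", "bursa", "kidney", "liver", "lung", "intestine", "spleen", "thymus")

_STREAMS = {"genome": 1, "expression": 2, "synteny": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def default_feature_coupling() -> dict[str, float]:
    """Regime-dependent feature effects (high blocks are RIDGE-like)."""
    return {
        "gc_shift_high": 0.05,
        "gc_shift_low": -0.03,
        "length_factor_high": 0.55,
        "length_factor_low": 1.6,
        "intron_factor_high": 0.55,
        "intron_factor_low": 1.6,
        "density_factor_high": 1.6,
        "density_factor_low": 0.7,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genome.  All rates are per genome A."""

    n_chromosomes: int = 10
    chrom_length_min: int = 10_000_000
    chrom_length_max: int = 40_000_000
    genes_per_mb: float = 22.0
    n_tissues: int = 8
    planted_high_fraction: float = 0.10
    planted_low_fraction: float = 0.10
    high_effect: float = 0.8  # log2 shift inside high blocks
    low_effect: float = -0.8
    baseline: float = 7.3  # log2 intensity scale of the arrays being emulated
    noise_sd: float = 0.5  # per-gene scatter, log2 units
    tissue_sd: float = 0.3  # per-(gene, tissue) scatter, log2 units
    feature_coupling: dict[str, float] = field(default_factory=default_feature_coupling)
    n_breakpoints: int = 200
    breakpoint_ridge_bias: float = 2.5  # relative breakpoint rate inside high blocks
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_high_fraction", "planted_low_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.planted_high_fraction + self.planted_low_fraction >= 0.8:
            raise ValueError("planted fractions leave too little background")
        if self.noise_sd < 0 or self.tissue_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    @classmethod
    def full_scale(cls, seed: int = 0) -> "SimulationConfig":
        """~11,400 genes on 27 chromosomes of widely varying size (~1.1 Gb)."""
        return cls(
            n_chromosomes=27,
            chrom_length_min=2_000_000,
            chrom_length_max=200_000_000,
            genes_per_mb=9.8,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulated genome."""

    chrom_lengths: dict[str, int]
    high_intervals: dict[str, list[tuple[int, int]]]
    low_intervals: dict[str, list[tuple[int, int]]]
    gene_regime: dict[str, str]  # gene id -> high / low / background

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def total_high_length(self) -> int:
        return sum(e - s for iv in self.high_intervals.values() for s, e in iv)

    def total_low_length(self) -> int:
        return sum(e - s for iv in self.low_intervals.values() for s, e in iv)

    def regime_at(self, chrom: str, pos: int) -> str:
        for s, e in self.high_intervals.get(chrom, []):
            if s <= pos < e:
                return "high"
        for s, e in self.low_intervals.get(chrom, []):
            if s <= pos < e:
                return "low"
        return "background"


def _place_blocks(
    rng: np.random.Generator,
    chrom_len: int,
    sizes: Sequence[int],
    min_gap: int,
    existing: Sequence[tuple[int, int]] = (),
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping intervals separated by >= min_gap."""
    placed: list[tuple[int, int]] = list(existing)
    out: list[tuple[int, int]] = []
    for size in sizes:
        if size >= chrom_len or size < 1:
            continue
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - size))
            cand = (start, start + size)
            if all(
                cand[1] + min_gap <= s or e + min_gap <= cand[0] for s, e in placed
            ):
                placed.append(cand)
                out.append(cand)
                break
        # unplaceable after max_tries: silently skip (tracked via realized fraction)
    return sorted(out)


def simulate_genome(
    config: SimulationConfig, min_genes: int = 39
) -> tuple[list[GeneRecord], GroundTruth]:
    """Simulate gene annotations with planted high/low expression blocks.

    Gene positions follow a Poisson process at ``genes_per_mb``
    (multiplied by the regime's density factor inside planted blocks);
    lengths and intron structures are log-normal with regime-dependent
    scale; GC is beta-distributed with a regime shift.  Raises when the
    expected gene count is below ``min_genes`` on every chromosome
    (no chromosome could ever be mapped).
    """
    rng = _rng(config.seed, "genome")
    fc = config.feature_coupling
    lengths = np.exp(
        rng.uniform(
            np.log(config.chrom_length_min),
            np.log(config.chrom_length_max),
            config.n_chromosomes,
        )
    ).astype(np.int64)
    if all(length * config.genes_per_mb / 1e6 < min_genes for length in lengths):
        raise ValueError(
            "infeasible density: expected gene count below "
            f"{min_genes} on every chromosome"
        )
    min_gap = int(39e6 / config.genes_per_mb)  # one smoothing window of expected genes
    genes: list[GeneRecord] = []
    truth = GroundTruth(chrom_lengths={}, high_intervals={}, low_intervals={}, gene_regime={})
    for ci, chrom_len in enumerate(lengths, start=1):
        chrom = f"chr{ci}"
        chrom_len = int(chrom_len)
        truth.chrom_lengths[chrom] = chrom_len
        high_size = int(chrom_len * rng.uniform(0.7, 1.3) * config.planted_high_fraction)
        low_size = int(chrom_len * rng.uniform(0.7, 1.3) * config.planted_low_fraction)
        high_iv = _place_blocks(rng, chrom_len, [high_size], min_gap)
        low_iv = _place_blocks(rng, chrom_len, [low_size], min_gap, existing=high_iv)
        truth.high_intervals[chrom] = high_iv
        truth.low_intervals[chrom] = low_iv

        # piecewise-constant Poisson process over regime segments
        cuts = sorted({0, chrom_len, *(x for iv in high_iv + low_iv for x in iv)})
        counter = 0
        for s, e in zip(cuts, cuts[1:]):
            regime = truth.regime_at(chrom, s)
            factor = {
                "high": fc["density_factor_high"],
                "low": fc["density_factor_low"],
                "background": 1.0,
            }[regime]
            lam = config.genes_per_mb * factor * (e - s) / 1e6
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            starts = np.sort(rng.integers(s, e, n))
            len_factor = {
                "high": fc["length_factor_high"],
                "low": fc["length_factor_low"],
                "background": 1.0,
            }[regime]
            glens = np.maximum(
                200, rng.lognormal(np.log(15_000 * len_factor), 0.8, n)
            ).astype(np.int64)
            gc_shift = {
                "high": fc["gc_shift_high"],
                "low": fc["gc_shift_low"],
                "background": 0.0,
            }[regime]
            gc_mean = np.clip(0.40 + gc_shift, 0.05, 0.95)
            gcs = rng.beta(gc_mean * 60, (1 - gc_mean) * 60, n)
            intron_factor = {
                "high": fc["intron_factor_high"],
                "low": fc["intron_factor_low"],
                "background": 1.0,
            }[regime]
            for j in range(n):
                start = int(starts[j])
                end = min(start + int(glens[j]), chrom_len)
                if end - start < 2:
                    continue
                counter += 1
                gene_id = f"g{ci:02d}_{counter:05d}"
                n_tx = int(rng.integers(1, 3))
                introns: list[list[int]] = []
                for _ in range(n_tx):
                    k = int(rng.poisson(6))
                    if k:
                        ilens = np.maximum(
                            25,
                            rng.lognormal(np.log(1200 * intron_factor), 1.1, k),
                        ).astype(int)
                        introns.append([int(x) for x in ilens])
                rec = GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand="+" if rng.random() < 0.5 else "-",
                    gc_fraction=float(gcs[j]),
                    transcript_intron_lengths=introns or None,
                )
                genes.append(rec)
                truth.gene_regime[gene_id] = truth.regime_at(chrom, rec.midpoint)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes, truth


def simulate_expression(
    genes: Sequence[GeneRecord], truth: GroundTruth, config: SimulationConfig
) -> ExpressionTable:
    """Log2 expression: baseline + regime shift + gene effect + tissue effect."""
    rng = _rng(config.seed, "expression")
    n = len(genes)
    shift = np.array(
        [
            {"high": config.high_effect, "low": config.low_effect, "background": 0.0}[
                truth.gene_regime[g.gene_id]
            ]
            for g in genes
        ]
    )
    gene_effect = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else np.zeros(n)
    tissue_effect = (
        rng.normal(0.0, config.tissue_sd, (n, config.n_tissues))
        if config.tissue_sd
        else np.zeros((n, config.n_tissues))
    )
    values = config.baseline + (shift + gene_effect)[:, None] + tissue_effect
    if config.n_tissues == len(_TISSUES):
        tissues = list(_TISSUES)
    else:
        tissues = [f"tissue_{i + 1}" for i in range(config.n_tissues)]
    return ExpressionTable(
        gene_ids=[g.gene_id for g in genes], tissue_names=tissues, values=values
    )


@dataclass
class SyntenySimulation:
    """A rearranged copy of genome A with full ground truth."""

    blocks: list[SyntenyBlock]
    genes_b: list[GeneRecord]
    truth_b: GroundTruth
    pairs: list[HomologPair]
    cut_positions: list[tuple[str, int]]  # internal breakpoints placed on genome A


def _gap_candidates(
    genes_by_chrom: dict[str, list[GeneRecord]]
) -> list[tuple[str, int]]:
    """Positions between consecutive genes where a cut splits no gene."""
    out: list[tuple[str, int]] = []
    for chrom, ordered in genes_by_chrom.items():
        bounds = [(g.start, g.end) for g in ordered]
        max_end = 0
        for (s0, e0), (s1, _e1) in zip(bounds, bounds[1:]):
            max_end = max(max_end, e0)
            if s1 > max_end:  # a true gap even with overlapping annotations
                out.append((chrom, (max_end + s1) // 2))
    return out


def simulate_synteny(
    genes_a: Sequence[GeneRecord],
    truth_a: GroundTruth,
    config: SimulationConfig,
) -> SyntenySimulation:
    """Cut genome A into blocks and reassemble them as genome B.

    Cut positions are sampled from the inter-gene gaps, with weight
    ``breakpoint_ridge_bias`` for gaps inside planted high blocks, so no
    gene is ever split.  Segments are shuffled, randomly oriented and
    concatenated into genome-B chromosomes; every A gene maps to exactly
    one B gene (the homolog pairs), and planted intervals are carried
    through the rearrangement into genome B's ground truth.
    """
    rng = _rng(config.seed, "synteny")
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes_a, key=lambda g: (g.chrom, g.start, g.gene_id)):
        by_chrom.setdefault(g.chrom, []).append(g)
    candidates = _gap_candidates(by_chrom)
    if config.n_breakpoints > len(candidates):
        raise ValueError(
            f"cannot place {config.n_breakpoints} breakpoints in "
            f"{len(candidates)} inter-gene gaps"
        )
    weights = np.array(
        [
            config.breakpoint_ridge_bias
            if truth_a.regime_at(chrom, pos) == "high"
            else 1.0
            for chrom, pos in candidates
        ]
    )
    idx = rng.choice(
        len(candidates),
        size=config.n_breakpoints,
        replace=False,
        p=weights / weights.sum(),
    )
    cuts: dict[str, list[int]] = {chrom: [] for chrom in truth_a.chrom_lengths}
    for i in idx:
        chrom, pos = candidates[i]
        cuts[chrom].append(pos)

    # genome-A segments
    segments: list[tuple[str, int, int]] = []
    for chrom, length in truth_a.chrom_lengths.items():
        edges = [0] + sorted(cuts[chrom]) + [length]
        for s, e in zip(edges, edges[1:]):
            if e > s:
                segments.append((chrom, s, e))
    if len(segments) < 2:
        raise ValueError("rearrangement needs at least 2 segments")

    order = rng.permutation(len(segments))
    orientations = rng.random(len(segments)) < 0.5  # True = inverted
    n_chrom_b = config.n_chromosomes
    offsets = [0] * n_chrom_b
    blocks: list[SyntenyBlock] = []
    genes_b: list[GeneRecord] = []
    pairs: list[HomologPair] = []
    truth_b = GroundTruth(
        chrom_lengths={f"chrB{i + 1}": 0 for i in range(n_chrom_b)},
        high_intervals={f"chrB{i + 1}": [] for i in range(n_chrom_b)},
        low_intervals={f"chrB{i + 1}": [] for i in range(n_chrom_b)},
        gene_regime={},
    )
    for rank, seg_idx in enumerate(order):
        chrom_a, s_a, e_a = segments[seg_idx]
        inverted = bool(orientations[seg_idx])
        bi = rank % n_chrom_b
        chrom_b = f"chrB{bi + 1}"
        s_b = offsets[bi]
        e_b = s_b + (e_a - s_a)
        offsets[bi] = e_b
        blocks.append(
            SyntenyBlock(
                block_id=f"blk{rank + 1:04d}",
                chrom_a=chrom_a,
                start_a=s_a,
                end_a=e_a,
                chrom_b=chrom_b,
                start_b=s_b,
                end_b=e_b,
                orientation="-" if inverted else "+",
            )
        )

        def to_b(pos: int) -> int:
            return (s_b + (e_a - pos)) if inverted else (s_b + (pos - s_a))

        # carry planted intervals into genome B truth
        for kind, ivs in (("high", truth_a.high_intervals.get(chrom_a, [])),
                          ("low", truth_a.low_intervals.get(chrom_a, []))):
            target = truth_b.high_intervals if kind == "high" else truth_b.low_intervals
            for iv_s, iv_e in ivs:
                lo, hi = max(iv_s, s_a), min(iv_e, e_a)
                if lo < hi:
                    b0, b1 = sorted((to_b(lo), to_b(hi)))
                    target[chrom_b].append((b0, b1))

        for g in by_chrom.get(chrom_a, []):
            if not (s_a <= g.midpoint < e_a):
                continue
            if inverted:
                nb_start, nb_end = to_b(g.end), to_b(g.start)
                strand = "-" if g.strand == "+" else "+"
            else:
                nb_start, nb_end = to_b(g.start), to_b(g.end)
                strand = g.strand
            nb_start = max(nb_start, s_b)
            nb_end = min(nb_end, e_b)
            if nb_end <= nb_start:
                continue
            gid_b = f"B_{g.gene_id}"
            rec = GeneRecord(
                gene_id=gid_b,
                chrom=chrom_b,
                start=nb_start,
                end=nb_end,
                strand=strand,
                gc_fraction=g.gc_fraction,
                transcript_intron_lengths=g.transcript_intron_lengths,
            )
            genes_b.append(rec)
            pairs.append(HomologPair(g.gene_id, gid_b))
            truth_b.gene_regime[gid_b] = truth_a.gene_regime[g.gene_id]
    for i in range(n_chrom_b):
        truth_b.chrom_lengths[f"chrB{i + 1}"] = offsets[i]
        truth_b.high_intervals[f"chrB{i + 1}"].sort()
        truth_b.low_intervals[f"chrB{i + 1}"].sort()
    genes_b.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    cut_positions = [candidates[i] for i in idx]
    return SyntenySimulation(
        blocks=blocks,
        genes_b=genes_b,
        truth_b=truth_b,
        pairs=pairs,
        cut_positions=cut_positions,
    )
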