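"""Transcriptome maps: gene ordering along chromosomes and running-median smoothing.

A transcriptome map orders the genes of each chromosome by their
midpoint and replaces each gene's expression value with the median of a
fixed-size window of neighbouring genes (39 genes for combined maps, 19
per strand).  Smoothing windows are counted in genes, not base pairs,
so gene-dense and gene-poor chromosomes are smoothed comparably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .core_io import ExpressionTable, GeneRecord

__all__ = [
    "running_median",
    "ChromosomeProfile",
    "TranscriptomeMap",
    "ChromosomeSummary",
    "build_map",
    "build_strand_maps",
    "chromosome_summaries",
    "expression_length_correlation",
]

DEFAULT_WINDOW = 39
DEFAULT_STRAND_WINDOW = 19


def running_median(
    values: Sequence[float] | np.ndarray, window: int, edge_rule: str = "shrink"
) -> np.ndarray:
    """Sliding-window median with odd ``window``, output same length as input.

    Edge rules:

    ``shrink`` (default)
        At position ``i`` use the largest odd window centred on ``i``
        that fits inside the series; the first and last points are
        therefore returned unchanged.
    ``keep``
        Positions where the full window does not fit keep their raw
        value (the classical smoother's "keep" end rule).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("running_median expects a 1-D series")
    if arr.size == 0:
        raise ValueError("running_median: empty series")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if edge_rule not in ("shrink", "keep"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    n = arr.size
    if window == 1:
        return arr.copy()
    k = window // 2
    out = np.empty(n, dtype=float)
    if n >= window:
        out[k : n - k] = np.median(sliding_window_view(arr, window), axis=-1)
        edge_idx: Iterable[int] = list(range(k)) + list(range(n - k, n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        if edge_rule == "keep":
            out[i] = arr[i]
        else:
            ke = min(i, n - 1 - i, k)
            out[i] = np.median(arr[i - ke : i + ke + 1])
    return out


@dataclass
class ChromosomeProfile:
    """One chromosome's ordered genes with raw and smoothed values."""

    chrom: str
    gene_ids: list[str]
    midpoints: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def span(self) -> tuple[int, int]:
        """(first gene start, last gene end) — the analyzed extent of the chromosome."""
        return int(self.starts.min()), int(self.ends.max())


@dataclass
class TranscriptomeMap:
    """Ordered, smoothed expression profiles for each retained chromosome."""

    profiles: dict[str, ChromosomeProfile]
    window: int
    label: str = "combined"
    dropped_genes: int = 0
    excluded_chromosomes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"map window must be odd and >= 3, got {self.window}")

    @property
    def chroms(self) -> list[str]:
        return list(self.profiles)

    @property
    def n_genes(self) -> int:
        return sum(p.n_genes for p in self.profiles.values())

    def all_raw(self) -> np.ndarray:
        return np.concatenate([p.raw for p in self.profiles.values()])

    def all_smoothed(self) -> np.ndarray:
        if any(p.smoothed is None for p in self.profiles.values()):
            raise ValueError("map has not been smoothed")
        return np.concatenate([p.smoothed for p in self.profiles.values()])

    def all_gene_ids(self) -> list[str]:
        return [g for p in self.profiles.values() for g in p.gene_ids]

    def analyzed_length(self) -> int:
        """Total analyzed span: per chromosome, first gene start to last gene end."""
        return sum(p.span[1] - p.span[0] for p in self.profiles.values())


def _order_genes(genes: Iterable[GeneRecord]) -> dict[str, list[GeneRecord]]:
    """Group by chromosome and order by (midpoint, start, gene_id)."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda g: (g.midpoint, g.start, g.gene_id))
    return dict(sorted(by_chrom.items()))


def build_map(
    genes: Sequence[GeneRecord],
    expr: ExpressionTable,
    window: int = DEFAULT_WINDOW,
    value_source: str = "median",
    min_genes: int | None = None,
    edge_rule: str = "shrink",
    allow_empty: bool = False,
    label: str | None = None,
) -> TranscriptomeMap:
    """Build an ordered, running-median-smoothed transcriptome map.

    ``value_source`` is ``"median"`` (per-gene median across tissues) or
    a tissue name.  Chromosomes retaining fewer than ``min_genes``
    (default: the window size) genes with expression are excluded with a
    warning; genes without an expression row are dropped and counted.
    """
    if min_genes is None:
        min_genes = window
    if value_source == "median":
        value_of = expr.summary_by_gene()
        map_label = label or "combined"
    else:
        value_of = expr.value_by_gene(value_source)
        map_label = label or f"tissue:{value_source}"
    dropped = 0
    profiles: dict[str, ChromosomeProfile] = {}
    excluded: list[str] = []
    for chrom, chrom_genes in _order_genes(genes).items():
        kept = [g for g in chrom_genes if g.gene_id in value_of]
        dropped += len(chrom_genes) - len(kept)
        if len(kept) < min_genes:
            excluded.append(chrom)
            warnings.warn(
                f"chromosome {chrom} excluded: {len(kept)} genes < minimum {min_genes}",
                stacklevel=2,
            )
            continue
        raw = np.array([value_of[g.gene_id] for g in kept], dtype=float)
        profiles[chrom] = ChromosomeProfile(
            chrom=chrom,
            gene_ids=[g.gene_id for g in kept],
            midpoints=np.array([g.midpoint for g in kept], dtype=np.int64),
            starts=np.array([g.start for g in kept], dtype=np.int64),
            ends=np.array([g.end for g in kept], dtype=np.int64),
            raw=raw,
            smoothed=running_median(raw, window, edge_rule=edge_rule),
        )
    if not profiles and not allow_empty:
        raise ValueError(
            "no chromosome retained enough genes to build a map "
            f"(minimum {min_genes} per chromosome)"
        )
    return TranscriptomeMap(
        profiles=profiles,
        window=window,
        label=map_label,
        dropped_genes=dropped,
        excluded_chromosomes=excluded,
    )


def build_strand_maps(
    genes: Sequence[GeneRecord],
    expr: ExpressionTable,
    window: int = DEFAULT_STRAND_WINDOW,
    value_source: str = "median",
    min_genes: int | None = None,
    edge_rule: str = "shrink",
) -> tuple[TranscriptomeMap, TranscriptomeMap]:
    """Per-strand maps: the same construction on the + and - gene subsets.

    A strand with no retained chromosome yields an empty map rather than
    an error (a chromosome may legitimately be one-strand-poor).
    """
    out = []
    for strand in ("+", "-"):
        subset = [g for g in genes if g.strand == strand]
        out.append(
            build_map(
                subset,
                expr,
                window=window,
                value_source=value_source,
                min_genes=min_genes,
                edge_rule=edge_rule,
                allow_empty=True,
                label=f"strand:{strand}",
            )
        )
    return out[0], out[1]


@dataclass(slots=True)
class ChromosomeSummary:
    """Per-chromosome length (first gene start to last gene end) and median expression."""

    chrom: str
    length: int
    n_genes: int
    median_expression: float


def chromosome_summaries(tmap: TranscriptomeMap) -> list[ChromosomeSummary]:
    out = []
    for chrom, p in tmap.profiles.items():
        lo, hi = p.span
        out.append(
            ChromosomeSummary(
                chrom=chrom,
                length=hi - lo,
                n_genes=p.n_genes,
                median_expression=float(np.median(p.raw)),
            )
        )
    return out


def expression_length_correlation(
    summaries: Sequence[ChromosomeSummary],
) -> tuple[float, float]:
    """Pearson correlation of per-chromosome median expression against length."""
    if len(summaries) < 3:
        raise ValueError("need at least 3 chromosomes for a correlation")
    lengths = [s.length for s in summaries]
    med = [s.median_expression for s in summaries]
    r, p = stats.pearsonr(lengths, med)
    return float(r), float(p)


def export_map_tsv(tmap: TranscriptomeMap, path) -> None:
    """Write the map as TSV: chrom, gene_id, midpoint, raw, smoothed, label."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write("chrom\tgene_id\tmidpoint\tstart\tend\traw\tsmoothed\tlabel\n")
        for chrom, p in tmap.profiles.items():
            sm = p.smoothed if p.smoothed is not None else [float("nan")] * p.n_genes
            for i in range(p.n_genes):
                fh.write(
                    f"{chrom}\t{p.gene_ids[i]}\t{p.midpoints[i]}\t{p.starts[i]}\t"
                    f"{p.ends[i]}\t{p.raw[i]!r}\t{sm[i]!r}\t{tmap.label}\n"
                )
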