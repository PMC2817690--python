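"""Per-gene genomic feature tracks and their relation to the transcriptome map.

Feature tracks mirror the transcriptome map's gene ordering (midpoint
order per chromosome) so the two can be correlated gene-for-gene.
Supported features:

- ``gene_density``: genes per 100 kb in a window centred on each gene's
  midpoint (clipped and rescaled at chromosome ends);
- ``gc_fraction``: the annotated GC fraction of each gene;
- ``gene_length``: genomic length (end - start);
- ``avg_intron_length``: mean over transcripts of the mean intron length
  within each transcript; missing for intronless genes;
- ``minimal_intron_density``: introns of 50-150 bp per 500 kb around
  each gene (minimal introns mark GC-rich, highly expressed regions).

Comparisons between region classes use the two-sided Wilcoxon rank-sum
test; map-vs-track association uses Spearman rank correlation on the
smoothed series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import GeneRecord
from .maps import TranscriptomeMap, running_median, _order_genes
from .regions import RIDGE, ANTIRIDGE, Region

__all__ = [
    "FeatureTrack",
    "gene_density",
    "avg_intron_length",
    "minimal_intron_density",
    "gene_feature_values",
    "build_feature_track",
    "map_feature_correlation",
    "compare_region_features",
    "CorrelationReport",
    "RegionFeatureReport",
    "align_genes_to_map",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "gene_density",
    "gc_fraction",
    "gene_length",
    "avg_intron_length",
    "minimal_intron_density",
)


@dataclass
class FeatureTrack:
    """A per-gene feature aligned 1:1 with a transcriptome map's ordering."""

    feature_name: str
    gene_ids: dict[str, list[str]]  # chrom -> ordered gene ids
    raw: dict[str, np.ndarray]
    smoothed: dict[str, np.ndarray]

    def all_raw(self) -> np.ndarray:
        return np.concatenate(list(self.raw.values()))

    def all_smoothed(self) -> np.ndarray:
        return np.concatenate(list(self.smoothed.values()))


def align_genes_to_map(genes: Sequence[GeneRecord], tmap: TranscriptomeMap) -> list[GeneRecord]:
    """Restrict a gene list to the genes a map retained (so tracks align)."""
    keep = set(tmap.all_gene_ids())
    return [g for g in genes if g.gene_id in keep]


def avg_intron_length(gene: GeneRecord) -> float | None:
    """Mean over transcripts of the mean intron length; None if no introns.

    Transcripts without introns do not contribute a term (an intronless
    transcript has no intron length to average).
    """
    if not gene.transcript_intron_lengths:
        return None
    per_tx = [float(np.mean(tx)) for tx in gene.transcript_intron_lengths if tx]
    if not per_tx:
        return None
    return float(np.mean(per_tx))


def _n_minimal_introns(gene: GeneRecord, min_bp: int, max_bp: int) -> int:
    if not gene.transcript_intron_lengths:
        return 0
    return sum(
        1
        for tx in gene.transcript_intron_lengths
        for length in tx
        if min_bp <= length <= max_bp
    )


def _windowed_density(
    ordered: Sequence[GeneRecord],
    weights: np.ndarray,
    window_bp: int,
    per_bp: int,
) -> np.ndarray:
    """Sum ``weights`` over genes whose midpoints fall in a window_bp interval
    centred on each gene, clipped to the chromosome's analyzed span and
    rescaled to a per-``per_bp`` rate."""
    mids = np.array([g.midpoint for g in ordered], dtype=np.int64)
    span_lo = min(g.start for g in ordered)
    span_hi = max(g.end for g in ordered)
    half = window_bp / 2.0
    lo = np.maximum(mids - half, span_lo)
    hi = np.minimum(mids + half, span_hi)
    csum = np.concatenate(([0.0], np.cumsum(weights)))
    i0 = np.searchsorted(mids, lo, side="left")
    i1 = np.searchsorted(mids, hi, side="left")
    counts = csum[i1] - csum[i0]
    widths = np.maximum(hi - lo, 1.0)
    return counts * (per_bp / widths)


def _track_from_per_gene(
    genes: Sequence[GeneRecord],
    feature_name: str,
    values_fn,
    smooth_window: int,
) -> FeatureTrack:
    gene_ids: dict[str, list[str]] = {}
    raw: dict[str, np.ndarray] = {}
    smoothed: dict[str, np.ndarray] = {}
    for chrom, ordered in _order_genes(genes).items():
        vals = values_fn(ordered)
        gene_ids[chrom] = [g.gene_id for g in ordered]
        raw[chrom] = vals
        smoothed[chrom] = running_median(vals, min(smooth_window, _odd_floor(len(vals))))
    return FeatureTrack(feature_name, gene_ids, raw, smoothed)


def _odd_floor(n: int) -> int:
    return n if n % 2 == 1 else max(1, n - 1)


def gene_density(
    genes: Sequence[GeneRecord], window_bp: int = 100_000, smooth_window: int = 39
) -> FeatureTrack:
    """Genes per 100 kb around each gene's midpoint, as a smoothed track."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    def values(ordered: Sequence[GeneRecord]) -> np.ndarray:
        w = np.ones(len(ordered))
        return _windowed_density(ordered, w, window_bp, 100_000)

    return _track_from_per_gene(genes, "gene_density", values, smooth_window)


def minimal_intron_density(
    genes: Sequence[GeneRecord],
    min_bp: int = 50,
    max_bp: int = 150,
    window_bp: int = 500_000,
    smooth_window: int = 39,
) -> FeatureTrack:
    """Minimal introns (50-150 bp inclusive) per 500 kb around each gene."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    def values(ordered: Sequence[GeneRecord]) -> np.ndarray:
        w = np.array([_n_minimal_introns(g, min_bp, max_bp) for g in ordered], dtype=float)
        return _windowed_density(ordered, w, window_bp, 500_000)

    return _track_from_per_gene(genes, "minimal_intron_density", values, smooth_window)


def gene_feature_values(genes: Sequence[GeneRecord], feature_name: str) -> np.ndarray:
    """Per-gene values for a feature, in the given gene order (NaN = missing).

    Window-based features (density, minimal-intron density) are computed
    from the corresponding track and mapped back by gene id.
    """
    if feature_name == "gene_length":
        return np.array([g.length for g in genes], dtype=float)
    if feature_name == "gc_fraction":
        return np.array(
            [g.gc_fraction if g.gc_fraction is not None else np.nan for g in genes],
            dtype=float,
        )
    if feature_name == "avg_intron_length":
        return np.array(
            [v if (v := avg_intron_length(g)) is not None else np.nan for g in genes],
            dtype=float,
        )
    if feature_name in ("gene_density", "minimal_intron_density"):
        track = (
            gene_density(genes) if feature_name == "gene_density" else minimal_intron_density(genes)
        )
        lookup: dict[str, float] = {}
        for chrom in track.gene_ids:
            lookup.update(zip(track.gene_ids[chrom], track.raw[chrom].tolist()))
        return np.array([lookup[g.gene_id] for g in genes], dtype=float)
    raise ValueError(f"unknown feature {feature_name!r}; expected one of {FEATURE_NAMES}")


def build_feature_track(
    genes: Sequence[GeneRecord], feature_name: str, smooth_window: int = 39
) -> FeatureTrack:
    """A smoothed track for any named feature, aligned with map ordering."""
    if feature_name == "gene_density":
        return gene_density(genes, smooth_window=smooth_window)
    if feature_name == "minimal_intron_density":
        return minimal_intron_density(genes, smooth_window=smooth_window)

    def values(ordered: Sequence[GeneRecord]) -> np.ndarray:
        per_gene = gene_feature_values(ordered, feature_name)
        # running medians tolerate NaN poorly; interpolate over missing genes
        if np.isnan(per_gene).any():
            idx = np.arange(per_gene.size)
            ok = ~np.isnan(per_gene)
            if ok.sum() == 0:
                return np.zeros_like(per_gene)
            per_gene = np.interp(idx, idx[ok], per_gene[ok])
        return per_gene

    return _track_from_per_gene(genes, feature_name, values, smooth_window)


@dataclass(slots=True)
class CorrelationReport:
    rho: float
    p_value: float
    n: int
    method: str


def map_feature_correlation(
    tmap: TranscriptomeMap,
    track: FeatureTrack,
    method: str = "spearman",
    permutation_p: bool = False,
    n_resamples: int = 9999,
    seed: int | None = None,
) -> CorrelationReport:
    """Correlate smoothed map values with a smoothed feature track.

    Spearman by default (the map values are not normally distributed);
    ``method="pearson"`` is available.  ``permutation_p`` replaces the
    large-sample p-value with a Monte Carlo permutation p (for short
    series where the approximation is doubtful).
    """
    if set(track.raw) != set(tmap.profiles):
        raise ValueError("track and map cover different chromosomes")
    xs, ys = [], []
    for chrom, p in tmap.profiles.items():
        if track.gene_ids[chrom] != p.gene_ids:
            raise ValueError(f"track/map gene orderings differ on {chrom}")
        xs.append(p.smoothed)
        ys.append(track.smoothed[chrom])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if method == "spearman":
        stat_fn = lambda a, b: stats.spearmanr(a, b).statistic  # noqa: E731
    elif method == "pearson":
        stat_fn = lambda a, b: stats.pearsonr(a, b).statistic  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    if permutation_p:
        res = stats.permutation_test(
            (x, y),
            stat_fn,
            permutation_type="pairings",
            n_resamples=n_resamples,
            rng=np.random.default_rng(seed),
        )
        rho, p = float(res.statistic), float(res.pvalue)
    else:
        r = stats.spearmanr(x, y) if method == "spearman" else stats.pearsonr(x, y)
        rho, p = float(r.statistic), float(r.pvalue)
    return CorrelationReport(rho=rho, p_value=p, n=x.size, method=method)


def _region_membership(regions: Sequence[Region]) -> dict[str, dict[str, list[tuple[int, int]]]]:
    out: dict[str, dict[str, list[tuple[int, int]]]] = {RIDGE: {}, ANTIRIDGE: {}}
    for r in regions:
        out[r.kind].setdefault(r.chrom, []).append((r.start, r.end))
    for kind in out:
        for chrom in out[kind]:
            out[kind][chrom].sort()
    return out


def point_in_intervals(pos: int, intervals: Sequence[tuple[int, int]]) -> bool:
    """Half-open membership test against a sorted, non-overlapping interval list."""
    import bisect

    i = bisect.bisect_right([s for s, _ in intervals], pos) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def genes_in_regions(
    genes: Sequence[GeneRecord], regions: Sequence[Region], kind: str
) -> list[GeneRecord]:
    """Genes whose midpoint lies inside a region of the given kind."""
    lookup = _region_membership(regions)[kind]
    return [
        g for g in genes if point_in_intervals(g.midpoint, lookup.get(g.chrom, []))
    ]


@dataclass
class RegionFeatureReport:
    """Wilcoxon rank-sum comparison of a feature between region classes."""

    feature_name: str
    medians: dict[str, float]  # RIDGE / antiRIDGE / genome
    n: dict[str, int]
    statistic: float  # RIDGE vs antiRIDGE rank-sum z statistic
    p_values: dict[str, float] = field(default_factory=dict)


def compare_region_features(
    genes: Sequence[GeneRecord],
    regions: Sequence[Region],
    feature_name: str,
) -> RegionFeatureReport:
    """Compare a feature over RIDGE genes, anti-RIDGE genes and the genome.

    Two-sided Wilcoxon rank-sum tests: RIDGE vs anti-RIDGE, plus each
    class against the whole genome.  Genes with a missing feature value
    (e.g. intronless genes for intron length) are excluded.
    """
    groups = {
        RIDGE: genes_in_regions(genes, regions, RIDGE),
        ANTIRIDGE: genes_in_regions(genes, regions, ANTIRIDGE),
        "genome": list(genes),
    }
    values: dict[str, np.ndarray] = {}
    for name, gs in groups.items():
        v = gene_feature_values(gs, feature_name)
        v = v[~np.isnan(v)]
        if v.size < 2:
            raise ValueError(
                f"group {name!r} has fewer than 2 genes with a {feature_name} value"
            )
        values[name] = v
    stat_ra = stats.ranksums(values[RIDGE], values[ANTIRIDGE])
    p_values = {
        "ridge_vs_antiridge": float(stat_ra.pvalue),
        "ridge_vs_genome": float(
            stats.ranksums(values[RIDGE], values["genome"]).pvalue
        ),
        "antiridge_vs_genome": float(
            stats.ranksums(values[ANTIRIDGE], values["genome"]).pvalue
        ),
    }
    return RegionFeatureReport(
        feature_name=feature_name,
        medians={k: float(np.median(v)) for k, v in values.items()},
        n={k: int(v.size) for k, v in values.items()},
        statistic=float(stat_ra.statistic),
        p_values=p_values,
    )
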