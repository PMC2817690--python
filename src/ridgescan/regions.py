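"""RIDGE / anti-RIDGE calling from a smoothed transcriptome map.

A RIDGE is a maximal run of at least ``min_run`` consecutive genes whose
running-median expression is strictly greater than ``ridge_multiplier``
times the genomic median (the median of all analyzed genes' raw summary
values); an anti-RIDGE is the converse with values strictly below
``antiridge_multiplier`` times the genomic median.  Runs never cross
chromosome boundaries.  A region's genomic span runs from the first
member gene's start to the last member gene's end.

The multipliers may instead be calibrated so each region class covers a
target fraction of the analyzed genome, mirroring the original
threshold choice (each class covering ~10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .maps import TranscriptomeMap

__all__ = [
    "Region",
    "CallerConfig",
    "CalibrationResult",
    "genomic_median",
    "call_regions",
    "coverage",
    "calibrate_multiplier",
    "regions_to_bed",
    "read_regions_bed",
]

RIDGE = "RIDGE"
ANTIRIDGE = "antiRIDGE"


@dataclass(slots=True)
class Region:
    """A called RIDGE or anti-RIDGE interval with its member genes."""

    chrom: str
    start: int
    end: int
    kind: str
    gene_ids: list[str]
    n_genes: int
    mean_smoothed: float
    run_length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region on {self.chrom}: start must be < end")
        if self.kind not in (RIDGE, ANTIRIDGE):
            raise ValueError(f"region kind must be {RIDGE!r} or {ANTIRIDGE!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class CallerConfig:
    """Thresholds for region calling.

    ``ridge_multiplier`` / ``antiridge_multiplier`` scale the genomic
    median; when ``target_coverage`` is set, both multipliers are
    re-derived by calibration and these values are ignored.
    """

    window: int = 39
    min_run: int = 10
    ridge_multiplier: float = 1.19
    antiridge_multiplier: float = 0.78
    target_coverage: float | None = None

    def __post_init__(self) -> None:
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if not 0 < self.antiridge_multiplier < 1 < self.ridge_multiplier:
            raise ValueError(
                "need 0 < antiridge_multiplier < 1 < ridge_multiplier, got "
                f"{self.antiridge_multiplier} / {self.ridge_multiplier}"
            )
        if self.target_coverage is not None and not 0 < self.target_coverage < 1:
            raise ValueError("target_coverage must be in (0, 1)")


def genomic_median(tmap: TranscriptomeMap) -> float:
    """Median of all per-gene raw values across retained chromosomes.

    The reference level for the multiplier thresholds; note it is taken
    over raw (unsmoothed) values.
    """
    if not tmap.profiles:
        raise ValueError("cannot take the genomic median of an empty map")
    return float(np.median(tmap.all_raw()))


def _runs(mask: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as half-open index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def call_regions(tmap: TranscriptomeMap, config: CallerConfig) -> list[Region]:
    """Call RIDGEs and anti-RIDGEs on a smoothed map.

    Strict inequalities at both thresholds: a smoothed value exactly at a
    threshold qualifies for neither region class.
    """
    if any(p.smoothed is None for p in tmap.profiles.values()):
        raise ValueError("call_regions requires a smoothed map")
    if tmap.window != config.window:
        raise ValueError(
            f"map smoothed at window {tmap.window} but caller configured for {config.window}"
        )
    gmed = genomic_median(tmap)
    hi_thr = config.ridge_multiplier * gmed
    lo_thr = config.antiridge_multiplier * gmed
    regions: list[Region] = []
    for chrom, p in tmap.profiles.items():
        sm = p.smoothed
        for kind, mask in ((RIDGE, sm > hi_thr), (ANTIRIDGE, sm < lo_thr)):
            kind_regions = [
                Region(
                    chrom=chrom,
                    start=int(p.starts[s:e].min()),
                    end=int(p.ends[s:e].max()),
                    kind=kind,
                    gene_ids=p.gene_ids[s:e],
                    n_genes=e - s,
                    mean_smoothed=float(sm[s:e].mean()),
                    run_length=e - s,
                )
                for s, e in _runs(mask, config.min_run)
            ]
            _clip_span_overlaps(kind_regions)
            regions.extend(kind_regions)
    return regions


def _clip_span_overlaps(regions: list[Region]) -> None:
    """Separate same-kind spans that overlap through long straggler genes.

    Runs are disjoint in gene-index space, but a long gene's extent in
    one run can reach past the start of the next run.  The earlier
    region's span is clipped at the later region's start so that
    coverage stays additive; member genes always keep their midpoint
    inside the clipped span.
    """
    for prev, cur in zip(regions, regions[1:]):
        if cur.start < prev.end:
            if cur.start > prev.start:
                prev.end = cur.start
            else:  # nested span (pathological annotation): shrink the later one
                cur.start = min(prev.end, cur.end - 1)


def coverage(regions: Sequence[Region], genome_length: int) -> float:
    """Fraction of the analyzed genome covered by a set of same-kind regions."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault((r.chrom, r.kind), []).append(r)  # type: ignore[arg-type]
    for key, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise AssertionError(
                    f"overlapping {key[1]} regions on {key[0]}: caller bug"
                )
    return sum(r.length for r in regions) / genome_length


@dataclass(slots=True)
class CalibrationResult:
    multiplier: float
    achieved_coverage: float
    target_coverage: float
    warning: bool  # target not attainable within tolerance (coverage is step-valued)


def calibrate_multiplier(
    tmap: TranscriptomeMap,
    kind: str,
    target_coverage: float,
    config: CallerConfig | None = None,
    n_iter: int = 60,
    tolerance: float = 0.01,
) -> CalibrationResult:
    """Bisect the multiplier so ``kind`` regions cover ~``target_coverage``.

    Coverage is non-increasing in the RIDGE multiplier and non-decreasing
    in the anti-RIDGE multiplier; the search brackets [1, 3] and [0.1, 1]
    respectively and returns the visited multiplier whose achieved
    coverage is closest to the target.  Deterministic given the map; sets
    ``warning`` when the discreteness of coverage leaves the best
    achievable value more than ``tolerance`` from the target.
    """
    if kind not in (RIDGE, ANTIRIDGE):
        raise ValueError(f"kind must be {RIDGE!r} or {ANTIRIDGE!r}")
    if not 0 < target_coverage < 1:
        raise ValueError("target_coverage must be in (0, 1)")
    base = config or CallerConfig()
    genome_length = tmap.analyzed_length()

    def coverage_at(mult: float) -> float:
        if kind == RIDGE:
            cfg = CallerConfig(base.window, base.min_run, mult, base.antiridge_multiplier)
        else:
            cfg = CallerConfig(base.window, base.min_run, base.ridge_multiplier, mult)
        regs = [r for r in call_regions(tmap, cfg) if r.kind == kind]
        return coverage(regs, genome_length)

    lo, hi = (1.0 + 1e-9, 3.0) if kind == RIDGE else (0.1, 1.0 - 1e-9)
    visited: list[tuple[float, float]] = []
    for mult in (lo, hi):
        visited.append((mult, coverage_at(mult)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        cov = coverage_at(mid)
        visited.append((mid, cov))
        # RIDGE: coverage decreases with multiplier; antiRIDGE: increases.
        too_high = cov > target_coverage if kind == RIDGE else cov < target_coverage
        if too_high:
            lo = mid
        else:
            hi = mid
    best_mult, best_cov = min(visited, key=lambda mc: abs(mc[1] - target_coverage))
    return CalibrationResult(
        multiplier=best_mult,
        achieved_coverage=best_cov,
        target_coverage=target_coverage,
        warning=abs(best_cov - target_coverage) > tolerance,
    )


def resolve_config(tmap: TranscriptomeMap, config: CallerConfig) -> CallerConfig:
    """Return a concrete config: calibrate both multipliers if a target is set."""
    if config.target_coverage is None:
        return config
    ridge = calibrate_multiplier(tmap, RIDGE, config.target_coverage, config)
    anti = calibrate_multiplier(tmap, ANTIRIDGE, config.target_coverage, config)
    return CallerConfig(
        window=config.window,
        min_run=config.min_run,
        ridge_multiplier=ridge.multiplier,
        antiridge_multiplier=anti.multiplier,
    )


# ---------------------------------------------------------------------------
# BED-style serialization (0-based half-open, BED6 plus member columns)
# ---------------------------------------------------------------------------


def regions_to_bed(regions: Sequence[Region], path) -> None:
    """Write regions as BED6+3: name = kind, score = mean smoothed value.

    The three extra columns (n_genes, run_length, comma-joined member
    gene ids) make the write/read round trip exact; a plain-BED consumer
    can ignore them.
    """
    from pathlib import Path

    with Path(path).open("w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.kind}\t{r.mean_smoothed!r}\t.\t"
                f"{r.n_genes}\t{r.run_length}\t{','.join(r.gene_ids)}\n"
            )


def read_regions_bed(path) -> list[Region]:
    from pathlib import Path

    regions = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            gene_ids = f[8].split(",") if len(f) > 8 and f[8] else []
            regions.append(
                Region(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    kind=f[3],
                    gene_ids=gene_ids,
                    n_genes=int(f[6]) if len(f) > 6 else len(gene_ids),
                    mean_smoothed=float(f[4]),
                    run_length=int(f[7]) if len(f) > 7 else len(gene_ids),
                )
            )
    return regions
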