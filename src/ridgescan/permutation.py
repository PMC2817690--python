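"""Permutation null for the number of called regions.

The observed RIDGE count is compared against the counts obtained when
per-gene expression values are randomly reassigned to the fixed gene
positions genome-wide (equivalent, under exchangeability, to permuting
gene locations).  Thresholds are held fixed across replicates: if the
caller configuration asks for coverage calibration, the calibration is
performed once on the observed map and the resulting multipliers are
reused for every replicate — re-calibrating per replicate would pin the
null coverage to the target and destroy the test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import ExpressionTable, GeneRecord
from .maps import TranscriptomeMap, build_map, running_median
from .regions import RIDGE, ANTIRIDGE, CallerConfig, genomic_median, resolve_config, _runs

__all__ = ["PermutationResult", "permute_and_count", "count_regions_from_values"]


@dataclass
class PermutationResult:
    """Observed region count against its permutation null distribution."""

    observed_count: int
    null_counts: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    kind: str = RIDGE
    conservative: bool = False

    def __post_init__(self) -> None:
        self.null_counts = np.asarray(self.null_counts, dtype=int)
        if self.null_counts.size != self.n_perm:
            raise ValueError("null_counts length must equal n_perm")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def count_regions_from_values(
    chrom_values: Sequence[np.ndarray],
    window: int,
    threshold: float,
    min_run: int,
    kind: str = RIDGE,
    edge_rule: str = "shrink",
) -> int:
    """Count qualifying runs after smoothing each chromosome's value series.

    The fast inner loop of the permutation test; shares the run-finding
    core with :func:`ridgescan.regions.call_regions`.
    """
    count = 0
    for vals in chrom_values:
        sm = running_median(vals, window, edge_rule=edge_rule)
        mask = sm > threshold if kind == RIDGE else sm < threshold
        count += len(_runs(mask, min_run))
    return count


def permute_and_count(
    genes: Sequence[GeneRecord],
    expr: ExpressionTable,
    config: CallerConfig,
    n_perm: int,
    seed: int,
    kind: str = RIDGE,
    conservative: bool = False,
    value_source: str = "median",
    edge_rule: str = "shrink",
) -> PermutationResult:
    """Permutation test of the observed region count.

    For each of ``n_perm`` replicates the multiset of per-gene values is
    shuffled over the fixed gene positions genome-wide, the maps are
    re-smoothed and regions re-called at the fixed thresholds, and the
    region count recorded.  ``p_value`` is the fraction of null counts
    strictly greater than the observed count (``conservative`` switches
    to the (k+1)/(n+1) estimator).  Bit-reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if kind not in (RIDGE, ANTIRIDGE):
        raise ValueError(f"kind must be {RIDGE!r} or {ANTIRIDGE!r}")
    tmap = build_map(genes, expr, window=config.window, value_source=value_source,
                     edge_rule=edge_rule)
    fixed = resolve_config(tmap, config)
    gmed = genomic_median(tmap)  # invariant under value permutation
    mult = fixed.ridge_multiplier if kind == RIDGE else fixed.antiridge_multiplier
    threshold = mult * gmed

    chrom_raw = [p.raw for p in tmap.profiles.values()]
    sizes = [v.size for v in chrom_raw]
    observed = count_regions_from_values(
        chrom_raw, fixed.window, threshold, fixed.min_run, kind, edge_rule
    )

    pooled = np.concatenate(chrom_raw)
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        shuffled = rng.permutation(pooled)
        per_chrom = [shuffled[bounds[j] : bounds[j + 1]] for j in range(len(sizes))]
        null_counts[i] = count_regions_from_values(
            per_chrom, fixed.window, threshold, fixed.min_run, kind, edge_rule
        )
    exceed = int(np.sum(null_counts > observed))
    p = (exceed + 1) / (n_perm + 1) if conservative else exceed / n_perm
    return PermutationResult(
        observed_count=observed,
        null_counts=null_counts,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        kind=kind,
        conservative=conservative,
    )
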