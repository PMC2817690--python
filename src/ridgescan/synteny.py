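"""Evolutionary breakpoints from synteny blocks, and their relation to regions.

Every synteny block contributes its two ends as evolutionary
breakpoints, each located in both genomes (respecting block
orientation: an inverted block pairs its left end in genome A with the
right end in genome B).  Enrichment of breakpoints within a region set
is tested with a one-degree-of-freedom chi-square goodness-of-fit
against the fraction of the genome the regions cover.  Breakpoints can
also be classified cross-species (RIDGE-to-RIDGE etc.), and 1-to-1
homolog pairs can be scored for joint RIDGE membership in both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import GeneRecord, HomologPair, SyntenyBlock, validate_homolog_pairs
from .features import _region_membership, point_in_intervals
from .regions import RIDGE, ANTIRIDGE, Region

__all__ = [
    "BreakPoint",
    "EnrichmentReport",
    "CrossSpeciesReport",
    "HomologOverlapReport",
    "blocks_to_breakpoints",
    "breakpoint_enrichment",
    "classify_cross_species",
    "homolog_region_overlap",
]


@dataclass(slots=True)
class BreakPoint:
    """One end of a synteny block, located in both genomes."""

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    source_block: str
    which_end: str  # 'left' / 'right', in genome-A orientation


def blocks_to_breakpoints(blocks: Sequence[SyntenyBlock]) -> list[BreakPoint]:
    """Two breakpoints per block — its two ends.

    For a ``+`` block the A-left end pairs with the B-left end; for a
    ``-`` (inverted) block the A-left end pairs with the B-right end.
    """
    out: list[BreakPoint] = []
    for b in blocks:
        if b.orientation == "+":
            pairs = ((b.start_a, b.start_b, "left"), (b.end_a, b.end_b, "right"))
        else:
            pairs = ((b.start_a, b.end_b, "left"), (b.end_a, b.start_b, "right"))
        for pos_a, pos_b, which in pairs:
            out.append(
                BreakPoint(
                    chrom_a=b.chrom_a,
                    pos_a=pos_a,
                    chrom_b=b.chrom_b,
                    pos_b=pos_b,
                    source_block=b.block_id,
                    which_end=which,
                )
            )
    return out


@dataclass(slots=True)
class EnrichmentReport:
    """Chi-square test of breakpoint counts inside vs outside a region set."""

    n_total: int
    n_in_regions: int
    region_fraction: float
    expected: float
    chi_square: float
    p_value: float
    direction: str  # 'enriched' / 'depleted'


def _chi_square_gof(observed_in: int, n_total: int, fraction: float) -> tuple[float, float]:
    expected = np.array([n_total * fraction, n_total * (1.0 - fraction)])
    observed = np.array([observed_in, n_total - observed_in])
    chi2, p = stats.chisquare(f_obs=observed, f_exp=expected)
    return float(chi2), float(p)


def breakpoint_enrichment(
    breakpoints: Sequence[BreakPoint],
    regions: Sequence[Region],
    genome_length: int,
    genome: str = "a",
) -> EnrichmentReport:
    """Are breakpoints over- or under-represented inside a set of regions?

    ``regions`` must all be one kind; the null expectation is that
    breakpoints fall inside with probability equal to the fraction of
    the genome the regions cover.  ``genome`` selects which side of each
    breakpoint ("a" or "b") is tested.
    """
    kinds = {r.kind for r in regions}
    if len(kinds) != 1:
        raise ValueError("breakpoint_enrichment requires regions of a single kind")
    kind = kinds.pop()
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    frac = sum(r.length for r in regions) / genome_length
    if frac <= 0.0 or frac >= 1.0:
        raise ValueError(f"degenerate region fraction {frac}: cannot form a null")
    lookup = _region_membership(regions)[kind]
    if genome == "a":
        inside = sum(
            point_in_intervals(bp.pos_a, lookup.get(bp.chrom_a, [])) for bp in breakpoints
        )
    elif genome == "b":
        inside = sum(
            point_in_intervals(bp.pos_b, lookup.get(bp.chrom_b, [])) for bp in breakpoints
        )
    else:
        raise ValueError("genome must be 'a' or 'b'")
    n = len(breakpoints)
    chi2, p = _chi_square_gof(inside, n, frac)
    return EnrichmentReport(
        n_total=n,
        n_in_regions=int(inside),
        region_fraction=frac,
        expected=n * frac,
        chi_square=chi2,
        p_value=p,
        direction="enriched" if inside >= n * frac else "depleted",
    )


@dataclass
class CrossSpeciesReport:
    """Cross-species labelling of breakpoints by region membership on both sides."""

    counts: dict[tuple[str, str], int]  # (label_a, label_b) -> count
    n_total: int
    ridge_to_ridge: int
    antiridge_to_antiridge: int
    ridge_chi_square: float
    ridge_p_value: float
    ridge_expected: float
    antiridge_chi_square: float
    antiridge_p_value: float
    antiridge_expected: float


def _label(pos: int, chrom: str, membership) -> str:
    if point_in_intervals(pos, membership[RIDGE].get(chrom, [])):
        return RIDGE
    if point_in_intervals(pos, membership[ANTIRIDGE].get(chrom, [])):
        return ANTIRIDGE
    return "none"


def classify_cross_species(
    breakpoints: Sequence[BreakPoint],
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
) -> CrossSpeciesReport:
    """Label each breakpoint by region membership in both genomes.

    A RIDGE-to-RIDGE breakpoint lies inside a RIDGE in genome A and its
    partner position lies inside a RIDGE in genome B.  The chi-square
    compares the joint count against the independence expectation
    ``n_total * fracA * fracB``, where the fractions are the empirical
    marginal membership rates.
    """
    if regions_a is None or regions_b is None:
        raise ValueError("both region sets are required")
    mem_a = _region_membership(regions_a)
    mem_b = _region_membership(regions_b)
    counts: dict[tuple[str, str], int] = {}
    for bp in breakpoints:
        key = (_label(bp.pos_a, bp.chrom_a, mem_a), _label(bp.pos_b, bp.chrom_b, mem_b))
        counts[key] = counts.get(key, 0) + 1
    n = len(breakpoints)

    def joint_test(kind: str) -> tuple[int, float, float, float]:
        observed = counts.get((kind, kind), 0)
        frac_a = sum(c for (la, _), c in counts.items() if la == kind) / n
        frac_b = sum(c for (_, lb), c in counts.items() if lb == kind) / n
        expected = n * frac_a * frac_b
        if expected <= 0 or expected >= n:
            return observed, float("nan"), float("nan"), expected
        chi2, p = _chi_square_gof(observed, n, frac_a * frac_b)
        return observed, chi2, p, expected

    r2r, r_chi2, r_p, r_exp = joint_test(RIDGE)
    a2a, a_chi2, a_p, a_exp = joint_test(ANTIRIDGE)
    return CrossSpeciesReport(
        counts=counts,
        n_total=n,
        ridge_to_ridge=r2r,
        antiridge_to_antiridge=a2a,
        ridge_chi_square=r_chi2,
        ridge_p_value=r_p,
        ridge_expected=r_exp,
        antiridge_chi_square=a_chi2,
        antiridge_p_value=a_p,
        antiridge_expected=a_exp,
    )


@dataclass
class HomologOverlapReport:
    """Joint RIDGE membership of 1-to-1 homolog pairs across two genomes."""

    n_pairs: int
    n_in_a_ridges: int
    n_also_in_b_ridges: int
    percent_conserved: float | None  # None when no pair falls in an A RIDGE
    b_ridge_gene_fraction: float
    expected: float
    chi_square: float
    p_value: float
    zero_denominator: bool = False


def homolog_region_overlap(
    pairs: Sequence[HomologPair],
    regions_a: Sequence[Region],
    regions_b: Sequence[Region],
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    membership: str = "midpoint",
) -> HomologOverlapReport:
    """Of homolog pairs whose A gene sits in an A-RIDGE, how many also sit
    in a B-RIDGE?

    Gene-in-region membership uses the gene midpoint by default
    (consistent with map ordering); ``membership`` may also be
    ``"full"`` (gene entirely inside a region) or ``"any"`` (any
    overlap).  The chi-square compares the joint count against the
    fraction of all genome-B genes located in B-RIDGEs.
    """
    validate_homolog_pairs(pairs)
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_b = {g.gene_id: g for g in genes_b}
    unknown = [p.gene_id_a for p in pairs if p.gene_id_a not in by_id_a]
    unknown += [p.gene_id_b for p in pairs if p.gene_id_b not in by_id_b]
    if unknown:
        raise KeyError(f"homolog pair gene ids missing from annotation: {unknown[:10]}")
    mem_a = _region_membership(regions_a)[RIDGE]
    mem_b = _region_membership(regions_b)[RIDGE]

    def in_ridge(g: GeneRecord, lookup) -> bool:
        intervals = lookup.get(g.chrom, [])
        if membership == "midpoint":
            return point_in_intervals(g.midpoint, intervals)
        if membership == "full":
            return any(s <= g.start and g.end <= e for s, e in intervals)
        if membership == "any":
            return any(s < g.end and g.start < e for s, e in intervals)
        raise ValueError(f"unknown membership rule {membership!r}")

    in_a = [p for p in pairs if in_ridge(by_id_a[p.gene_id_a], mem_a)]
    both = [p for p in in_a if in_ridge(by_id_b[p.gene_id_b], mem_b)]
    frac_b = (
        sum(in_ridge(g, mem_b) for g in genes_b) / len(genes_b) if genes_b else 0.0
    )
    if not in_a:
        return HomologOverlapReport(
            n_pairs=len(pairs),
            n_in_a_ridges=0,
            n_also_in_b_ridges=0,
            percent_conserved=None,
            b_ridge_gene_fraction=frac_b,
            expected=0.0,
            chi_square=float("nan"),
            p_value=float("nan"),
            zero_denominator=True,
        )
    if 0.0 < frac_b < 1.0:
        chi2, p = _chi_square_gof(len(both), len(in_a), frac_b)
    else:
        chi2, p = float("nan"), float("nan")
    return HomologOverlapReport(
        n_pairs=len(pairs),
        n_in_a_ridges=len(in_a),
        n_also_in_b_ridges=len(both),
        percent_conserved=100.0 * len(both) / len(in_a),
        b_ridge_gene_fraction=frac_b,
        expected=len(in_a) * frac_b,
        chi_square=chi2,
        p_value=p,
    )
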