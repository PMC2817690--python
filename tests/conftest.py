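"""Shared fixtures: small simulated genomes with known planted structure."""

from __future__ import annotations

import pytest

import ridgescan as rs


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (~5,000 genes, 10 chromosomes)."""
    cfg = rs.SimulationConfig(seed=1)
    genes, truth = rs.simulate_genome(cfg)
    expr = rs.simulate_expression(genes, truth, cfg)
    return cfg, genes, truth, expr


@pytest.fixture(scope="session")
def small_sim():
    """A compact genome (~1,300 genes on 4 chromosomes) for fast checks."""
    cfg = rs.SimulationConfig(
        seed=3,
        n_chromosomes=4,
        chrom_length_min=8_000_000,
        chrom_length_max=20_000_000,
    )
    genes, truth = rs.simulate_genome(cfg)
    expr = rs.simulate_expression(genes, truth, cfg)
    return cfg, genes, truth, expr


@pytest.fixture(scope="session")
def default_map(default_sim):
    _, genes, _, expr = default_sim
    return rs.build_map(genes, expr)


def bp_jaccard(regions, intervals) -> float:
    """Base-pair Jaccard between called regions and planted truth intervals."""
    inter = 0
    called = 0
    planted = sum(e - s for iv in intervals.values() for s, e in iv)
    for r in regions:
        called += r.length
        for s, e in intervals.get(r.chrom, []):
            inter += max(0, min(e, r.end) - max(s, r.start))
    union = called + planted - inter
    return inter / union if union else 0.0
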