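"""Feature tracks, map-track correlation and region-wise rank-sum comparisons."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

import ridgescan as rs
from ridgescan.features import (
    FeatureTrack,
    _n_minimal_introns,
    gene_feature_values,
    genes_in_regions,
)


def g(gene_id, chrom, start, end, strand="+", gc=None, introns=None):
    return rs.GeneRecord(gene_id, chrom, start, end, strand, gc, introns)


class TestGeneDensity:
    def test_five_clustered_genes_central_query(self):
        # cluster of 5 midpoints inside one unclipped 100-kb window
        genes = [
            g("f0", "chr1", 0, 100),
            g("c1", "chr1", 179_950, 180_050),
            g("c2", "chr1", 189_950, 190_050),
            g("c3", "chr1", 199_950, 200_050),
            g("c4", "chr1", 209_950, 210_050),
            g("c5", "chr1", 219_950, 220_050),
            g("f1", "chr1", 399_950, 400_050),
        ]
        track = rs.gene_density(genes, smooth_window=1)
        vals = dict(zip(track.gene_ids["chr1"], track.raw["chr1"]))
        assert vals["c3"] == pytest.approx(5.0)

    def test_isolated_gene_density_one(self):
        genes = [
            g("f0", "chr1", 0, 100),
            g("iso", "chr1", 199_950, 200_050),
            g("f1", "chr1", 399_950, 400_050),
        ]
        track = rs.gene_density(genes, smooth_window=1)
        vals = dict(zip(track.gene_ids["chr1"], track.raw["chr1"]))
        assert vals["iso"] == pytest.approx(1.0)

    def test_clipped_window_rescaled(self):
        # query gene midpoint 10 kb from the chromosome start: 60-kb window,
        # one midpoint inside, rescaled by 100/60
        genes = [
            g("q", "chr1", 0, 20_000),  # midpoint 10_000, defines span start 0
            g("far", "chr1", 99_000, 101_000),
        ]
        track = rs.gene_density(genes, smooth_window=1)
        vals = dict(zip(track.gene_ids["chr1"], track.raw["chr1"]))
        assert vals["q"] == pytest.approx(1 * 100 / 60)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            rs.gene_density([g("a", "chr1", 0, 10)], window_bp=0)

    def test_track_invariant_to_input_row_order(self, small_sim):
        _, genes, _, _ = small_sim
        rng = np.random.default_rng(1)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        t1 = rs.gene_density(genes)
        t2 = rs.gene_density(shuffled)
        for chrom in t1.raw:
            assert t1.gene_ids[chrom] == t2.gene_ids[chrom]
            np.testing.assert_array_equal(t1.raw[chrom], t2.raw[chrom])

    def test_density_integrates_back_to_gene_count(self):
        # gene-dense uniform genome: mean density x span recovers the gene
        # count within 10% (each window also counts its own query gene, so
        # the genome must hold many genes per window for this to integrate)
        rng = np.random.default_rng(8)
        span = 20_000_000
        n = 4000
        starts = np.sort(rng.integers(0, span, n))
        genes = [g(f"u{i}", "chr1", int(s), int(s) + 500) for i, s in enumerate(starts)]
        track = rs.gene_density(genes, smooth_window=1)
        mean_density = track.raw["chr1"].mean()  # genes per 100 kb
        est_count = mean_density * (span / 100_000)
        assert abs(est_count - n) / n < 0.10


class TestIntronFeatures:
    def test_avg_intron_two_level_average(self):
        gene = g("a", "chr1", 0, 1000, introns=[[100, 200], [300]])
        assert rs.avg_intron_length(gene) == 225.0

    def test_intronless_gene_missing(self):
        assert rs.avg_intron_length(g("a", "chr1", 0, 1000)) is None
        assert rs.avg_intron_length(g("a", "chr1", 0, 1000, introns=[])) is None

    def test_single_transcript(self):
        assert rs.avg_intron_length(g("a", "chr1", 0, 1000, introns=[[50, 150]])) == 100.0

    def test_minimal_intron_bounds_inclusive(self):
        gene = g("a", "chr1", 0, 1000, introns=[[49, 50, 150, 151]])
        assert _n_minimal_introns(gene, 50, 150) == 2

    def test_no_introns_gives_all_zero_track(self):
        genes = [g(f"a{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(10)]
        track = rs.minimal_intron_density(genes, smooth_window=1)
        np.testing.assert_array_equal(track.raw["chr1"], 0.0)

    def test_clustered_short_introns_elevate_track(self):
        genes = []
        for i in range(60):
            short = 20 <= i < 40  # planted cluster of minimal introns
            introns = [[100, 100, 100]] if short else [[1000, 2000]]
            genes.append(g(f"a{i}", "chr1", i * 50_000, i * 50_000 + 2000, introns=introns))
        track = rs.minimal_intron_density(genes, smooth_window=5)
        raw = track.raw["chr1"]
        assert raw[25:35].mean() > raw[:10].mean()


class TestMapFeatureCorrelation:
    def _map_and_identity_track(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(7, 0.5, n)
        genes = [g(f"m{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(n)]
        expr = rs.ExpressionTable([x.gene_id for x in genes], ["t"], vals[:, None])
        tmap = rs.build_map(genes, expr, window=3)
        track = FeatureTrack(
            "identity",
            gene_ids={"chr1": tmap.profiles["chr1"].gene_ids},
            raw={"chr1": tmap.profiles["chr1"].raw.copy()},
            smoothed={"chr1": tmap.profiles["chr1"].smoothed.copy()},
        )
        return tmap, track

    def test_track_equal_to_map_gives_rho_one(self):
        tmap, track = self._map_and_identity_track()
        rep = rs.map_feature_correlation(tmap, track)
        assert rep.rho == pytest.approx(1.0)

    def test_negated_track_gives_rho_minus_one(self):
        tmap, track = self._map_and_identity_track()
        track.smoothed["chr1"] = -track.smoothed["chr1"]
        rep = rs.map_feature_correlation(tmap, track)
        assert rep.rho == pytest.approx(-1.0)

    def test_independent_tracks_have_small_rho(self):
        exceed = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            n = 2000
            vals = rng.normal(7, 0.5, n)
            genes = [g(f"m{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(n)]
            expr = rs.ExpressionTable([x.gene_id for x in genes], ["t"], vals[:, None])
            tmap = rs.build_map(genes, expr, window=3)
            indep = rng.normal(0, 1, n)
            track = FeatureTrack(
                "noise",
                gene_ids={"chr1": tmap.profiles["chr1"].gene_ids},
                raw={"chr1": indep},
                smoothed={"chr1": indep},
            )
            if abs(rs.map_feature_correlation(tmap, track).rho) >= 0.1:
                exceed += 1
        assert exceed <= 1

    def test_length_mismatch_is_error(self):
        tmap, track = self._map_and_identity_track()
        track.gene_ids["chr1"] = track.gene_ids["chr1"][:-1]
        track.smoothed["chr1"] = track.smoothed["chr1"][:-1]
        with pytest.raises(ValueError):
            rs.map_feature_correlation(tmap, track)

    def test_permutation_p_close_to_asymptotic(self):
        tmap, track = self._map_and_identity_track(n=60, seed=3)
        track.smoothed["chr1"] = np.random.default_rng(4).normal(0, 1, 60)
        a = rs.map_feature_correlation(tmap, track)
        b = rs.map_feature_correlation(tmap, track, permutation_p=True, seed=0)
        assert abs(a.p_value - b.p_value) < 0.15


def brute_force_ranksum_z(x, y):
    """Independent oracle: rank-sum W of x by explicit midranks, then the
    normal z statistic (n1 n2 <= 8 keeps the enumeration honest)."""
    combined = list(x) + list(y)
    order = sorted(range(len(combined)), key=lambda i: combined[i])
    ranks = [0.0] * len(combined)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and combined[order[j + 1]] == combined[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = midrank
        i = j + 1
    w = sum(ranks[: len(x)])
    n1, n2 = len(x), len(y)
    mean = n1 * (n1 + n2 + 1) / 2
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
    return (w - mean) / sd


class TestCompareRegionFeatures:
    def _regions_and_genes(self, ridge_lengths, anti_lengths):
        genes, regions = [], []
        pos = 0
        for i, length in enumerate(ridge_lengths):
            genes.append(g(f"r{i}", "chr1", pos, pos + length, gc=0.5))
            pos += length + 10_000
        regions.append(rs.Region("chr1", 0, pos, rs.RIDGE, [x.gene_id for x in genes], len(genes), 9.0, len(genes)))
        anti_start = pos + 50_000
        pos = anti_start
        anti_genes = []
        for i, length in enumerate(anti_lengths):
            gene = g(f"a{i}", "chr1", pos, pos + length, gc=0.4)
            genes.append(gene)
            anti_genes.append(gene)
            pos += length + 10_000
        regions.append(
            rs.Region("chr1", anti_start, pos, rs.ANTIRIDGE,
                      [x.gene_id for x in anti_genes], len(anti_genes), 5.0, len(anti_genes))
        )
        return genes, regions

    def test_identical_distributions_give_p_near_one(self):
        genes, regions = self._regions_and_genes([1000] * 10, [1000] * 10)
        rep = rs.compare_region_features(genes, regions, "gene_length")
        assert rep.p_values["ridge_vs_antiridge"] > 0.9
        assert rep.medians[rs.RIDGE] == rep.medians[rs.ANTIRIDGE]

    def test_planted_shorter_ridge_genes_detected(self):
        rng = np.random.default_rng(0)
        ridge_lengths = rng.integers(500, 2000, 200).tolist()
        anti_lengths = rng.integers(5000, 20000, 200).tolist()
        genes, regions = self._regions_and_genes(ridge_lengths, anti_lengths)
        rep = rs.compare_region_features(genes, regions, "gene_length")
        assert rep.medians[rs.RIDGE] < rep.medians[rs.ANTIRIDGE]
        assert rep.p_values["ridge_vs_antiridge"] < 0.01

    def test_statistic_matches_brute_force_ranksum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(2, 9, 2)
            x = rng.integers(0, 10, n1).astype(float)
            y = rng.integers(0, 10, n2).astype(float)
            z_oracle = brute_force_ranksum_z(x, y)
            z_scipy = stats.ranksums(x, y).statistic
            assert z_scipy == pytest.approx(z_oracle, abs=1e-12)

    def test_group_with_too_few_genes_names_the_group(self):
        genes, regions = self._regions_and_genes([1000] * 10, [1000])
        with pytest.raises(ValueError, match="antiRIDGE"):
            rs.compare_region_features(genes, regions, "gene_length")

    def test_intronless_genes_excluded_not_zero(self):
        genes, regions = self._regions_and_genes([1000] * 5, [1000] * 5)
        # give introns only to some genes; missing ones must not enter as 0
        for i, gene in enumerate(genes):
            if i % 2 == 0:
                gene.transcript_intron_lengths = [[500]]
        rep = rs.compare_region_features(genes, regions, "avg_intron_length")
        assert rep.n[rs.RIDGE] == 3
        assert rep.medians[rs.RIDGE] == 500.0


class TestMembership:
    def test_midpoint_membership(self):
        region = rs.Region("chr1", 100, 200, rs.RIDGE, [], 0, 9.0, 1)
        inside = g("in", "chr1", 120, 180)
        edge = g("edge", "chr1", 180, 220)  # midpoint 200, half-open: outside
        out = g("out", "chr1", 300, 400)
        got = genes_in_regions([inside, edge, out], [region], rs.RIDGE)
        assert [x.gene_id for x in got] == ["in"]
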