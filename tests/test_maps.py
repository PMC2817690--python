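"""Running-median smoothing and transcriptome-map construction."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ridgescan as rs
from ridgescan.maps import export_map_tsv


def brute_force_running_median(values, window):
    """Independent oracle: per-position sort-and-middle with shrinking
    symmetric edge windows."""
    n = len(values)
    k = window // 2
    out = []
    for i in range(n):
        ke = min(i, n - 1 - i, k)
        win = sorted(values[i - ke : i + ke + 1])
        m = len(win)
        mid = win[m // 2] if m % 2 else 0.5 * (win[m // 2 - 1] + win[m // 2])
        out.append(mid)
    return out


class TestRunningMedian:
    def test_constant_series_is_fixed_point(self):
        np.testing.assert_array_equal(
            rs.running_median([5, 5, 5, 5, 5], 3), [5, 5, 5, 5, 5]
        )

    def test_hand_computed_window3(self):
        np.testing.assert_array_equal(
            rs.running_median([1, 5, 2, 8, 3], 3), [1, 2, 5, 3, 3]
        )

    def test_window_one_is_identity(self):
        vals = [3.0, 1.0, 4.0, 1.0, 5.0]
        np.testing.assert_array_equal(rs.running_median(vals, 1), vals)

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            rs.running_median([1.0, 2.0], window)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            rs.running_median([], 3)

    def test_keep_edge_rule_preserves_edge_values(self):
        vals = [9.0, 1.0, 2.0, 3.0, 9.0]
        out = rs.running_median(vals, 3, edge_rule="keep")
        assert out[0] == 9.0 and out[-1] == 9.0
        assert out[1] == 2.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=200,
        ),
        half=st.integers(min_value=0, max_value=20),
    )
    def test_matches_brute_force_oracle(self, values, half):
        window = 2 * half + 1
        expected = brute_force_running_median(values, window)
        np.testing.assert_allclose(rs.running_median(values, window), expected)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=100,
        ),
        half=st.integers(min_value=1, max_value=10),
    )
    def test_bounded_by_raw_extremes(self, values, half):
        out = rs.running_median(values, 2 * half + 1)
        assert out.min() >= min(values) - 1e-12
        assert out.max() <= max(values) + 1e-12


def _toy_genes_expr(n=45, chrom="chr1", value=2.0):
    genes = [
        rs.GeneRecord(f"g{i}", chrom, i * 1000, i * 1000 + 500, "+") for i in range(n)
    ]
    expr = rs.ExpressionTable(
        gene_ids=[g.gene_id for g in genes],
        tissue_names=["t1", "t2", "t3"],
        values=np.full((n, 3), value),
    )
    return genes, expr


class TestBuildMap:
    def test_constant_values_give_constant_smoothed_profile(self):
        genes, expr = _toy_genes_expr(39, value=4.0)
        tmap = rs.build_map(genes, expr, window=39)
        np.testing.assert_array_equal(tmap.profiles["chr1"].smoothed, 4.0)

    def test_small_chromosome_excluded_with_warning(self):
        genes, expr = _toy_genes_expr(45)
        extra = [rs.GeneRecord(f"x{i}", "chr2", i * 100, i * 100 + 50, "+") for i in range(5)]
        expr2 = rs.ExpressionTable(
            gene_ids=expr.gene_ids + [g.gene_id for g in extra],
            tissue_names=expr.tissue_names,
            values=np.vstack([expr.values, np.ones((5, 3))]),
        )
        with pytest.warns(UserWarning, match="chr2"):
            tmap = rs.build_map(genes + extra, expr2, window=39)
        assert "chr2" in tmap.excluded_chromosomes
        assert list(tmap.profiles) == ["chr1"]

    def test_invariant_under_input_row_order(self, small_sim):
        cfg, genes, _, expr = small_sim
        tmap1 = rs.build_map(genes, expr, window=11)
        rng = np.random.default_rng(0)
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        tmap2 = rs.build_map(shuffled, expr, window=11)
        assert tmap1.profiles.keys() == tmap2.profiles.keys()
        for chrom in tmap1.profiles:
            assert tmap1.profiles[chrom].gene_ids == tmap2.profiles[chrom].gene_ids
            np.testing.assert_array_equal(
                tmap1.profiles[chrom].smoothed, tmap2.profiles[chrom].smoothed
            )

    def test_gene_order_nondecreasing_in_midpoint(self, default_map):
        for p in default_map.profiles.values():
            assert np.all(np.diff(p.midpoints) >= 0)

    def test_genes_without_expression_dropped_and_counted(self):
        genes, expr = _toy_genes_expr(45)
        extra = rs.GeneRecord("orphan", "chr1", 1, 400, "+")
        tmap = rs.build_map(genes + [extra], expr, window=39)
        assert tmap.dropped_genes == 1
        assert "orphan" not in tmap.profiles["chr1"].gene_ids

    def test_zero_retained_chromosomes_is_error(self):
        genes, expr = _toy_genes_expr(5)
        with pytest.raises(ValueError):
            rs.build_map(genes, expr, window=39)

    def test_export_tsv_has_expected_columns(self, tmp_path, small_sim):
        _, genes, _, expr = small_sim
        tmap = rs.build_map(genes, expr, window=11)
        out = tmp_path / "map.tsv"
        export_map_tsv(tmap, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[:3] == ["chrom", "gene_id", "midpoint"]


class TestStrandMaps:
    def test_single_strand_input_leaves_other_map_empty(self):
        genes, expr = _toy_genes_expr(45)  # all on +
        plus, minus = rs.build_strand_maps(genes, expr, window=19)
        assert plus.n_genes == 45
        assert minus.n_genes == 0

    def test_planted_block_elevates_both_strand_maps(self, default_sim):
        cfg, genes, truth, expr = default_sim
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plus, minus = rs.build_strand_maps(genes, expr, window=19)
        for tmap in (plus, minus):
            gmed = rs.genomic_median(tmap)
            in_block, out_block = [], []
            for chrom, p in tmap.profiles.items():
                ivs = truth.high_intervals.get(chrom, [])
                for mid, sm in zip(p.midpoints, p.smoothed):
                    if any(s <= mid < e for s, e in ivs):
                        in_block.append(sm)
                    else:
                        out_block.append(sm)
            assert np.mean(in_block) > gmed + 0.3 * cfg.high_effect
            assert np.mean(in_block) > np.mean(out_block)


class TestChromosomeSummaries:
    def test_median_and_length(self):
        genes = [
            rs.GeneRecord("a", "chr1", 100, 300, "+"),
            rs.GeneRecord("b", "chr1", 400, 600, "+"),
            rs.GeneRecord("c", "chr1", 700, 900, "+"),
        ]
        expr = rs.ExpressionTable(["a", "b", "c"], ["t"], np.array([[1.0], [2.0], [9.0]]))
        tmap = rs.build_map(genes, expr, window=3)
        (summ,) = rs.chromosome_summaries(tmap)
        assert summ.median_expression == 2.0
        assert summ.length == 800

    def test_planted_small_chromosome_offset_gives_negative_pearson(self):
        # small chromosomes get +1 log2: median expression must fall with length
        rng = np.random.default_rng(42)
        genes, ids, vals = [], [], []
        lengths = [2_000_000, 4_000_000, 8_000_000, 16_000_000, 32_000_000]
        for ci, length in enumerate(lengths, 1):
            n = 40
            starts = np.sort(rng.integers(0, length - 1000, n))
            offset = 1.0 if length < 10_000_000 else 0.0
            for i, s in enumerate(starts):
                gid = f"c{ci}_{i}"
                genes.append(rs.GeneRecord(gid, f"chr{ci}", int(s), int(s) + 900, "+"))
                ids.append(gid)
                vals.append(7.0 + offset + rng.normal(0, 0.2))
        expr = rs.ExpressionTable(ids, ["t"], np.array(vals)[:, None])
        tmap = rs.build_map(genes, expr, window=11)
        r, _ = rs.expression_length_correlation(rs.chromosome_summaries(tmap))
        assert r < -0.5
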