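import numpy as np
import pytest

from conftest import per_base_support, regions_to_base_mask
from sweepscan.data_io import GeneModel
from sweepscan.pooled_het import ScoreTrack
from sweepscan.sweep_calling import (
    CandidateRegion,
    OutlierRule,
    OutlierWindow,
    annotate_genes,
    call_outlier_windows,
    intersect_contexts,
    merge_regions,
)
from sweepscan.windows import WindowGrid


def _track(values, step=10):
    values = np.asarray(values, dtype=float)
    n = len(values)
    grid = WindowGrid(chrom="1", window_size=step, step=step,
                      starts=np.arange(1, step * n, step),
                      ends=np.arange(step, step * n + 1, step), min_snps=0)
    return ScoreTrack(statistic="Z", context="p", grid=grid, values=values,
                      n_snps=np.full(n, 25), standardized=True)


class TestCallOutlierWindows:
    def test_q_selects_single_extreme(self):
        track = _track(np.arange(1, 1001))
        sel = call_outlier_windows(track, OutlierRule("Z", "high", q=0.001))
        assert len(sel) == 1
        assert sel[0].value == 1000

    def test_low_tail_symmetric(self):
        track = _track(np.arange(1, 1001))
        sel = call_outlier_windows(track, OutlierRule("Z", "low", q=0.001))
        assert len(sel) == 1
        assert sel[0].value == 1

    def test_boundary_ties_all_included(self):
        vals = np.arange(1, 1001, dtype=float)
        vals[-5:] = 1000.0
        sel = call_outlier_windows(_track(vals), OutlierRule("Z", "high", q=0.001))
        assert len(sel) == 5

    def test_k_rule(self):
        # q*N = 0.01*250 = 2.5 -> k = 3 most extreme
        track = _track(np.arange(250))
        sel = call_outlier_windows(track, OutlierRule("Z", "high", q=0.01))
        assert len(sel) == 3

    def test_fixed_threshold_elementwise(self):
        vals = [-4.0, -3.5, -3.4, 0.0, 2.0, -5.1]
        sel = call_outlier_windows(_track(vals),
                                   OutlierRule("ZHp", "low", threshold=-3.5))
        assert sorted(w.value for w in sel) == [-5.1, -4.0, -3.5]

    def test_selected_count_at_least_ceil_qn(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.normal(size=500)
            sel = call_outlier_windows(_track(vals), OutlierRule("Z", "high", q=0.01))
            assert len(sel) >= int(np.ceil(0.01 * 500))

    def test_undefined_windows_excluded(self):
        vals = np.array([np.nan, 1.0, 2.0, np.nan, 3.0])
        sel = call_outlier_windows(_track(vals), OutlierRule("Z", "high", q=0.3))
        assert all(not np.isnan(w.value) for w in sel)

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            call_outlier_windows(_track([np.nan, np.nan]),
                                 OutlierRule("Z", "high"))


def _win(start, end, value=1.0, chrom="1"):
    return OutlierWindow(chrom=chrom, start=start, end=end, value=value)


class TestMergeRegions:
    def test_overlapping_merge(self):
        regions = merge_regions([_win(1, 20_000), _win(10_001, 30_000)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 30_000)
        assert regions[0].n_windows == 2

    def test_book_ended_merge(self):
        regions = merge_regions([_win(1, 20_000), _win(20_001, 40_000)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1, 40_000)

    def test_gap_not_merged(self):
        regions = merge_regions([_win(1, 20_000), _win(30_001, 50_000)])
        assert len(regions) == 2

    def test_max_gap(self):
        regions = merge_regions([_win(1, 20_000), _win(30_001, 50_000)],
                                max_gap=10_000)
        assert len(regions) == 1

    def test_peak_score_attained_by_member(self):
        regions = merge_regions([_win(1, 20, 3.0), _win(10, 30, 5.0)],
                                tail="high")
        assert regions[0].peak_score == 5.0
        regions = merge_regions([_win(1, 20, -3.0), _win(10, 30, -5.0)],
                                tail="low")
        assert regions[0].peak_score == -5.0

    def test_idempotent(self):
        wins = [_win(1, 20), _win(15, 40), _win(100, 120)]
        once = merge_regions(wins)
        again = merge_regions(
            [_win(r.start, r.end, r.peak_score) for r in once])
        assert [(r.start, r.end) for r in once] == \
            [(r.start, r.end) for r in again]

    def test_disjoint_sorted_output(self):
        rng = np.random.default_rng(2)
        wins = [_win(int(s), int(s) + 50) for s in rng.integers(1, 1000, 40)]
        regions = merge_regions(wins)
        for r1, r2 in zip(regions, regions[1:]):
            assert r1.end + 1 < r2.start  # disjoint, non-book-ended, sorted


def _region(start, end, chrom="1", method="m", context="c"):
    return CandidateRegion(chrom=chrom, start=start, end=end, method=method,
                           tail="high", peak_score=1.0, n_windows=1,
                           context=context, support=[(method, context)])


class TestIntersectContexts:
    def test_identical_sets_intersection(self):
        a = [_region(10, 50, method="m1")]
        b = [_region(10, 50, method="m2")]
        out = intersect_contexts([a, b], mode="intersection")
        assert len(out) == 1
        assert (out[0].start, out[0].end) == (10, 50)
        assert len(out[0].support) == 2

    def test_partial_overlap(self):
        out = intersect_contexts([[_region(1, 100)], [_region(50, 150)]],
                                 mode="intersection")
        assert [(r.start, r.end) for r in out] == [(50, 100)]

    def test_k_of_n_matches_per_base_oracle(self):
        sets = [
            [_region(1, 60, method="a"), _region(120, 160, method="a")],
            [_region(40, 100, method="b")],
            [_region(50, 140, method="c"), _region(150, 200, method="c")],
        ]
        for k in (1, 2, 3):
            out = intersect_contexts(sets, mode="k_of_n", k=k)
            mask = regions_to_base_mask(out, 1, 200)
            support = per_base_support(sets, 1, 200)
            np.testing.assert_array_equal(mask, support >= k)

    def test_union_superset_of_intersection(self):
        sets = [[_region(1, 60)], [_region(40, 100)], [_region(55, 58)]]
        union = regions_to_base_mask(intersect_contexts(sets, "union"), 1, 200)
        inter = regions_to_base_mask(
            intersect_contexts(sets, "intersection"), 1, 200)
        assert np.all(union[inter])

    def test_k1_is_union_kn_is_intersection(self):
        sets = [[_region(1, 60)], [_region(40, 100)]]
        u1 = regions_to_base_mask(intersect_contexts(sets, "k_of_n", k=1), 1, 200)
        u2 = regions_to_base_mask(intersect_contexts(sets, "union"), 1, 200)
        np.testing.assert_array_equal(u1, u2)
        i1 = regions_to_base_mask(intersect_contexts(sets, "k_of_n", k=2), 1, 200)
        i2 = regions_to_base_mask(intersect_contexts(sets, "intersection"), 1, 200)
        np.testing.assert_array_equal(i1, i2)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            intersect_contexts([], mode="union")


def _gene(start, end, chrom="1", name="g"):
    return GeneModel(gene_id=name, gene_name=name, chrom=chrom,
                     start=start, end=end)


class TestAnnotateGenes:
    def test_overlap(self):
        tbl = annotate_genes([_region(1000, 2000)], [_gene(1500, 3000)])
        assert tbl.iloc[0]["n_genes"] == 1

    def test_adjacent_no_overlap(self):
        tbl = annotate_genes([_region(1000, 2000)], [_gene(2001, 3000)])
        assert tbl.iloc[0]["n_genes"] == 0
        assert tbl.iloc[0]["genes"] == "."

    def test_gene_containing_region_counts(self):
        tbl = annotate_genes([_region(1000, 2000)], [_gene(1, 10_000)])
        assert tbl.iloc[0]["n_genes"] == 1

    def test_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        regions = []
        for _ in range(10):
            s = int(rng.integers(1, 5000))
            regions.append(_region(s, s + int(rng.integers(1, 500))))
        genes = []
        for i in range(20):
            s = int(rng.integers(1, 5000))
            genes.append(_gene(s, s + int(rng.integers(1, 800)), name=f"g{i}"))
        tbl = annotate_genes(regions, genes)
        for row, r in zip(tbl.itertuples(), regions):
            expected = sorted(g.gene_name for g in genes
                              if g.start <= r.end and g.end >= r.start)
            got = sorted(row.genes.split(",")) if row.genes != "." else []
            assert got == expected

    def test_chrom_mismatch_warns(self, caplog):
        with caplog.at_level("WARNING"):
            tbl = annotate_genes([_region(1, 10, chrom="chrX")],
                                 [_gene(1, 10, chrom="1")])
        assert "absent" in caplog.text
        assert tbl.iloc[0]["n_genes"] == 0
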