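import numpy as np
import pytest

from mslchip import (
    BoundRegion,
    CallingParams,
    GeneAnnotation,
    GenomeAssembly,
    GenomeTrack,
    call_bound_regions,
    genes_overlapping_regions,
    threshold_top_percent,
)
from .conftest import random_track_values
from .oracles import call_regions_brute, nearest_rank_cutoff


class TestThreshold:
    def test_top_1p5_percent_of_1_to_1000(self, make_track):
        t = make_track({"c": np.arange(1, 1001, dtype=float)})
        cutoff = threshold_top_percent(t, 1.5)
        assert cutoff == 986.0
        assert int((t.values["c"] >= cutoff).sum()) == 15

    def test_all_equal_values_tie_at_cutoff(self, make_track):
        t = make_track({"c": [7.0] * 50})
        cutoff = threshold_top_percent(t, 1.5)
        assert cutoff == 7.0
        assert int((t.values["c"] >= cutoff).sum()) == 50

    def test_nearest_rank_on_small_sample(self, make_track):
        t = make_track({"c": [1.0, 2.0, 3.0, 4.0]})
        assert threshold_top_percent(t, 50.0) == 3.0

    def test_all_missing_track_rejected(self, make_track):
        t = make_track({"c": [np.nan] * 10})
        with pytest.raises(ValueError, match="no defined"):
            threshold_top_percent(t, 1.5)

    def test_per_chromosome_scope(self, make_track):
        t = make_track({"a": np.arange(100.0), "b": np.arange(100.0, 200.0)})
        cut = threshold_top_percent(t, 10.0, scope="per-chromosome")
        assert cut["a"] == 90.0 and cut["b"] == 190.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sort_and_count_oracle(self, make_track, seed):
        rng = np.random.default_rng(seed)
        vals = random_track_values(rng, 500, missing_frac=0.2)
        t = make_track({"c": vals})
        p = float(rng.uniform(0.5, 30))
        assert threshold_top_percent(t, p) == nearest_rank_cutoff(vals.tolist(), p)


class TestCallRegions:
    def _track(self, vals, step=10):
        asm = GenomeAssembly({"c": len(vals) * step}, step=step)
        return GenomeTrack(asm, {"c": np.asarray(vals, dtype=float)})

    def test_single_run_score_is_mean_of_top_five_consecutive(self):
        vals = np.full(100, np.nan)
        vals[10:40] = np.arange(1.0, 31.0)  # 300 bp run, values 1..30
        t = self._track(vals)
        (region,) = call_bound_regions(t, CallingParams(top_percent=99.9))
        assert (region.start, region.end) == (100, 400)
        assert region.score == pytest.approx(28.0)  # mean of 26..30
        # run covers steps 35..39 -> genomic 350..400, centre 375
        assert region.peak_center == 375
        assert region.n_units == 30

    def test_region_shorter_than_200bp_discarded(self):
        vals = np.full(100, np.nan)
        vals[10:25] = 5.0  # 150 bp above-cutoff run
        t = self._track(vals)
        assert call_bound_regions(t, CallingParams(top_percent=99.9)) == []

    def test_runs_within_200bp_gap_merge(self):
        vals = np.zeros(100)
        vals[10:25] = 5.0  # 150 bp
        vals[40:55] = 5.0  # 150 bp, gap = steps 25..39 = 150 bp
        t = self._track(vals)
        (region,) = call_bound_regions(t, CallingParams(top_percent=30.0))
        assert (region.start, region.end) == (100, 550)
        assert region.n_units == 30

    def test_gap_above_200bp_splits(self):
        vals = np.zeros(200)
        vals[10:40] = 5.0
        vals[61:91] = 5.0  # gap = steps 40..60 = 210 bp
        t = self._track(vals)
        regions = call_bound_regions(t, CallingParams(top_percent=30.0))
        assert len(regions) == 2

    def test_fewer_than_five_units_discarded(self):
        vals = np.zeros(200)
        vals[10] = vals[20] = vals[30] = vals[40] = 5.0  # 4 units, 310 bp span
        t = self._track(vals)
        params = CallingParams(top_percent=2.0, max_gap_bp=200, min_units=5)
        assert call_bound_regions(t, params) == []

    def test_score_window_may_use_subcutoff_values_inside_region(self):
        vals = np.zeros(100)
        vals[10:35] = 4.0
        vals[14] = 3.0  # below the 4.0 cutoff but inside the region
        t = self._track(vals)
        (region,) = call_bound_regions(t, CallingParams(top_percent=24.0))
        assert (region.start, region.end) == (100, 350)
        # leftmost best 5-window avoids the dip: steps 15..19, all 4.0
        assert region.score == pytest.approx(4.0)
        assert region.peak_center == 175

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_caller(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(100, 2000))
        vals = random_track_values(rng, n, missing_frac=0.15)
        t = self._track(vals)
        params = CallingParams(top_percent=float(rng.uniform(1.0, 20.0)))
        got = call_bound_regions(t, params)
        expected = call_regions_brute(
            {"c": vals.tolist()}, {"c": n * 10}, 10,
            top_percent=params.top_percent,
        )
        assert len(got) == len(expected)
        for r, (chrom, start, end, score, centre, n_units) in zip(got, expected):
            assert (r.chrom, r.start, r.end, r.peak_center, r.n_units) == (
                chrom, start, end, centre, n_units,
            )
            assert r.score == pytest.approx(score)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_regions_sorted_disjoint_with_enough_units(self, seed):
        rng = np.random.default_rng(100 + seed)
        vals = random_track_values(rng, 1500, missing_frac=0.1)
        t = self._track(vals)
        params = CallingParams(top_percent=10.0)
        regions = call_bound_regions(t, params)
        cutoff = threshold_top_percent(t, 10.0)
        prev_end = -1
        for r in regions:
            assert r.start >= prev_end
            prev_end = r.end
            v = t.values["c"][r.start // 10 : r.end // 10]
            assert int(np.nansum(v >= cutoff)) == r.n_units >= params.min_units
            assert r.end - r.start >= params.min_length_bp


class TestGeneOverlap:
    def _genes(self):
        return [
            GeneAnnotation("g1", "c", 1000, 2000, "+"),
            GeneAnnotation("g2", "c", 3000, 4000, "-"),
            GeneAnnotation("g3", "c", 5000, 6000, "+", expressed=False),
        ]

    def test_region_inside_gene_marks_it_bound(self):
        regions = [BoundRegion("c", 1200, 1500, 1.0, 1300, 5)]
        out = genes_overlapping_regions(regions, self._genes())
        assert [g.group for g in out] == ["bound", "unbound", "unassigned"]

    def test_no_regions_all_expressed_unbound(self):
        out = genes_overlapping_regions([], self._genes())
        assert [g.group for g in out] == ["unbound", "unbound", "unassigned"]

    def test_region_abutting_gene_start_does_not_overlap(self):
        regions = [BoundRegion("c", 800, 1000, 1.0, 900, 5)]
        out = genes_overlapping_regions(regions, self._genes())
        assert out[0].group == "unbound"

    def test_flank_extends_gene_span(self):
        regions = [BoundRegion("c", 800, 1000, 1.0, 900, 5)]
        out = genes_overlapping_regions(regions, self._genes(), flank_bp=1)
        assert out[0].group == "bound"
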