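import numpy as np
import pandas as pd
import pytest

from mslchip import (
    GeneAnnotation,
    GenomeAssembly,
    GenomeTrack,
    IntervalSet,
    repeat_fraction_track,
    select_wildtype_bound_genes,
    threshold_top_percent,
    tss_repeat_profile,
)


def _intervals(rows, assembly=None):
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), assembly=assembly)


class TestFractionTrack:
    def test_no_repeats_gives_zero(self):
        asm = GenomeAssembly({"c": 10_000}, step=10)
        # repeats on another chromosome leave this one at zero
        t = repeat_fraction_track(_intervals([("chrOther", 1, 2)]), asm)
        assert np.all(t.values["c"] == 0.0)

    def test_fully_masked_chromosome_gives_one(self):
        asm = GenomeAssembly({"c": 5_000}, step=10)
        t = repeat_fraction_track(_intervals([("c", 0, 5_000)]), asm)
        assert np.allclose(t.values["c"], 1.0)

    def test_50bp_repeat_inside_200bp_window_gives_quarter(self):
        asm = GenomeAssembly({"c": 10_000}, step=10)
        # step 100 has midpoint 1005, window [905, 1105); repeat fully inside
        t = repeat_fraction_track(_intervals([("c", 950, 1_000)]), asm)
        assert t.values["c"][100] == pytest.approx(0.25)

    def test_values_in_unit_interval_and_mass_conserved(self):
        rng = np.random.default_rng(3)
        asm = GenomeAssembly({"c": 100_000}, step=10)
        starts = np.sort(rng.choice(99_000, 80, replace=False))
        reps = _intervals([("c", int(s), int(s) + int(rng.integers(20, 800))) for s in starts])
        t = repeat_fraction_track(reps, asm)
        v = t.values["c"]
        assert v.min() >= 0.0 and v.max() <= 1.0
        total = reps.merged().total_bp()
        # sum(track)*step integrates masked bp; edge effects < window per end
        assert abs(v.sum() * 10 - total) <= 400

    def test_window_truncated_at_chromosome_start(self):
        asm = GenomeAssembly({"c": 1_000}, step=10)
        t = repeat_fraction_track(_intervals([("c", 0, 105)]), asm)
        # step 0: window [0, 105) fully masked -> 1.0 with truncated denominator
        assert t.values["c"][0] == pytest.approx(1.0)


class TestTssProfile:
    def _uniform_track(self, frac, length=60_000):
        asm = GenomeAssembly({"c": length}, step=10)
        return GenomeTrack(asm, {"c": np.full(asm.n_steps("c"), frac)}, semantics="repeat fraction")

    def test_uniform_masking_gives_flat_profile(self):
        genes = [
            GeneAnnotation(f"g{i}", "c", 25_000 + i, 27_000 + i, "+", group="bound")
            for i in range(10)
        ]
        prof = tss_repeat_profile(genes, self._uniform_track(0.3))
        assert np.allclose(prof["mean_pct"], 30.0)
        assert (prof["n_genes"] == 10).all()

    def test_group_mean_averages_gene_means(self):
        track = self._uniform_track(0.0)
        track.values["c"][:2_500] = 0.1  # first 25 kb at 10%
        track.values["c"][2_500:] = 0.3  # rest at 30%
        genes = [
            GeneAnnotation("gA", "c", 5_000, 6_000, "+", group="bound"),
            GeneAnnotation("gB", "c", 45_000, 46_000, "+", group="bound"),
        ]
        prof = tss_repeat_profile(genes, track, n_bins=1, bin_bp=1_000)
        assert prof.loc[0, "mean_pct"] == pytest.approx(20.0, abs=0.5)

    def test_ci_halves_shrink_with_sqrt_n(self):
        rng = np.random.default_rng(9)
        asm = GenomeAssembly({"c": 2_000_000}, step=10)
        vals = rng.random(asm.n_steps("c"))
        track = GenomeTrack(asm, {"c": vals}, semantics="repeat fraction")
        tss = rng.choice(np.arange(30_000, 1_970_000), 200, replace=False)
        genes = [
            GeneAnnotation(f"g{i}", "c", int(t), int(t) + 1_000, "+", group="bound")
            for i, t in enumerate(tss)
        ]
        small = tss_repeat_profile(genes[:50], track, n_bins=5)
        large = tss_repeat_profile(genes, track, n_bins=5)
        ratio = small["ci95_half_pct"].mean() / large["ci95_half_pct"].mean()
        assert ratio == pytest.approx(2.0, rel=0.35)  # sqrt(200/50) = 2

    def test_profile_invariant_to_gene_ordering(self):
        rng = np.random.default_rng(4)
        asm = GenomeAssembly({"c": 500_000}, step=10)
        track = GenomeTrack(asm, {"c": rng.random(asm.n_steps("c"))}, semantics="repeat fraction")
        genes = [
            GeneAnnotation(f"g{i}", "c", int(t), int(t) + 500, "+", group="bound")
            for i, t in enumerate(rng.choice(np.arange(25_000, 470_000), 30, replace=False))
        ]
        a = tss_repeat_profile(genes, track)
        b = tss_repeat_profile(genes[::-1], track)
        pd.testing.assert_frame_equal(a, b)

    def test_gene_near_chromosome_edge_retained(self):
        genes = [GeneAnnotation("g0", "c", 100, 1_100, "+", group="bound")]
        prof = tss_repeat_profile(genes, self._uniform_track(0.2))
        assert (prof["n_genes"] == 1).all()
        assert np.allclose(prof["mean_pct"], 20.0)

    def test_empty_group_is_an_error(self):
        genes = [GeneAnnotation("g0", "c", 25_000, 26_000, "+", group="bound")]
        with pytest.raises(ValueError, match="unbound"):
            tss_repeat_profile(genes, self._uniform_track(0.2), groups=("bound", "unbound"))

    def test_signed_profile_orients_by_strand(self):
        track = self._uniform_track(0.0)
        track.values["c"][3_000:3_100] = 1.0  # masked block at 30-31 kb
        plus = [GeneAnnotation("gp", "c", 29_000, 31_000, "+", group="bound")]
        minus = [GeneAnnotation("gm", "c", 27_000, 29_001, "-", group="bound")]
        p = tss_repeat_profile(plus, track, n_bins=5, signed=True)
        m = tss_repeat_profile(minus, track, n_bins=5, signed=True)
        # both TSSs sit at 29 kb; the block at 30-31 kb is 1-2 kb downstream of
        # the + gene but 1-2 kb upstream of the - gene after strand orientation
        assert p[p["dist_lo_bp"] == 1_000]["mean_pct"].iloc[0] > 0
        assert m[m["dist_lo_bp"] == 1_000]["mean_pct"].iloc[0] == 0
        assert m[m["dist_lo_bp"] == -2_000]["mean_pct"].iloc[0] > 0


class TestWildtypeBoundSelection:
    def _track(self, vals):
        asm = GenomeAssembly({"c": len(vals) * 10}, step=10)
        return GenomeTrack(asm, {"c": np.asarray(vals, float)}, semantics="log2 ChIP/input")

    def test_constant_track_marks_every_gene_bound(self):
        t = self._track([1.0] * 100)
        genes = [GeneAnnotation(f"g{i}", "c", i * 100, i * 100 + 50, "+") for i in range(5)]
        out = select_wildtype_bound_genes(genes, t)
        assert all(g.group == "bound" for g in out)

    def test_only_gene_covering_the_maximum_is_bound_at_tiny_cutoff(self):
        vals = np.zeros(1000)
        vals[500] = 10.0
        t = self._track(vals)
        genes = [
            GeneAnnotation("hit", "c", 4_990, 5_020, "+"),
            GeneAnnotation("miss", "c", 100, 400, "+"),
        ]
        out = select_wildtype_bound_genes(genes, t, top_percent=0.0001)
        assert [g.group for g in out] == ["bound", "unbound"]

    def test_matches_direct_counting_oracle(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 1, 5_000)
        t = self._track(vals)
        genes = [
            GeneAnnotation(f"g{i}", "c", int(s), int(s) + 200, "+")
            for i, s in enumerate(rng.choice(49_000, 100, replace=False))
        ]
        out = select_wildtype_bound_genes(genes, t, top_percent=5.0)
        cutoff = threshold_top_percent(t, 5.0)
        for g, labelled in zip(genes, out):
            steps = vals[g.start // 10 : -(-g.end // 10)]
            assert (labelled.group == "bound") == bool((steps >= cutoff).any())

    def test_unexpressed_genes_stay_unassigned(self):
        t = self._track([1.0] * 100)
        genes = [GeneAnnotation("g", "c", 0, 100, "+", expressed=False)]
        assert select_wildtype_bound_genes(genes, t)[0].group == "unassigned"
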