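"""Three-channel amplicon detection and ampliconic gene calling."""

import numpy as np
import pytest

from sexchromtk import amplicons as amp
from sexchromtk.intervals import GenomicInterval, bin_genome
from sexchromtk.io import AlignmentSegment
from sexchromtk.tracks import WindowTrack

from conftest import interval_matches


def seg(q, t, strand, identity, chrom="s"):
    return AlignmentSegment(
        GenomicInterval(chrom, *q), GenomicInterval(chrom, *t),
        strand, identity, q[1] - q[0],
    )


class TestDetectPalindromes:
    def test_single_inverted_segment_passes_thresholds(self):
        pals = amp.detect_palindromes([seg((0, 10_000), (110_000, 120_000), "-", 0.985)], [])
        assert len(pals) == 1
        assert pals[0].spacer == 100_000

    def test_arm_below_8kb_rejected(self):
        pals = amp.detect_palindromes([seg((0, 7_999), (10_000, 17_999), "-", 0.99)], [])
        assert pals == []

    @pytest.mark.parametrize(
        "identity,spacer,expect", [(0.979, 1_000, 0), (0.98, 1_000, 1), (0.99, 500_001, 0)]
    )
    def test_identity_and_spacer_thresholds(self, identity, spacer, expect):
        s = seg((0, 10_000), (10_000 + spacer, 20_000 + spacer), "-", identity)
        assert len(amp.detect_palindromes([s], [])) == expect

    def test_repeat_dense_candidate_rejected(self):
        s = seg((0, 10_000), (12_000, 22_000), "-", 0.99)
        repeats = [GenomicInterval("s", 0, 20_000)]  # > 80% of the 22-kb span
        assert amp.detect_palindromes([s], repeats) == []

    def test_forward_self_hits_ignored(self):
        assert amp.detect_palindromes([seg((0, 10_000), (20_000, 30_000), "+", 0.99)], []) == []

    def test_chained_segments_form_one_palindrome(self):
        # two co-linear inverted pieces chained into 10.5-kb arms: as the
        # query arm advances, the inverted target arm recedes
        s1 = seg((0, 5_000), (25_000, 30_000), "-", 0.99)
        s2 = seg((5_500, 10_500), (19_500, 24_500), "-", 0.99)
        pals = amp.detect_palindromes([s1, s2], [])
        assert len(pals) == 1
        assert len(pals[0].arm1) == 10_500

    def test_scenario_recovery_exact(self, scenario, self_segs):
        """All planted palindromes recovered within 100 bp; the
        repeat-covered decoy and everything else rejected."""
        pals = amp.detect_palindromes(self_segs, scenario.repeats)
        assert len(pals) == len(scenario.truth_palindromes)
        for p, (arm1, arm2) in zip(pals, scenario.truth_palindromes):
            assert interval_matches(p.arm1, arm1, 100)
            assert interval_matches(p.arm2, arm2, 100)


class TestDetectArrays:
    def test_window_candidate_rule(self):
        # hit covering 60% of a single window at 99.5% identity, from a
        # distant locus; three consecutive windows make a >= 10-kb region
        hits = [
            seg((w, w + 3_000), (50_000, 53_000), "+", 0.995)
            for w in (0, 3_000, 6_000, 9_000)
        ]
        out = amp.detect_arrays({"s": 60_000}, hits)
        assert len(out) == 1 and len(out[0]) >= 10_000

    def test_below_min_merged_dropped(self):
        hits = [seg((0, 3_000), (50_000, 53_000), "+", 0.995)]
        assert amp.detect_arrays({"s": 60_000}, hits) == []

    @pytest.mark.parametrize("identity", [0.985, 0.99])
    def test_identity_strictly_above_99(self, identity):
        hits = [seg((w, w + 3_000), (50_000, 53_000), "+", identity) for w in range(0, 12_000, 3_000)]
        assert amp.detect_arrays({"s": 60_000}, hits) == []

    def test_self_locus_hits_excluded(self):
        # a hit whose target is the window itself must not self-support
        hits = [seg((w, w + 3_000), (w, w + 3_000), "+", 0.995) for w in range(0, 12_000, 3_000)]
        assert amp.detect_arrays({"s": 60_000}, hits) == []

    def test_order_invariant(self, scenario, self_segs):
        sizes = {c: len(scenario.genome[c]) for c in ("chrX1", "chrY1", "scaffold_x")}
        fwd = amp.detect_arrays(sizes, self_segs)
        rev = amp.detect_arrays(sizes, list(reversed(self_segs)))
        assert fwd == rev

    def test_scenario_recovery_within_one_window(self, scenario, self_segs):
        sizes = {c: len(scenario.genome[c]) for c in ("chrX1", "chrY1", "scaffold_x")}
        arrays = amp.detect_arrays(sizes, self_segs)
        assert len(arrays) == len(scenario.truth_arrays)
        for got, truth in zip(arrays, scenario.truth_arrays):
            assert interval_matches(got, truth, 5_000)


class TestGcCorrection:
    def grid(self, n, chrom="s"):
        return bin_genome({chrom: 5_000 * n}, 5_000)

    def test_uniform_gc_identity(self):
        wins = self.grid(100)
        rng = np.random.default_rng(0)
        depth = WindowTrack(wins, rng.normal(30, 1, 100))
        gc = WindowTrack(wins, np.full(100, 0.41))
        out = amp.gc_correct_depth(depth, gc)
        assert np.allclose(out.values, depth.values)

    def test_removes_planted_bias_and_preserves_median(self):
        """On ~2,000 autosomal windows the planted sinusoidal GC bias is
        erased (|r| < 0.05 post-correction) and the median depth is kept."""
        from sexchromtk import simulate as sim

        cfg = sim.ScenarioConfig(
            seed=7, n_autosomes=4, autosome_length=2_500_000,
            gap_plan=(), palindrome_plan=(), array_plan=(), collapse_plan=(),
        )
        sc = sim.simulate_genome(cfg)
        male = sim.simulate_depth(sc, "male")
        gc = sim.gc_track(sc)
        corrected = amp.gc_correct_depth(male, gc)
        auto = np.array([
            i for i, w in enumerate(male.windows) if w.chrom.startswith("chrA")
        ])
        before = np.corrcoef(male.values[auto], gc.values[auto])[0, 1]
        after = np.corrcoef(corrected.values[auto], gc.values[auto])[0, 1]
        assert abs(before) > 0.4      # the generator really planted a bias
        assert abs(after) < 0.05
        assert np.median(corrected.values[auto]) == pytest.approx(
            np.median(male.values[auto]), rel=0.01
        )

    def test_grid_mismatch_rejected(self):
        depth = WindowTrack(self.grid(3), np.ones(3))
        gc = WindowTrack(self.grid(2), np.ones(2))
        with pytest.raises(ValueError):
            amp.gc_correct_depth(depth, gc)


class TestDepthAmplicons:
    def test_threshold_is_inclusive_and_repeats_filtered(self):
        wins = bin_genome({"y": 20_000}, 5_000)
        depth = WindowTrack(wins, np.array([30.0, 29.9, 30.0, 15.0]))
        sex = [GenomicInterval("y", 0, 20_000)]
        reps = [GenomicInterval("y", 10_000, 14_500)]  # 90% of window 3
        out = amp.detect_depth_amplicons(depth, 30.0, reps, sex)
        # window 1 at exactly the reference kept; window 2 below; window 3
        # repeat-dense; window 4 haploid
        assert out == [GenomicInterval("y", 0, 5_000)]

    def test_scenario_collapse_recovered(self, scenario, corrected_depth):
        corrected, ref = corrected_depth
        out = amp.detect_depth_amplicons(corrected, ref, scenario.repeats, scenario.sex_regions())
        assert len(out) == len(scenario.truth_collapsed)
        for got, (truth, _) in zip(out, scenario.truth_collapsed):
            assert interval_matches(got, truth, 5_000)


class TestMergeAndGeneCalls:
    def test_disjoint_pass_through_with_singleton_evidence(self):
        pal = amp.detect_palindromes([seg((0, 10_000), (12_000, 22_000), "-", 0.99)], [])
        regions = amp.merge_evidence(pal, [GenomicInterval("s", 50_000, 62_000)], [])
        assert [sorted(r.evidence) for r in regions] == [["palindrome"], ["array"]]

    def test_overlapping_channels_merge(self):
        pal = amp.detect_palindromes([seg((0, 10_000), (12_000, 22_000), "-", 0.99)], [])
        regions = amp.merge_evidence(pal, [], [GenomicInterval("s", 20_000, 30_000)])
        assert len(regions) == 1
        assert regions[0].evidence == frozenset({"palindrome", "depth"})

    def test_union_length_matches_mask_oracle(self):
        rng = np.random.default_rng(8)
        ivs = [
            GenomicInterval("s", int(a), int(a + l))
            for a, l in zip(rng.integers(0, 50_000, 40), rng.integers(1, 4_000, 40))
        ]
        regions = amp.merge_evidence([], ivs[:20], ivs[20:])
        mask = np.zeros(60_000, bool)
        for iv in ivs:
            mask[iv.start:iv.end] = True
        assert sum(len(r.interval) for r in regions) == int(mask.sum())

    @pytest.mark.parametrize(
        "region_end,called", [(8_100, True), (7_900, False)]
    )
    def test_gene_overlap_cutoff(self, region_end, called):
        # 10-kb gene covered 81% (called) vs 79% (not): > 80% rule
        region = [amp.AmpliconRegion(GenomicInterval("s", 0, region_end), frozenset({"array"}))]
        calls = amp.call_ampliconic_genes([("g", GenomicInterval("s", 0, 10_000))], region)
        assert calls[0].called is called

    def test_scenario_gene_calls(self, scenario, self_segs, corrected_depth):
        corrected, ref = corrected_depth
        pals = amp.detect_palindromes(self_segs, scenario.repeats)
        sizes = {c: len(scenario.genome[c]) for c in ("chrX1", "chrY1", "scaffold_x")}
        arrays = amp.detect_arrays(sizes, self_segs)
        depth_regions = amp.detect_depth_amplicons(
            corrected, ref, scenario.repeats, scenario.sex_regions()
        )
        regions = amp.merge_evidence(pals, arrays, depth_regions)
        calls = {
            c.gene: c for c in amp.call_ampliconic_genes(
                scenario.genes, regions, corrected, ref, scenario.sex_regions()
            )
        }
        assert calls["AmpX1"].called and calls["AmpY1"].called and calls["AmpY2"].called
        assert not calls["EdgeGene"].called          # 79% overlap
        assert calls["OR5A1"].excluded_class and not calls["OR5A1"].called
        assert not calls["HK1"].called and not calls["HK2"].called
        # planted 6-copy collapse: depth-ratio estimate within +- 1
        assert abs(calls["AmpY1"].copy_number_estimate - 6) <= 1
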