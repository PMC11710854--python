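"""JC69 divergence, bootstrap intervals, rate model, strata plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sexchromtk import simulate as sim
from sexchromtk.intervals import GenomicInterval
from sexchromtk.io import AlignmentSegment
from sexchromtk.strata import (
    PairwiseAlignment,
    bootstrap_divergence,
    build_rate_model,
    filter_y_segments,
    identity_windows,
    jc69,
    jc69_p,
    stratum_age,
)


class TestJC69:
    def test_zero(self):
        assert jc69(0.0) == 0.0

    def test_known_value(self):
        # d = -0.75 ln(0.6), evaluated independently to high precision
        assert jc69(0.3) == pytest.approx(0.3831192178244929, rel=1e-12)

    def test_saturation_rejected(self):
        for p in (0.75, 0.8, -0.01):
            with pytest.raises(ValueError):
                jc69(p)

    @given(st.floats(0.0, 0.749, allow_nan=False))
    def test_inverse_round_trip(self, p):
        assert jc69_p(jc69(p)) == pytest.approx(p, abs=1e-12)

    @given(st.floats(0.001, 0.749))
    def test_correction_exceeds_raw_proportion(self, p):
        assert jc69(p) >= p


class TestRateModel:
    def test_published_platypus_rates(self):
        """alpha = 2.95 with mu_AA = 7e-9 gives mu_XY = 8.15e-9 (3 s.f.)."""
        m = build_rate_model(2.95, 7e-9)
        assert m.mu_XY * 1e9 == pytest.approx(8.15, abs=0.005)

    def test_no_bias_is_neutral(self):
        m = build_rate_model(1.0, 7e-9)
        assert m.ratio == 1.0 and m.mu_XY == 7e-9

    def test_alpha_two(self):
        assert build_rate_model(2.0, 7e-9).mu_XY == pytest.approx(7e-9 * 10 / 9)

    def test_ratio_bounds_and_monotonicity(self):
        grid = np.linspace(0.1, 10, 200)
        ratios = [build_rate_model(a, 1e-9).ratio for a in grid]
        assert all(2 / 3 < r < 4 / 3 for r in ratios)
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_mu_f_consistency(self):
        m = build_rate_model(2.95, 7e-9)
        # autosomal rate = (1+alpha)/2 mu_f must reproduce mu_AA
        assert (1 + m.alpha) / 2 * m.mu_f == pytest.approx(m.mu_AA)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            build_rate_model(0.0, 7e-9)


class TestBootstrapDivergence:
    def test_identical_sequences(self):
        est = bootstrap_divergence(PairwiseAlignment("ACGT" * 100, "ACGT" * 100), 200, seed=1)
        assert est.d == 0.0 and est.ci == (0.0, 0.0)

    def test_deterministic_under_seed(self):
        aln = PairwiseAlignment("ACGTAC" * 500, "ACGTAC" * 250 + "ACGTAT" * 250)
        a = bootstrap_divergence(aln, 500, seed=9)
        b = bootstrap_divergence(aln, 500, seed=9)
        assert a == b
        c = bootstrap_divergence(aln, 500, seed=10)
        assert c.ci != a.ci

    def test_gaps_ns_and_mask_excluded(self):
        aln = PairwiseAlignment("ACG-NA", "ACGTNC", mask=[False] * 5 + [True])
        assert len(aln.mismatch_indicator()) == 3  # columns 0,1,2 only
        assert aln.mismatch_indicator().sum() == 0

    def test_no_valid_columns_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_divergence(PairwiseAlignment("---", "AAA"))

    def test_saturated_replicates_discarded_with_warning(self):
        # p = 0.7 on 40 columns: some resamples cross the 3/4 ceiling
        aln = PairwiseAlignment("A" * 40, "C" * 28 + "A" * 12)
        with pytest.warns(UserWarning, match="saturated"):
            est = bootstrap_divergence(aln, 2_000, seed=3)
        assert est.n_discarded > 0
        assert est.d == pytest.approx(jc69(0.7))

    def test_scenario_divergences_inside_ci(self, scenario):
        for i, (_, _, d_true) in enumerate(scenario.truth_strata):
            x, y = scenario.stratum_alignment(i)
            est = bootstrap_divergence(PairwiseAlignment(x, y), 1_000, seed=11 + i)
            assert est.ci[0] <= d_true <= est.ci[1]


class TestStratumAge:
    def test_exact_division(self):
        model = build_rate_model(2.95, 7e-9)
        est = bootstrap_divergence(
            PairwiseAlignment("A" * 10, "A" * 10), 10, seed=0
        )
        assert stratum_age(est, model).T == 0.0

    def test_ten_million_years(self):
        model = build_rate_model(2.95, 7e-9)
        fake = type(
            "E", (), {"d": 0.0815, "ci": (0.08, 0.083)}
        )  # minimal estimate-like object
        age = stratum_age(fake, model)
        assert age.T == pytest.approx(1.0e7, rel=5e-4)
        assert age.ci[0] < age.T < age.ci[1]

    def test_end_to_end_recovery_of_planted_age(self, scenario):
        """When the same rate model generated the divergence, the age comes
        back as planted d / mu_XY within the bootstrap CI."""
        model = build_rate_model(2.95, 7e-9)
        x, y = scenario.stratum_alignment(0)
        est = bootstrap_divergence(PairwiseAlignment(x, y), 1_000, seed=21)
        age = stratum_age(est, model)
        planted_age = scenario.truth_strata[0][2] / model.mu_XY
        assert age.ci[0] <= planted_age <= age.ci[1]
        assert age.T == pytest.approx(planted_age, rel=0.05)


def xseg(q, t, identity, length=None, matches=None, qc="X", tc="Y", strand="+"):
    length = length or (q[1] - q[0])
    return AlignmentSegment(
        GenomicInterval(qc, *q), GenomicInterval(tc, *t), strand, identity, length, matches
    )


class TestIdentityWindows:
    def test_fully_covered_window(self):
        track = identity_windows([xseg((0, 1_000), (0, 1_000), 0.99, matches=990)])
        assert track.values[0] == pytest.approx(0.990)

    def test_uncovered_window_missing(self):
        track = identity_windows(
            [xseg((0, 1_000), (0, 1_000), 0.99)], chrom_sizes={"X": 3_000}
        )
        assert np.isnan(track.values[2])

    def test_matched_bases_conserved(self, scenario):
        segs = sim.xy_segments(scenario)
        track = identity_windows(segs, chrom_sizes={"chrX1": len(scenario.genome["chrX1"])})
        total_track = np.nansum(
            track.values * np.array([
                sum(min(w.end, s.q_interval.end) - max(w.start, s.q_interval.start)
                    for s in segs if s.q_interval.overlap(w) > 0)
                for w in track.windows
            ])
        )
        total_segs = sum(s.matches for s in segs)
        assert total_track == pytest.approx(total_segs, rel=1e-6)

    def test_stratum_identity_tracks_planted_divergence(self, scenario):
        track = identity_windows(
            sim.xy_segments(scenario), chrom_sizes={"chrX1": len(scenario.genome["chrX1"])}
        )
        for x_iv, _, d in scenario.truth_strata:
            sel = [
                v for w, v in zip(track.windows, track.values)
                if x_iv.contains(w) and not np.isnan(v)
            ]
            expected = 1 - 0.75 * (1 - np.exp(-4 * d / 3))
            assert np.mean(sel) == pytest.approx(expected, abs=0.01)


class TestFilterYSegments:
    def test_strictly_better_competitor_drops_segment(self):
        xy = [xseg((0, 1_000), (0, 1_000), 0.95)]
        other = [xseg((0, 1_000), (0, 2_000), 0.99, length=2_000, qc="Y", tc="chrA1")]
        assert filter_y_segments(xy, other) == []

    def test_tie_on_identity_keeps_segment(self):
        xy = [xseg((0, 1_000), (0, 1_000), 0.95)]
        other = [xseg((0, 1_000), (0, 2_000), 0.95, length=2_000, qc="Y", tc="chrA1")]
        assert filter_y_segments(xy, other) == xy

    def test_no_competitors_keeps_all(self):
        xy = [xseg((0, 1_000), (0, 1_000), 0.5)]
        assert filter_y_segments(xy, []) == xy

    def test_low_reciprocal_overlap_ignored(self):
        xy = [xseg((0, 1_000), (0, 1_000), 0.95)]
        other = [xseg((900, 3_000), (0, 3_000), 0.99, length=2_100, qc="Y", tc="chrA1")]
        assert filter_y_segments(xy, other) == xy

    def test_scenario_decoy_removed_keeper_kept(self, scenario):
        xy = sim.xy_segments(scenario)
        others, drop_idx = sim.y_vs_other_segments(scenario, xy)
        kept = filter_y_segments(xy, others)
        assert len(kept) == len(xy) - len(drop_idx)
        for i in drop_idx:
            assert xy[i] not in kept
        assert xy[1] in kept  # equal-identity competitor must not drop it
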