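"""Target CNV stage: binning, log2 normalization, segmentation, calls."""

import math

import numpy as np
import pytest

from asval import cnv_target
from asval.cnv_target import (
    DELETION_ABSOLUTE,
    DUPLICATION_ABSOLUTE,
    INDETERMINATE,
    TWO_FLANKING_DUPS,
    Log2Track,
    binned_depth,
    call_target_cnv,
    disambiguate_del_vs_dup,
    segment_and_call,
    target_log2,
)
from asval.types import (
    AlignmentSegment,
    DepthProfile,
    GenomeLayout,
    SegmentStatus,
    Sex,
    TargetRegion,
)
from conftest import passing_segments


class TestBinnedDepth:
    def test_no_alignments_all_zero(self):
        profile = binned_depth([], [("chr1", 0, 2000)], 500)
        assert profile.depth == pytest.approx([0, 0, 0, 0])

    def test_partial_overlap(self):
        seg = AlignmentSegment("r", 0, "chr1", 100, 350, "+")
        profile = binned_depth([seg], [("chr1", 0, 500)], 500)
        assert profile.depth == pytest.approx([0.5])  # 250/500

    def test_last_bin_short(self):
        profile = binned_depth([], [("chr1", 0, 1200)], 500)
        assert profile.bins[-1] == ("chr1", 1000, 1200)

    def test_interval_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than 1"):
            binned_depth([], [("chr1", 100, 100)], 500)

    def test_matches_per_base_pileup_oracle(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            ival_start = int(rng.integers(0, 1000))
            ival_end = ival_start + int(rng.integers(800, 5000))
            bin_size = int(rng.integers(50, 700))
            segs = []
            for i in range(int(rng.integers(1, 60))):
                s = int(rng.integers(0, ival_end + 1000))
                e = s + int(rng.integers(1, 2500))
                segs.append(AlignmentSegment(f"r{i}", 0, "chr1", s, e, "+"))
            profile = binned_depth(segs, [("chr1", ival_start, ival_end)], bin_size)
            # brute force: count every base
            pile = np.zeros(ival_end - ival_start)
            for seg in segs:
                lo = max(seg.start, ival_start) - ival_start
                hi = min(seg.end, ival_end) - ival_start
                for b in range(lo, max(lo, hi)):
                    pile[b] += 1
            for (c, s, e), d in zip(profile.bins, profile.depth):
                assert d == pytest.approx(pile[s - ival_start : e - ival_start].mean())


def flat_profile(depths, bin_size=500, contig="chr1", start=0):
    bins = [
        (contig, start + i * bin_size, start + (i + 1) * bin_size)
        for i in range(len(depths))
    ]
    return DepthProfile(bins=bins, depth=list(depths), bin_size=bin_size)


AUTOSOMES = GenomeLayout([("chr1", 10_000_000)])


class TestTargetLog2:
    def test_bin_at_mean_is_zero(self):
        track = target_log2(flat_profile([10.0] * 8), AUTOSOMES)
        assert track.log2 == pytest.approx([0.0] * 8)

    def test_half_and_gain_levels(self):
        # 30 reference bins keep mu near 10; probe bins at 5x and 15x
        depths = [10.0] * 30 + [5.0, 15.0]
        track = target_log2(flat_profile(depths), AUTOSOMES)
        mu_shift = math.log2(track.mu / 10.0)
        assert track.log2[30] == pytest.approx(-1.0 + -mu_shift, abs=0.05)
        assert track.log2[31] == pytest.approx(math.log2(1.5), abs=0.05)

    def test_zero_depth_floor(self):
        track = target_log2(flat_profile([10.0] * 10 + [0.0]), AUTOSOMES)
        assert track.log2[-1] == cnv_target.ZERO_DEPTH_FLOOR

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            target_log2(flat_profile([0.0] * 5), AUTOSOMES)

    def test_normalization_closure(self):
        """Length-weighted mean of 2^r over the normalization bins is 1."""
        rng = np.random.default_rng(3)
        depths = rng.gamma(20, 0.5, size=50)
        track = target_log2(flat_profile(list(depths)), AUTOSOMES)
        widths = np.asarray([e - s for _, s, e in track.bins], dtype=float)
        assert np.average(2.0 ** track.log2, weights=widths) == pytest.approx(1.0, abs=1e-9)

    def test_male_x_bins_against_half_reference(self):
        genome = GenomeLayout([("chr1", 10_000_000), ("chrX", 10_000_000)], sex=Sex.MALE)
        bins = [("chr1", i * 500, (i + 1) * 500) for i in range(10)] + [
            ("chrX", i * 500, (i + 1) * 500) for i in range(10)
        ]
        profile = DepthProfile(bins=bins, depth=[20.0] * 10 + [10.0] * 10, bin_size=500)
        track = target_log2(profile, genome)
        assert track.mu == pytest.approx(20.0)  # X excluded from the reference
        assert track.log2[15] == pytest.approx(0.0)  # 10x vs mu/2
        assert track.baseline[15] == 1


def synthetic_track(levels, bins_per_level=40, depth0=28.0):
    """Noise-free log2 track with plateaus at given copy numbers."""
    depths = []
    for cn in levels:
        depths.extend([depth0 * cn / 2.0] * bins_per_level)
    return target_log2(flat_profile(depths, contig="chr1"), AUTOSOMES)


class TestSegmentAndCall:
    def test_flat_track_single_neutral_cn2(self):
        track = target_log2(flat_profile([10.0] * 100), AUTOSOMES)
        (seg,) = segment_and_call(track)
        assert seg.status == SegmentStatus.NEUTRAL
        assert seg.cn_estimate == 2
        assert seg.n_bins == 100

    def test_cn_exactness_noise_free(self):
        """Depth scaled by k/2 against a dominating diploid reference gives cn k."""
        for k in range(0, 9):
            n_ref = 4000  # reference dwarfs the event, pinning mu at diploid
            depths = [28.0] * n_ref + [28.0 * k / 2.0] * 40
            track = target_log2(flat_profile(depths), AUTOSOMES)
            segs = segment_and_call(track)
            assert segs[-1].cn_estimate == k, f"k={k}: {segs}"

    def test_constructed_deletion_called_loss_cn1(self):
        track = synthetic_track([2, 2, 1, 2, 2])
        losses = [s for s in segment_and_call(track) if s.status == SegmentStatus.LOSS]
        assert len(losses) == 1
        assert losses[0].cn_estimate == 1
        assert losses[0].start == 2 * 40 * 500
        assert losses[0].end == 3 * 40 * 500

    def test_trip_quint_trip_plateaus_stay_separate(self):
        depths = (
            [28.0] * 2000
            + [56.0] * 40 + [84.0] * 40 + [56.0] * 40
            + [28.0] * 2000
        )
        track = target_log2(flat_profile(depths), AUTOSOMES)
        gains = [s for s in segment_and_call(track) if s.status == SegmentStatus.GAIN]
        assert [s.cn_estimate for s in gains] == [4, 6, 4]

    def test_simulated_trip_quint_trip_recovery(self, fixture_runs, fixture_cfgs):
        cfg = fixture_cfgs["trip_quint_trip"]
        _, segs = passing_segments(fixture_runs["trip_quint_trip"])
        calls, _ = call_target_cnv(segs, cfg.targets, cfg.genome)
        locus = [
            s for s in calls
            if s.contig == "chr2"
            and s.status == SegmentStatus.GAIN
            and s.end > 1_245_000
            and s.start < 1_755_000
        ]
        assert [s.cn_estimate for s in locus] == [4, 6, 4]
        truth_bounds = [1_250_000, 1_400_000, 1_600_000, 1_750_000]
        got_bounds = [locus[0].start, locus[1].start, locus[2].start, locus[2].end]
        for got, want in zip(got_bounds, truth_bounds):
            assert abs(got - want) <= 5_000  # within one window

    def test_empty_track_rejected(self):
        track = Log2Track(
            bins=[], depth=np.array([]), log2=np.array([]), mu=1.0, baseline=np.array([])
        )
        with pytest.raises(ValueError):
            segment_and_call(track)


class TestDisambiguation:
    def two_region_track(self, event_levels, control_level=1.0, depth0=28.0):
        """Event region (3 x 40-bin plateaus) plus a dominating control region."""
        event = []
        for level in event_levels:
            event.extend([depth0 * level] * 40)
        bins = [("chr1", i * 500, (i + 1) * 500) for i in range(len(event))]
        n_ctrl = 400
        bins += [("chr2", i * 500, (i + 1) * 500) for i in range(n_ctrl)]
        profile = DepthProfile(
            bins=bins, depth=event + [depth0 * control_level] * n_ctrl, bin_size=500
        )
        return target_log2(profile, AUTOSOMES)

    def test_absolute_dip_is_deletion(self):
        track = self.two_region_track([1.0, 0.5, 1.0])
        segs = disambiguate_del_vs_dup(segment_and_call(track), track)
        losses = [s for s in segs if s.status == SegmentStatus.LOSS]
        assert len(losses) == 1
        assert losses[0].annotation == DELETION_ABSOLUTE

    def test_elevated_flanks_are_two_duplications(self):
        track = self.two_region_track([1.5, 1.0, 1.5])
        segs = disambiguate_del_vs_dup(segment_and_call(track), track)
        gains = [s for s in segs if s.status == SegmentStatus.GAIN]
        assert len(gains) == 2
        assert all(s.annotation == DUPLICATION_ABSOLUTE for s in gains)
        middles = [s for s in segs if s.annotation == TWO_FLANKING_DUPS]
        assert len(middles) == 1
        assert middles[0].status == SegmentStatus.NEUTRAL

    def test_all_neutral_nothing_annotated(self):
        track = self.two_region_track([1.0, 1.0, 1.0])
        segs = disambiguate_del_vs_dup(segment_and_call(track), track)
        assert all(s.annotation == "" for s in segs)

    def test_single_region_indeterminate(self):
        depths = [28.0] * 40 + [14.0] * 40 + [28.0] * 40
        track = target_log2(flat_profile(depths), AUTOSOMES)
        segs = disambiguate_del_vs_dup(segment_and_call(track), track)
        aberrant = [s for s in segs if s.status != SegmentStatus.NEUTRAL]
        assert aberrant
        assert all(s.annotation == INDETERMINATE for s in aberrant)
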