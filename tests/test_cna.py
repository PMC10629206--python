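"""Coverage windowing, log ratios, median decimation, and CNA calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glioprog.cna import (
    CoverageTrack,
    LogRatioTrack,
    SegmentThresholds,
    call_segments,
    count_windows,
    coverage_log_ratio,
    median_decimate,
    targeted_gene_copy_state,
)
from glioprog.genome import ReferenceGenome


def flat_genome(length=10_000, chroms=("chr1",)):
    return ReferenceGenome({c: bytearray(b"A" * length) for c in chroms})


def make_tracks(tumor_counts, ref_counts, window=1000):
    t = CoverageTrack(window, {"chr1": np.asarray(tumor_counts, float)})
    r = CoverageTrack(window, {"chr1": np.asarray(ref_counts, float)})
    return t, r


class TestCountWindows:
    def test_half_open_window_boundaries(self):
        genome = flat_genome(3000)
        track = count_windows({"chr1": np.array([0, 999, 1000])}, genome, 1000)
        assert track.counts["chr1"].tolist() == [2, 1, 0]

    def test_empty_input_gives_zero_track(self):
        track = count_windows({}, flat_genome(2500), 1000)
        assert track.counts["chr1"].tolist() == [0, 0, 0]

    def test_total_count_conserved_uniform(self, rng):
        genome = flat_genome(1_000_000)
        starts = rng.integers(0, 1_000_000, size=10_000)
        track = count_windows({"chr1": starts}, genome, 1000)
        assert track.counts["chr1"].sum() == 10_000
        assert np.allclose(track.counts["chr1"].mean(), 10.0)
        # cross-check against a direct histogram
        expected = np.histogram(starts, bins=1000, range=(0, 1_000_000))[0]
        assert (track.counts["chr1"] == expected).all()

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            count_windows({"chr1": np.array([5000])}, flat_genome(3000), 1000)


class TestLogRatio:
    def test_identical_tracks_are_flat_zero(self):
        t, r = make_tracks([10, 20, 30], [10, 20, 30])
        ratio = coverage_log_ratio(t, r)
        assert np.allclose(ratio.values["chr1"], 0.0)

    def test_global_doubling_is_depth_not_copy_number(self):
        t, r = make_tracks([20, 40, 60], [10, 20, 30])
        ratio = coverage_log_ratio(t, r)
        assert np.allclose(ratio.values["chr1"], 0.0)

    def test_single_window_enrichment(self):
        base = [100.0] * 100
        tumor = list(base)
        tumor[50] = 200.0
        ratio = coverage_log_ratio(*make_tracks(tumor, base))
        # closed form including library-size normalization
        shift = math.log2(10_100 / 10_000)
        assert ratio.values["chr1"][50] == pytest.approx(1.0 - shift)
        assert ratio.values["chr1"][0] == pytest.approx(-shift)

    def test_zero_reference_masked_zero_tumor_is_neg_inf(self):
        t, r = make_tracks([0, 10], [10, 0])
        ratio = coverage_log_ratio(t, r)
        assert ratio.values["chr1"][0] == -np.inf
        assert np.isnan(ratio.values["chr1"][1])

    def test_grid_mismatch_rejected(self):
        t, _ = make_tracks([1, 2], [1, 2])
        r = CoverageTrack(500, {"chr1": np.array([1.0, 2.0])})
        with pytest.raises(ValueError):
            coverage_log_ratio(t, r)

    def test_scale_invariance(self, rng):
        base = rng.poisson(30, 200).astype(float) + 1
        tumor = rng.poisson(30, 200).astype(float) + 1
        r1 = coverage_log_ratio(*make_tracks(tumor, base))
        r2 = coverage_log_ratio(*make_tracks(tumor * 7.3, base))
        assert np.allclose(r1.values["chr1"], r2.values["chr1"])


class TestMedianDecimate:
    def test_factor_200_on_400_windows(self, rng):
        values = rng.normal(size=400)
        track = LogRatioTrack(1000, {"chr1": values})
        out = median_decimate(track, 200)
        assert out.values["chr1"].size == 2
        assert out.values["chr1"][0] == pytest.approx(np.median(values[:200]))
        assert out.values["chr1"][1] == pytest.approx(np.median(values[200:]))
        assert out.decimation_factor == 200

    def test_factor_one_is_identity(self, rng):
        values = rng.normal(size=17)
        out = median_decimate(LogRatioTrack(1000, {"chr1": values}), 1)
        assert (out.values["chr1"] == values).all()

    def test_median_robust_to_outlier(self):
        out = median_decimate(
            LogRatioTrack(1000, {"chr1": np.array([-1.0, -1.0, 5.0])}), 3
        )
        assert out.values["chr1"].tolist() == [-1.0]

    def test_masked_windows_ignored_within_block(self):
        out = median_decimate(
            LogRatioTrack(1000, {"chr1": np.array([np.nan, 2.0, 4.0, np.nan])}), 4
        )
        assert out.values["chr1"].tolist() == [3.0]

    @given(n=st.integers(0, 500), factor=st.integers(1, 250))
    @settings(max_examples=40, deadline=None)
    def test_length_law(self, n, factor):
        track = LogRatioTrack(1000, {"chr1": np.zeros(n)})
        out = median_decimate(track, factor)
        assert out.values["chr1"].size == math.ceil(n / factor)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            median_decimate(LogRatioTrack(1000, {"chr1": np.zeros(3)}), 0)


class TestSegments:
    def test_flat_track_is_one_neutral_segment(self):
        track = LogRatioTrack(1000, {"chr1": np.zeros(50)}, decimation_factor=10)
        segments = call_segments(track)
        assert segments == [("chr1", 0, 500_000, "neutral")]

    def test_amplification_ratio_closed_form(self):
        # 26x relative copy at one decimated window
        base = np.zeros(100)
        base[40] = math.log2(26)
        track = LogRatioTrack(1000, {"chr1": base})
        segments = call_segments(track)
        states = {s[3] for s in segments}
        assert ("chr1", 40_000, 41_000, "amplification") in segments
        assert states == {"neutral", "amplification"}

    def test_band_boundaries(self):
        thr = SegmentThresholds()
        values = np.array([-5.0, -1.0, 0.0, 0.5, 2.5])
        track = LogRatioTrack(1, {"chr1": values})
        states = [s[3] for s in call_segments(track, thr)]
        assert states == [
            "homozygous_deletion",
            "loss",
            "neutral",
            "gain",
            "amplification",
        ]


class TestTargeted:
    def test_baseline_depth_not_called(self):
        calls = targeted_gene_copy_state({"CDKN2A": 100.0}, [90, 100, 110])
        assert calls[0].state == "not_called"

    def test_zero_depth_is_homozygous_deletion(self):
        calls = targeted_gene_copy_state({"CDKN2A": 0.0}, [100, 100])
        assert calls[0].state == "homozygous_deletion"

    def test_sixteen_fold_is_amplification(self):
        calls = targeted_gene_copy_state({"PDGFRA": 1600.0}, [100, 100])
        assert calls[0].state == "amplification"
        assert calls[0].log_ratio == pytest.approx(4.0, abs=0.01)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            targeted_gene_copy_state({"g": 1.0}, [])


class TestPlantedRecovery:
    def test_planted_cna_recovered_within_one_decimated_window(self, small_cohort):
        """Homozygous deletions and amplifications land within one
        decimated window of truth; hemizygous losses average near -1."""
        factor = 10
        step = small_cohort.config.window_size * factor
        for patient, (pre_name, post_name) in small_cohort.pairs.items():
            obs = small_cohort.samples[post_name]
            ratio = coverage_log_ratio(obs.coverage, small_cohort.reference_coverage)
            decimated = median_decimate(ratio, factor)
            segments = call_segments(decimated)
            truth = {
                ev.kind: ev
                for ev in small_cohort.truth[post_name]
                if ev.kind in ("homozygous_deletion", "amplification", "hemizygous_loss")
            }
            for kind in ("homozygous_deletion", "amplification"):
                ev = truth[kind]
                matches = [
                    s
                    for s in segments
                    if s[3] == kind and s[0] == ev.chrom and s[1] < ev.end and s[2] > ev.start
                ]
                assert matches, (patient, kind)
                seg = max(matches, key=lambda s: s[2] - s[1])
                assert abs(seg[1] - ev.start) <= step
                assert abs(seg[2] - ev.end) <= step
            ev = truth["hemizygous_loss"]
            w0, w1 = ev.start // step, ev.end // step
            values = decimated.values[ev.chrom][w0:w1]
            assert abs(np.nanmean(values) - (-1.0)) <= 0.15
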