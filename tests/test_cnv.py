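"""CNV pipeline: each signal-processing step against direct oracles, then
end-to-end parameter recovery on planted events."""

import math

import numpy as np
import pytest

from wgscohort import (
    GenomeSpec,
    PlantedCNV,
    RDProfile,
    bin_and_log_ratio,
    bin_frequency_map,
    classify_segments,
    gen_rd_profiles,
    intersect_with_caller,
    normalize_normal,
    segment_constant,
    segment_recovery,
    segment_sample,
    smooth_lr,
)
from wgscohort.cnv import CNSegment, LRTrack, read_segments_bed, write_segments_bed
from wgscohort.genome import read_bedgraph, write_bedgraph


def profile(values, bin_size=3000, tissue="tumor", chrom="chr1"):
    return RDProfile("s", tissue, {chrom: np.asarray(values, dtype=float)}, bin_size)


class TestNormalizeNormal:
    def test_equal_totals_is_identity(self):
        t = profile([10, 20, 30])
        n = profile([30, 20, 10], tissue="normal")
        out = normalize_normal(t, n)
        np.testing.assert_allclose(out.bins["chr1"], [30, 20, 10])

    def test_double_total_doubles_every_bin(self):
        t = profile([20, 20, 20])
        n = profile([10, 10, 10], tissue="normal")
        out = normalize_normal(t, n)
        np.testing.assert_allclose(out.bins["chr1"], [20, 20, 20])

    def test_total_signal_conserved_on_random_profiles(self, rng):
        t = profile(rng.gamma(2.0, 50.0, 500))
        n = profile(rng.gamma(2.0, 30.0, 500), tissue="normal")
        out = normalize_normal(t, n)
        assert math.isclose(out.total(), t.total(), rel_tol=1e-12)

    def test_partition_mismatch_names_chromosome(self):
        t = profile([1, 2, 3])
        n = RDProfile("s", "normal", {"chr2": np.ones(3)}, 3000)
        with pytest.raises(ValueError, match="chr"):
            normalize_normal(t, n)

    def test_all_zero_normal_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_normal(profile([1, 2]), profile([0, 0], tissue="normal"))


class TestBinAndLogRatio:
    def test_equal_bins_give_zero_and_double_gives_one(self):
        t = profile([40, 80])
        n = profile([40, 40], tissue="normal")
        lr = bin_and_log_ratio(t, n, bin_size=3000)
        np.testing.assert_allclose(lr.values["chr1"], [0.0, 1.0])

    def test_matches_per_bin_oracle_with_aggregation(self, rng):
        # profiles at 1-kb resolution aggregated into 3-kb LR bins
        t = profile(rng.gamma(3.0, 20.0, 300), bin_size=1000)
        n = profile(rng.gamma(3.0, 20.0, 300), bin_size=1000, tissue="normal")
        lr = bin_and_log_ratio(t, n, bin_size=3000)
        for b in range(100):
            ts = t.bins["chr1"][3 * b: 3 * b + 3].sum()
            ns = n.bins["chr1"][3 * b: 3 * b + 3].sum()
            assert math.isclose(lr.values["chr1"][b], math.log2(ts / ns), rel_tol=1e-12)

    def test_zero_bins_are_masked(self):
        t = profile([10, 0, 10])
        n = profile([10, 10, 0], tissue="normal")
        lr = bin_and_log_ratio(t, n, bin_size=3000)
        v = lr.values["chr1"]
        assert np.isnan(v[1]) and np.isnan(v[2]) and v[0] == 0.0

    def test_indivisible_bin_size_rejected(self):
        t = profile([1.0] * 10, bin_size=2000)
        n = profile([1.0] * 10, bin_size=2000, tissue="normal")
        with pytest.raises(ValueError, match="not divisible"):
            bin_and_log_ratio(t, n, bin_size=3000)


def brute_force_sliding_median(v, w):
    out = np.empty(len(v))
    for b in range(len(v)):
        window = v[max(0, b - w): b + w + 1]
        window = window[~np.isnan(window)]
        out[b] = np.median(window) if len(window) else np.nan
    return out


class TestSmoothLR:
    def make_track(self, values):
        v = np.asarray(values, dtype=float)
        return LRTrack({"chr1": v}, 3000, smoothed=False,
                       tumor_sums={"chr1": np.ones_like(v)},
                       normal_sums={"chr1": np.ones_like(v)},
                       chrom_lengths={"chr1": len(v) * 3000})

    def test_constant_track_unchanged_and_idempotent(self):
        track = self.make_track([0.4] * 50)
        once = smooth_lr(track, half_window=5)
        np.testing.assert_array_equal(once.values["chr1"], track.values["chr1"])
        twice = smooth_lr(once, half_window=5)
        np.testing.assert_array_equal(twice.values["chr1"], once.values["chr1"])

    def test_single_spike_removed(self):
        v = np.zeros(41)
        v[20] = 5.0
        out = smooth_lr(self.make_track(v), half_window=5)
        np.testing.assert_array_equal(out.values["chr1"], np.zeros(41))

    @pytest.mark.parametrize("w", [1, 3, 8, 25])
    def test_equals_brute_force_on_step_and_noise(self, w, rng):
        v = np.concatenate([np.zeros(30), np.ones(40), rng.normal(0, 1, 50)])
        out = smooth_lr(self.make_track(v), half_window=w)
        np.testing.assert_allclose(out.values["chr1"], brute_force_sliding_median(v, w))

    def test_masked_bins_excluded_and_stay_masked(self, rng):
        v = rng.normal(0, 1, 60)
        v[[7, 8, 30]] = np.nan
        out = smooth_lr(self.make_track(v), half_window=4)
        expected = brute_force_sliding_median(v, 4)
        expected[[7, 8, 30]] = np.nan
        np.testing.assert_allclose(out.values["chr1"], expected)

    def test_oversized_window_truncates_to_chromosome(self, caplog):
        v = np.arange(9, dtype=float)
        out = smooth_lr(self.make_track(v), half_window=100)
        np.testing.assert_allclose(out.values["chr1"], np.full(9, 4.0))


class TestSegmentation:
    def step_track(self):
        v = np.concatenate([np.zeros(40), np.full(60, 1.0)])
        t = np.concatenate([np.full(40, 100.0), np.full(60, 200.0)])
        n = np.full(100, 100.0)
        return LRTrack({"chr1": v}, 3000, smoothed=True,
                       tumor_sums={"chr1": t}, normal_sums={"chr1": n},
                       chrom_lengths={"chr1": 300_000})

    def test_two_level_step_gives_two_segments_at_boundary(self):
        segs = segment_constant(self.step_track(), tol=1e-9)
        assert [(s.start, s.end) for s in segs] == [(0, 120_000), (120_000, 300_000)]
        # per-segment lr recomputed from raw totals, not from smoothed values
        assert math.isclose(segs[0].lr, 0.0, abs_tol=1e-12)
        assert math.isclose(segs[1].lr, 1.0, abs_tol=1e-12)

    def test_segments_tile_each_chromosome(self, rng):
        v = rng.choice([0.0, 0.5, -0.5], size=200)
        track = LRTrack({"chr1": v}, 3000, smoothed=True,
                        tumor_sums={"chr1": np.ones(200)},
                        normal_sums={"chr1": np.ones(200)},
                        chrom_lengths={"chr1": 599_000})  # trailing partial bin
        segs = segment_constant(track, tol=1e-9)
        assert sum(s.length for s in segs) == 599_000
        assert segs[0].start == 0 and segs[-1].end == 599_000

    def test_masked_gap_splits_segments(self):
        v = np.zeros(30)
        v[10:13] = np.nan
        track = LRTrack({"chr1": v}, 3000, smoothed=True,
                        tumor_sums={"chr1": np.ones(30)},
                        normal_sums={"chr1": np.ones(30)},
                        chrom_lengths={"chr1": 90_000})
        segs = segment_constant(track, tol=1e-9)
        assert [(s.start, s.end) for s in segs] == [(0, 30_000), (39_000, 90_000)]


class TestClassify:
    @pytest.mark.parametrize(
        "lr,length,expected",
        [
            (0.3, 150_000, "gain"),    # above threshold, long enough
            (0.3, 50_000, "neutral"),  # too short
            (0.0, 500_000, "neutral"),
            (0.2, 500_000, "neutral"),   # strict inequality at the threshold
            (-0.2, 500_000, "neutral"),
            (-0.25, 150_000, "loss"),
            (0.21, 100_000, "neutral"),  # length must strictly exceed 100 kb
            (0.21, 100_001, "gain"),
        ],
    )
    def test_threshold_and_length_rules(self, lr, length, expected):
        seg = CNSegment("chr1", 0, length, lr)
        assert classify_segments([seg])[0].call == expected


class TestEndToEnd:
    def test_noiseless_recovery_exact_for_events_beyond_window_support(self):
        """Events longer than half_window+1 bins survive the median filter
        with exact boundaries; precision and recall are 1.0 at bin level."""
        genome = GenomeSpec((("chr1", 25_000_000), ("chr2", 25_000_000)), 3000)
        events = [
            PlantedCNV("chr1", 3_000_000, 5_100_000, 1.0),    # 700 bins
            PlantedCNV("chr1", 15_000_000, 18_000_000, -0.6),
            PlantedCNV("chr2", 8_000_000, 10_000_000, 0.3),   # 667 bins, weak
        ]
        tumor, normal, truth = gen_rd_profiles(genome, events, 100.0, 0.0, seed=3)
        segs = segment_sample(tumor, normal)
        precision, recall = segment_recovery(truth, segs, genome)
        assert precision == 1.0 and recall == 1.0

    def test_small_event_recovered_with_window_matched_to_its_scale(self):
        """A 60-bin (180-kb) noiseless event is one exact segment when the
        smoothing window is smaller than the event."""
        genome = GenomeSpec((("chr1", 6_000_000),), 3000)
        ev = PlantedCNV("chr1", 3_000_000, 3_180_000, 1.0)
        tumor, normal, truth = gen_rd_profiles(genome, [ev], 100.0, 0.0, seed=4)
        segs = segment_sample(tumor, normal, half_window=20)
        gains = [s for s in segs if s.call == "gain"]
        assert len(gains) == 1
        assert (gains[0].start, gains[0].end) == (3_000_000, 3_180_000)
        assert abs(gains[0].lr - 1.0) < 0.05  # shifted slightly by normalization
        assert segment_recovery(truth, segs, genome) == (1.0, 1.0)

    def test_moderate_noise_recovery_with_matched_window(self):
        """Under bin-level noise the detected plateau shrinks toward the event
        center but the event is still found with the correct sign."""
        genome = GenomeSpec((("chr1", 25_000_000),), 3000)
        events = [PlantedCNV("chr1", 5_000_000, 7_100_000, 0.6),
                  PlantedCNV("chr1", 15_000_000, 17_100_000, -0.6)]
        found_gain = found_loss = 0
        for seed in range(5):
            tumor, normal, _ = gen_rd_profiles(genome, events, 100.0, 0.1, seed=seed)
            segs = segment_sample(tumor, normal)
            found_gain += any(s.call == "gain" and s.start >= 4_000_000 and s.end <= 8_000_000
                              for s in segs)
            found_loss += any(s.call == "loss" and s.start >= 14_000_000 and s.end <= 18_000_000
                              for s in segs)
        assert found_gain == 5 and found_loss == 5


class TestFrequencyMap:
    def test_single_sample_single_gain(self, small_genome):
        calls = {"s1": [CNSegment("chr1", 100_000, 400_000, 0.5, "gain", "s1")]}
        fmap = bin_frequency_map(calls, ["s1"], small_genome, map_bin=1_000_000)
        t = fmap.table
        row = t[(t.chrom == "chr1") & (t.bin_start == 0)].iloc[0]
        assert row.gain_freq == 1.0 and row.loss_freq == 0.0
        assert t.gain_count.sum() == 1

    def test_straddling_segment_counts_in_both_bins(self, small_genome):
        calls = {"s1": [CNSegment("chr1", 900_000, 1_100_000, -0.5, "loss", "s1")]}
        fmap = bin_frequency_map(calls, ["s1"], small_genome, map_bin=1_000_000)
        t = fmap.table[fmap.table.chrom == "chr1"]
        assert t.loss_count.tolist() == [1, 1, 0]

    def test_matches_brute_force_overlap_scan(self, small_genome, rng):
        samples = [f"s{i}" for i in range(6)]
        calls = {}
        for s in samples:
            segs = []
            for _ in range(4):
                chrom = rng.choice(small_genome.names)
                start = int(rng.integers(0, 2_800_000))
                end = start + int(rng.integers(50_000, 900_000))
                end = min(end, small_genome.length(chrom))
                call = str(rng.choice(["gain", "loss", "neutral"]))
                segs.append(CNSegment(chrom, start, end, 0.5, call, s))
            calls[s] = segs
        fmap = bin_frequency_map(calls, samples, small_genome, map_bin=1_000_000)
        for row in fmap.table.itertuples():
            for kind in ("gain", "loss"):
                expected = sum(
                    any(seg.call == kind and seg.chrom == row.chrom
                        and seg.start < row.bin_end and row.bin_start < seg.end
                        for seg in calls[s])
                    for s in samples
                )
                assert getattr(row, f"{kind}_count") == expected

    def test_empty_cohort_rejected(self, small_genome):
        with pytest.raises(ValueError, match="empty cohort"):
            bin_frequency_map({}, [], small_genome)


class TestCallerIntersection:
    def test_same_sign_overlap_required(self):
        ours = classify_segments([CNSegment("chr1", 0, 200_000, 0.5),
                                  CNSegment("chr1", 200_000, 400_000, -0.5)])
        external = [CNSegment("chr1", 150_000, 160_000, 0.9, "gain"),
                    CNSegment("chr1", 250_000, 260_000, 0.9, "gain")]
        kept = intersect_with_caller(ours, external)
        assert [s.call for s in kept] == ["gain"]  # loss lacks a same-sign overlap


class TestRoundTrips:
    def test_bedgraph_round_trip(self, small_genome, tmp_path):
        tumor, _, _ = gen_rd_profiles(small_genome, [], 80.0, 0.2, seed=6)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(tumor, path)
        back = read_bedgraph(path, tissue="tumor")
        assert back.bin_size == tumor.bin_size
        for chrom in small_genome.names:
            np.testing.assert_allclose(back.bins[chrom], tumor.bins[chrom])

    def test_segment_bed_round_trip_preserves_calls_and_coords(self, tmp_path):
        segs = classify_segments([CNSegment("chr1", 0, 200_000, 0.5),
                                  CNSegment("chr1", 200_000, 201_000, 0.5),
                                  CNSegment("chr1", 201_000, 500_000, -0.31)])
        path = tmp_path / "s.bed"
        write_segments_bed(segs, path)
        back = read_segments_bed(path)
        assert [(s.chrom, s.start, s.end, s.call) for s in back] == \
               [(s.chrom, s.start, s.end, s.call) for s in segs]
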