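import numpy as np
import pytest

from acgh.caller import (
    CallingCriterion,
    CnvEvent,
    call_events,
    resolution,
    segment_track,
)
from acgh.intervals import GenomicInterval
from acgh.simulate import (
    HybridizationSpec,
    TruthCnv,
    random_truth,
    simulate_hybridization,
)
from acgh.tracks import ProbeMap, RatioTrack


def make_track(values, hyb_id="Self1", role="self"):
    import pandas as pd

    n = len(values)
    df = pd.DataFrame(
        {
            "probe": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 50,
        }
    )
    return RatioTrack(ProbeMap(df), np.asarray(values, float), hyb_id, role)


class TestResolution:
    @pytest.mark.parametrize(
        "probes,spacing,expected",
        [(5, 1200, 4800), (2, 1000, 1000), (5, 1000, 4000)],
    )
    def test_formula(self, probes, spacing, expected):
        crit = CallingCriterion(min_abs_shift=0.5, min_probes=probes)
        assert resolution(crit, spacing) == expected

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            resolution(CallingCriterion(), 0)


class TestCriterion:
    def test_validation(self):
        with pytest.raises(ValueError):
            CallingCriterion(min_abs_shift=0.0)
        with pytest.raises(ValueError):
            CallingCriterion(min_probes=1)


class TestSegmentation:
    def test_constant_track_is_one_segment(self):
        segs = segment_track(make_track(np.full(50, 0.3)))
        assert len(segs) == 1
        assert segs[0].start == 0 and segs[0].end == 50

    def test_noise_free_block_recovered_exactly(self):
        values = np.zeros(60)
        values[25:35] = 0.8
        segs = segment_track(make_track(values))
        assert [(s.start, s.end, round(s.mean_log2, 6)) for s in segs] == [
            (0, 25, 0.0),
            (25, 35, 0.8),
            (35, 60, 0.0),
        ]

    def test_segments_tile_track(self):
        rng = np.random.default_rng(0)
        track = make_track(rng.normal(0, 0.3, 200))
        segs = segment_track(track)
        assert segs[0].start == 0 and segs[-1].end == 200
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start

    def test_noisy_boundaries_within_two_probes(self, toy_map):
        df = toy_map.df
        sub = df[df["chrom"] == "chr1"]
        lo, hi = 80, 100
        iv = GenomicInterval(
            "chr1", int(sub["start"].iloc[lo]), int(sub["end"].iloc[hi - 1])
        )
        hits = 0
        for seed in range(100):
            spec = HybridizationSpec(
                "High1", "high", (TruthCnv(iv, "gain", 0.8),),
                noise_sd=0.2, seed=seed,
            )
            track, _ = simulate_hybridization(toy_map, None, spec)
            bounds = {s.start for s in segment_track(track)} | {
                s.end for s in segment_track(track)
            }
            if any(abs(b - lo) <= 2 for b in bounds) and any(
                abs(b - hi) <= 2 for b in bounds
            ):
                hits += 1
        assert hits >= 95

    def test_deterministic(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 0.2, 300)
        track = make_track(values)
        assert segment_track(track) == segment_track(track)


class TestCallEvents:
    def test_all_zero_track_has_no_events(self):
        track = make_track(np.zeros(30))
        assert call_events(segment_track(track), track) == []

    def test_ten_probe_block_called_once(self):
        values = np.zeros(30)
        values[10:20] = 0.8
        track = make_track(values)
        events = call_events(segment_track(track), track)
        assert len(events) == 1
        ev = events[0]
        assert ev.kind == "gain"
        assert ev.n_probes == 10
        assert ev.interval == GenomicInterval("chr1", 10_000, 19_050)
        assert ev.mean_log2 == pytest.approx(0.8)

    def test_four_probe_block_below_min_probes(self):
        values = np.zeros(30)
        values[10:14] = 1.0
        track = make_track(values)
        assert call_events(segment_track(track), track) == []

    def test_adjacent_same_sign_segments_fuse(self):
        values = np.zeros(40)
        values[10:15] = 0.6
        values[15:20] = 1.0
        track = make_track(values)
        events = call_events(segment_track(track), track)
        assert len(events) == 1
        assert events[0].n_probes == 10
        assert events[0].mean_log2 == pytest.approx(0.8)

    def test_opposite_signs_do_not_fuse(self):
        values = np.zeros(40)
        values[10:16] = 0.8
        values[16:22] = -0.8
        track = make_track(values)
        events = call_events(segment_track(track), track)
        assert [e.kind for e in events] == ["gain", "loss"]

    def test_masked_probes_split_runs(self):
        values = np.full(12, 0.8)
        values[6] = np.nan
        track = make_track(values)
        events = call_events(segment_track(track), track)
        # two 6- and 5-probe runs; both >= default min_probes except none split
        assert [e.n_probes for e in events] == [6, 5]

    def test_event_sign_invariant(self):
        with pytest.raises(ValueError):
            CnvEvent(GenomicInterval("chr1", 0, 10), -0.6, "gain", 5, "Self1")


class TestRecoveryAndMonotonicity:
    def test_zero_noise_planted_recovery_is_exact(self, toy_map):
        df = toy_map.df
        for seed in range(5):
            rng = np.random.default_rng(seed)
            truths = random_truth(toy_map, 4, rng)
            spec = HybridizationSpec(
                "High1", "high", tuple(truths), noise_sd=0.0, seed=seed
            )
            track, _ = simulate_hybridization(toy_map, None, spec)
            events = call_events(segment_track(track), track)
            expected = sorted(
                t.interval for t in truths
                if abs(t.log2_shift) >= 0.5
            )
            got = sorted(e.interval for e in events)
            assert len(got) == len(expected)
            for g, x in zip(got, expected):
                # event spans first to last probe midpoint-covered by truth
                assert g.chrom == x.chrom
                assert x.start <= g.start and g.end <= x.end

    def test_event_count_monotone_in_both_thresholds(self, toy_map):
        for seed in range(5):
            spec = HybridizationSpec("Self1", "self", noise_sd=0.25, seed=seed)
            track, _ = simulate_hybridization(toy_map, None, spec)
            segs = segment_track(track, penalty=0.1)
            counts = {
                (s, p): len(
                    call_events(segs, track, CallingCriterion(s, p))
                )
                for s in (0.2, 0.3, 0.4, 0.5)
                for p in (3, 4, 5, 6)
            }
            for s in (0.2, 0.3, 0.4):
                for p in (3, 4, 5, 6):
                    assert counts[(s, p)] >= counts[(round(s + 0.1, 1), p)]
            for s in (0.2, 0.3, 0.4, 0.5):
                for p in (3, 4, 5):
                    assert counts[(s, p)] >= counts[(s, p + 1)]

    def test_events_never_overlap_within_track(self, toy_map):
        for seed in range(3):
            spec = HybridizationSpec("Self1", "self", noise_sd=0.3, seed=seed)
            track, _ = simulate_hybridization(toy_map, None, spec)
            events = call_events(
                segment_track(track, penalty=0.1), track, CallingCriterion(0.2, 3)
            )
            events.sort(key=lambda e: (e.interval.chrom, e.interval.start))
            for a, b in zip(events, events[1:]):
                if a.interval.chrom == b.interval.chrom:
                    assert a.interval.end <= b.interval.start
            for e in events:
                assert (e.mean_log2 > 0) == (e.kind == "gain")
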