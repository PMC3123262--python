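import numpy as np
import pytest

from acgh.gc import probe_gc
from acgh.intervals import GenomicInterval
from acgh.simulate import (
    HybridizationSpec,
    TruthCnv,
    make_genome,
    make_probe_map,
    read_truth,
    simulate_hybridization,
    write_truth,
)


class TestMakeGenome:
    def test_gc_target_hit_within_tolerance(self, small_genome):
        assert abs(small_genome.gc_fraction - 0.417) <= 0.02

    def test_high_gc_scenario(self):
        g = make_genome({"chr1": 200_000}, gc_target=0.535, seed=3)
        assert abs(g.gc_fraction - 0.535) <= 0.02

    def test_deterministic(self):
        a = make_genome({"chr1": 50_000}, seed=5)
        b = make_genome({"chr1": 50_000}, seed=5)
        assert a.sequence("chr1") == b.sequence("chr1")
        c = make_genome({"chr1": 50_000}, seed=6)
        assert a.sequence("chr1") != c.sequence("chr1")

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_genome({}, seed=1)
        with pytest.raises(ValueError):
            make_genome({"chr1": 10}, seed=1)
        with pytest.raises(ValueError):
            make_genome({"chr1": 10_000}, gc_target=1.5, seed=1)

    def test_landscape_is_smooth(self, small_genome):
        # adjacent 100 bp blocks of the propensity field move by far less
        # than the field's overall spread (50 kb correlation length)
        land = small_genome.gc_landscape["chr1"]
        assert np.abs(np.diff(land)).max() < 0.25 * (land.max() - land.min() + 1e-9)

    def test_fasta_round_trip(self, small_genome, tmp_path):
        from pyfaidx import Fasta

        path = tmp_path / "g.fa"
        small_genome.write_fasta(path)
        fa = Fasta(str(path))
        assert str(fa["chr1"][:1000]) == small_genome.sequence("chr1")[:1000]
        assert len(fa["chr2"]) == 300_000


class TestMakeProbeMap:
    def test_probe_count_and_spacing(self, toy_build):
        pmap = make_probe_map(toy_build, mean_spacing=1200, seed=2)
        per_chrom = pmap.df.groupby("chrom").size()
        expected = 240_000 / 1200
        assert all(abs(n - expected) / expected < 0.05 for n in per_chrom)
        assert abs(pmap.mean_spacing - 1200) / 1200 < 0.05

    def test_sorted_and_non_overlapping(self, toy_map):
        for _, sub in toy_map.df.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (np.diff(starts) > 0).all()
            assert (starts[1:] >= ends[:-1]).all()

    def test_deterministic(self, toy_build):
        a = make_probe_map(toy_build, seed=9)
        b = make_probe_map(toy_build, seed=9)
        assert a.df.equals(b.df)

    def test_spacing_smaller_than_probe_rejected(self, toy_build):
        with pytest.raises(ValueError):
            make_probe_map(toy_build, mean_spacing=40, probe_length=50)

    def test_short_chromosome_gets_one_probe(self):
        from acgh.intervals import GenomeBuild

        build = GenomeBuild("tiny", (("chr1", 800),))
        pmap = make_probe_map(build, mean_spacing=1200, seed=0)
        assert len(pmap) == 1


class TestSimulateHybridization:
    def test_null_spec_gives_zero_track(self, toy_map):
        track, truth = simulate_hybridization(
            toy_map, None, HybridizationSpec("Self1", "self", noise_sd=0.0)
        )
        assert truth == []
        assert np.all(track.values == 0.0)

    def test_planted_block_is_exact(self, toy_map):
        df = toy_map.df
        sub = df[df["chrom"] == "chr1"]
        iv = GenomicInterval(
            "chr1", int(sub["start"].iloc[20]), int(sub["end"].iloc[29])
        )
        spec = HybridizationSpec(
            "High1", "high", (TruthCnv(iv, "gain", 0.8),), noise_sd=0.0
        )
        track, _ = simulate_hybridization(toy_map, None, spec)
        inside = track.values[sub.index[20:30]]
        assert np.allclose(inside, 0.8)
        assert np.count_nonzero(track.values) == 10

    def test_dye_bias_offsets_whole_track(self, toy_map):
        spec = HybridizationSpec("Self1", "self", noise_sd=0.0, dye_bias=0.1)
        track, _ = simulate_hybridization(toy_map, None, spec)
        assert np.allclose(track.values, 0.1)

    def test_deterministic_given_seed(self, toy_map):
        spec = HybridizationSpec("Self1", "self", noise_sd=0.2, seed=42)
        a, _ = simulate_hybridization(toy_map, None, spec)
        b, _ = simulate_hybridization(toy_map, None, spec)
        assert np.array_equal(a.values, b.values)

    def test_overlapping_truth_rejected(self, toy_map):
        t1 = TruthCnv(GenomicInterval("chr1", 1000, 5000), "gain", 0.8)
        t2 = TruthCnv(GenomicInterval("chr1", 4000, 9000), "loss", -0.8)
        with pytest.raises(ValueError, match="overlapping"):
            simulate_hybridization(
                toy_map, None,
                HybridizationSpec("High1", "high", (t1, t2), noise_sd=0.0),
            )

    def test_self_role_forbids_truth(self):
        with pytest.raises(ValueError):
            HybridizationSpec(
                "Self1", "self",
                (TruthCnv(GenomicInterval("chr1", 0, 10), "gain", 0.5),),
            )

    def test_truth_kind_must_match_sign(self):
        with pytest.raises(ValueError):
            TruthCnv(GenomicInterval("chr1", 0, 10), "gain", -0.5)


class TestWave:
    def test_gc_correlation_grows_with_coefficient(self, desk_genome, desk_map):
        gc = probe_gc(desk_genome, desk_map)
        corrs = []
        for coeff in (0.5, 2.0, 4.0):
            rs = []
            for seed in range(3):
                spec = HybridizationSpec(
                    "Self1", "self", noise_sd=0.2,
                    wave_coefficient=coeff, seed=seed,
                )
                track, _ = simulate_hybridization(desk_map, desk_genome, spec)
                rs.append(np.corrcoef(track.values, gc)[0, 1])
            corrs.append(np.mean(rs))
        assert corrs[0] > 0
        assert corrs[0] < corrs[1] < corrs[2]

    def test_wave_requires_genome(self, toy_map):
        with pytest.raises(ValueError):
            simulate_hybridization(
                toy_map, None,
                HybridizationSpec("Self1", "self", wave_coefficient=1.0),
            )


def test_quiet_self_tracks_stay_below_calling_criterion(toy_map):
    """At noise_sd 0.15, no 5-probe window reaches |mean| 0.5 in >=95% of seeds."""
    bad = 0
    kernel = np.ones(5) / 5
    for seed in range(20):
        spec = HybridizationSpec("Self1", "self", noise_sd=0.15, seed=seed)
        track, _ = simulate_hybridization(toy_map, None, spec)
        window_means = np.convolve(track.values, kernel, mode="valid")
        bad += bool(np.any(np.abs(window_means) >= 0.5))
    assert bad <= 1


def test_truth_file_round_trip(tmp_path):
    truths = [
        TruthCnv(GenomicInterval("chr1", 1000, 5000), "gain", 0.8123456789),
        TruthCnv(GenomicInterval("chr2", 0, 77), "loss", -0.5),
    ]
    path = tmp_path / "truth.bed"
    write_truth(truths, path)
    assert read_truth(path) == truths
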