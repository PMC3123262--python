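"""Synthetic genomes, probe maps and hybridizations with known truth.

The generator emulates the statistical structure an array-CGH pipeline has to
cope with, at desk scale:

* a multi-chromosome genome whose GC content varies smoothly around a
  configurable target (default 0.417, the bovine genome average), with
  occasional GC-rich islands a few kb wide — the local feature implicated in
  recurrent false-positive calls;
* a jittered probe map at ~1.2 kb mean spacing (the real design places ~2.1M
  probes genome-wide at that spacing; defaults here cover a 10 Mb toy genome,
  ~8,300 probes);
* per-probe log2 ratios composed of a global dye-bias offset, a GC-correlated
  genomic wave, planted copy-number shifts, and Gaussian probe noise.

Self-self hybridizations carry no true CNVs, so every event called on them is
a false positive — the property the calibration stage exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .intervals import GenomeBuild, GenomicInterval
from .tracks import ProbeMap, RatioTrack

_BASE_AT = np.frombuffer(b"AT", dtype=np.uint8)
_BASE_GC = np.frombuffer(b"GC", dtype=np.uint8)

DEFAULT_GC_TARGET = 0.417
DEFAULT_NOISE_SD = 0.2
DEFAULT_SPACING = 1200


@dataclass(frozen=True)
class TruthCnv:
    """A planted copy-number event: interval, direction and log2 shift."""

    interval: GenomicInterval
    kind: str  # "gain" | "loss"
    log2_shift: float

    def __post_init__(self) -> None:
        if self.kind not in ("gain", "loss"):
            raise ValueError(f"kind must be gain/loss, got {self.kind!r}")
        if self.log2_shift == 0:
            raise ValueError("log2_shift must be non-zero")
        if (self.log2_shift > 0) != (self.kind == "gain"):
            raise ValueError(f"kind {self.kind!r} disagrees with shift sign")


@dataclass
class HybridizationSpec:
    """Recipe for one simulated hybridization.

    ``noise_sd`` is per-probe Gaussian noise in log2 units;
    ``wave_coefficient`` scales the GC wave (log2 units per unit of GC
    fraction above the genome average); ``dye_bias`` is a global log2 offset.
    """

    hyb_id: str
    role: str = "self"
    truth: tuple[TruthCnv, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD
    wave_coefficient: float = 0.0
    dye_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.truth = tuple(self.truth)
        if self.role == "self" and self.truth:
            raise ValueError("self-self hybridizations carry no true CNVs")


class SyntheticGenome:
    """Random genome with a smooth, island-punctuated GC landscape.

    The landscape is stored at ``landscape_step`` bp resolution; bases are
    drawn independently with the local GC propensity, so the realized
    genome-wide GC fraction matches the target to within sampling error
    (the propensity field is re-centred on the target exactly).
    """

    def __init__(
        self,
        build: GenomeBuild,
        seqs: dict[str, np.ndarray],
        gc_landscape: dict[str, np.ndarray],
        landscape_step: int,
        gc_target: float,
    ) -> None:
        self.build = build
        self.seqs = seqs  # uint8 ASCII codes
        self.gc_landscape = gc_landscape
        self.landscape_step = landscape_step
        self.gc_target = gc_target
        self._gc_cumsum: dict[str, np.ndarray] = {}
        self._gc_fraction: float | None = None

    def sequence(self, chrom: str) -> str:
        return self.seqs[chrom].tobytes().decode()

    def _cumsum(self, chrom: str) -> np.ndarray:
        if chrom not in self._gc_cumsum:
            seq = self.seqs[chrom]
            is_gc = (seq == ord("G")) | (seq == ord("C"))
            cs = np.zeros(len(seq) + 1, dtype=np.int64)
            np.cumsum(is_gc, out=cs[1:])
            self._gc_cumsum[chrom] = cs
        return self._gc_cumsum[chrom]

    @property
    def gc_fraction(self) -> float:
        """Realized genome-wide GC fraction."""
        if self._gc_fraction is None:
            gc = sum(int(self._cumsum(c)[-1]) for c in self.seqs)
            total = sum(len(s) for s in self.seqs.values())
            self._gc_fraction = gc / total
        return self._gc_fraction

    def local_gc(self, chrom: str, centers: np.ndarray, window: int = 500) -> np.ndarray:
        """GC fraction of a centred window around each position."""
        cs = self._cumsum(chrom)
        length = len(self.seqs[chrom])
        centers = np.asarray(centers, dtype=np.int64)
        lo = np.clip(centers - window // 2, 0, length)
        hi = np.clip(centers + (window - window // 2), 0, length)
        width = np.maximum(hi - lo, 1)
        return (cs[hi] - cs[lo]) / width

    def write_fasta(self, path: str | Path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, _ in self.build.chromosomes:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def make_genome(
    sizes: dict[str, int],
    gc_target: float = DEFAULT_GC_TARGET,
    seed: int = 0,
    baseline_sd: float = 0.03,
    correlation_length: int = 50_000,
    island_rate_per_mb: float = 2.0,
    island_width: int = 8_000,
    island_gc_boost: float = 0.15,
    landscape_step: int = 100,
    name: str = "synth",
) -> SyntheticGenome:
    """Generate a deterministic genome with the configured GC structure.

    The GC propensity at each position is target + smooth baseline
    fluctuation (Gaussian field, ``correlation_length`` smoothing) + flat-top
    GC-rich islands (Poisson-placed, ~``island_width`` bp wide, raised by
    ``island_gc_boost``), re-centred so the weighted mean equals the target.
    """
    if not sizes:
        raise ValueError("at least one chromosome required")
    if not 0 < gc_target < 1:
        raise ValueError("GC target must be in (0, 1)")
    for chrom, length in sizes.items():
        if length < landscape_step:
            raise ValueError(f"chromosome {chrom!r} shorter than landscape step")

    root = np.random.default_rng(seed)
    build = GenomeBuild(name, tuple(sizes.items()))
    landscapes: dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        rng = np.random.default_rng(root.integers(2**31))
        n_blocks = math.ceil(length / landscape_step)
        base = rng.standard_normal(n_blocks)
        sigma = max(correlation_length / landscape_step, 1.0)
        base = gaussian_filter1d(base, sigma, mode="reflect")
        sd = base.std()
        base = base / sd * baseline_sd if sd > 0 else base * 0.0
        # flat-top islands with 500 bp cosine-free linear ramps
        island = np.zeros(n_blocks)
        n_islands = rng.poisson(island_rate_per_mb * length / 1e6)
        x = np.arange(n_blocks) * landscape_step
        ramp = 500.0
        for center in np.sort(rng.uniform(0, length, n_islands)):
            half = island_width / 2
            up = np.clip((x - (center - half)) / ramp, 0, 1)
            down = np.clip(((center + half) - x) / ramp, 0, 1)
            island = np.maximum(island, island_gc_boost * up * down)
        landscapes[chrom] = base + island

    # re-centre the propensity field so the length-weighted mean is the target
    total = sum(sizes.values())
    weighted = sum(land.sum() * landscape_step for land in landscapes.values())
    offset = weighted / total
    seqs: dict[str, np.ndarray] = {}
    for chrom, length in sizes.items():
        rng = np.random.default_rng(root.integers(2**31))
        p = np.clip(landscapes[chrom] - offset + gc_target, 0.02, 0.98)
        landscapes[chrom] = p
        p_full = np.repeat(p, landscape_step)[:length]
        is_gc = rng.random(length) < p_full
        which = rng.integers(0, 2, length)
        seq = np.where(is_gc, _BASE_GC[which], _BASE_AT[which]).astype(np.uint8)
        seqs[chrom] = seq

    return SyntheticGenome(build, seqs, landscapes, landscape_step, gc_target)


def make_probe_map(
    genome: SyntheticGenome | GenomeBuild,
    mean_spacing: int = DEFAULT_SPACING,
    probe_length: int = 50,
    seed: int = 0,
    jitter_frac: float = 0.25,
) -> ProbeMap:
    """Jittered, sorted, non-overlapping probes at the requested mean spacing.

    Jitter is uniform within ±``jitter_frac``·spacing around the regular
    grid, bounded so adjacent probes cannot overlap. A chromosome shorter
    than one spacing still receives a single centred probe when it can hold
    one.
    """
    if mean_spacing < probe_length:
        raise ValueError("mean_spacing must be >= probe_length")
    build = genome.build if isinstance(genome, SyntheticGenome) else genome
    rng = np.random.default_rng(seed)
    max_jitter = min(jitter_frac * mean_spacing, (mean_spacing - probe_length) / 2 - 1)
    frames = []
    for chrom, length in build.chromosomes:
        if length < probe_length:
            raise ValueError(f"chromosome {chrom!r} cannot hold one probe")
        n = max(int((length - probe_length) // mean_spacing), 1)
        grid = (np.arange(n) + 0.5) * (length / n) - probe_length / 2
        jitter = rng.uniform(-max_jitter, max_jitter, n) if n > 1 else np.zeros(1)
        starts = np.clip((grid + jitter).astype(np.int64), 0, length - probe_length)
        starts.sort()
        frames.append(
            pd.DataFrame(
                {
                    "probe": [
                        f"{chrom.upper()}FS{int(s):09d}" for s in starts
                    ],
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + probe_length,
                }
            )
        )
    pmap = ProbeMap(pd.concat(frames, ignore_index=True),
                    chrom_order=tuple(c for c, _ in build.chromosomes))
    return pmap


def simulate_hybridization(
    pmap: ProbeMap,
    genome: SyntheticGenome | None,
    spec: HybridizationSpec,
) -> tuple[RatioTrack, list[TruthCnv]]:
    """Simulate one hybridization track over a probe map.

    Per-probe value = dye_bias + wave_coefficient·(local GC − genome GC)
    + Σ planted shifts covering the probe + N(0, noise_sd). ``genome`` may be
    None when ``wave_coefficient`` is zero (no GC lookup needed).
    Deterministic given ``spec.seed``.
    """
    if spec.wave_coefficient != 0.0 and genome is None:
        raise ValueError("a genome is required for a non-zero GC wave")
    ivs = sorted(t.interval for t in spec.truth)
    for a, b in zip(ivs, ivs[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError("overlapping truth CNVs on one track")
    if genome is not None:
        for t in spec.truth:
            t.interval.validate_against(genome.build)

    rng = np.random.default_rng(spec.seed)
    df = pmap.df
    values = np.full(len(df), spec.dye_bias, dtype=float)

    if spec.wave_coefficient != 0.0:
        assert genome is not None
        for chrom, idx in df.groupby("chrom", sort=False).indices.items():
            mids = ((df["start"].to_numpy()[idx] + df["end"].to_numpy()[idx]) // 2)
            gc = genome.local_gc(str(chrom), mids, window=500)
            values[idx] += spec.wave_coefficient * (gc - genome.gc_fraction)

    if spec.truth:
        chroms = df["chrom"].to_numpy()
        mids = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        for t in spec.truth:
            mask = (chroms == t.interval.chrom) & (mids >= t.interval.start) & (
                mids < t.interval.end
            )
            values[mask] += t.log2_shift

    if spec.noise_sd > 0:
        values += rng.normal(0.0, spec.noise_sd, len(values))

    track = RatioTrack(
        pmap,
        values,
        hyb_id=spec.hyb_id,
        role=spec.role,
        notes={
            "seed": spec.seed,
            "noise_sd": spec.noise_sd,
            "wave_coefficient": spec.wave_coefficient,
            "dye_bias": spec.dye_bias,
        },
    )
    return track, list(spec.truth)


DEFAULT_PLAN = (
    "Self1", "High1", "Low1",
    "Self2", "High2", "Low2",
    "Self3", "High3", "Low3",
    "Self4",
)


def random_truth(
    pmap: ProbeMap,
    n_events: int,
    rng: np.random.Generator,
    span_probes: tuple[int, int] = (8, 40),
    abs_shift: tuple[float, float] = (0.6, 1.2),
    gain_fraction: float = 0.5,
) -> list[TruthCnv]:
    """Non-overlapping random CNVs snapped to probe positions.

    Spans are drawn in probes (so every event is callable at the default
    spacing) and converted to bp via the probe map; shifts are uniform in
    ``abs_shift`` with a ``gain_fraction`` chance of being a gain.
    """
    df = pmap.df
    truths: list[TruthCnv] = []
    taken: list[GenomicInterval] = []
    attempts = 0
    while len(truths) < n_events and attempts < 50 * max(n_events, 1):
        attempts += 1
        n_probes = int(rng.integers(span_probes[0], span_probes[1] + 1))
        i = int(rng.integers(0, len(df) - n_probes))
        sub = df.iloc[i : i + n_probes]
        if sub["chrom"].nunique() != 1:
            continue
        iv = GenomicInterval(
            str(sub["chrom"].iloc[0]),
            int(sub["start"].iloc[0]),
            int(sub["end"].iloc[-1]),
        )
        if any(
            iv.chrom == t.chrom and iv.start < t.end and t.start < iv.end
            for t in taken
        ):
            continue
        shift = float(rng.uniform(*abs_shift))
        gain = rng.random() < gain_fraction
        truths.append(
            TruthCnv(iv, "gain" if gain else "loss", shift if gain else -shift)
        )
        taken.append(iv)
    return truths


def simulate_cohort(
    pmap: ProbeMap,
    genome: SyntheticGenome | None,
    seed: int = 0,
    plan: tuple[str, ...] = DEFAULT_PLAN,
    noise_sd: float = DEFAULT_NOISE_SD,
    wave_coefficient: float = 0.0,
    dye_bias_sd: float = 0.02,
    cnvs_per_comparative: int = 10,
) -> dict[str, tuple[RatioTrack, list[TruthCnv]]]:
    """Simulate a full hybridization plan (self controls + comparisons).

    Self hybridizations get no planted CNVs; comparative ("High"/"Low")
    hybridizations get ``cnvs_per_comparative`` random ones. Every track
    receives its own dye-bias offset (N(0, ``dye_bias_sd``)) and seed, all
    derived deterministically from ``seed``.
    """
    root = np.random.default_rng(seed)
    cohort: dict[str, tuple[RatioTrack, list[TruthCnv]]] = {}
    for hyb_id in plan:
        role = next(r for r in ("self", "high", "low") if hyb_id.lower().startswith(r))
        truth_rng = np.random.default_rng(root.integers(2**31))
        truth = (
            random_truth(pmap, cnvs_per_comparative, truth_rng)
            if role != "self" and cnvs_per_comparative > 0
            else []
        )
        spec = HybridizationSpec(
            hyb_id=hyb_id,
            role=role,
            truth=tuple(truth),
            noise_sd=noise_sd,
            wave_coefficient=wave_coefficient,
            dye_bias=float(root.normal(0.0, dye_bias_sd)),
            seed=int(root.integers(2**31)),
        )
        cohort[hyb_id] = simulate_hybridization(pmap, genome, spec)
    return cohort


# -- truth-set text round trip ---------------------------------------------

def write_truth(truths: list[TruthCnv], path: str | Path) -> None:
    """BED-style truth file: chrom start end kind log2_shift."""
    with open(path, "w") as fh:
        for t in truths:
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}"
                f"\t{t.kind}\t{t.log2_shift!r}\n"
            )


def read_truth(path: str | Path) -> list[TruthCnv]:
    truths = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, kind, shift = line.split("\t")
        truths.append(
            TruthCnv(GenomicInterval(chrom, int(start), int(end)), kind, float(shift))
        )
    return truths
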