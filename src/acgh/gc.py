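"""GC-content profiling of genomes and called events.

Recurrent false-positive CGH calls sit preferentially in GC-rich
neighbourhoods (the genomic-wave artifact); comparing the GC fraction of
each called region against the genome average (0.417 for the bovine
reference) is the descriptive evidence for that mechanism. Profiles use
browser-style tiling windows (default 5 bp, matching a "GC percent in
5-base windows" track).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CnvEvent
from .intervals import GenomicInterval
from .simulate import SyntheticGenome


class AllMissingSequence(ValueError):
    """GC fraction of a sequence with no unambiguous bases is undefined."""


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T), case-insensitive; N bases excluded."""
    if not seq:
        raise ValueError("empty sequence")
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    if gc + at == 0:
        raise AllMissingSequence("sequence contains no A/C/G/T bases")
    return gc / (gc + at)


@dataclass
class GcProfile:
    """Tiled GC-fraction track along one sequence."""

    window: int
    starts: np.ndarray
    fractions: np.ndarray
    genome_average: float | None = None

    def to_bedgraph(self, chrom: str, path: str | Path, seq_length: int) -> None:
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="GC%_{self.window}bp"\n')
            for s, f in zip(self.starts, self.fractions):
                end = min(s + self.window, seq_length)
                fh.write(f"{chrom}\t{s}\t{end}\t{f:.4f}\n")


def windowed_gc(seq: str, window: int = 5, step: int | None = None) -> GcProfile:
    """GC fraction in tiling windows (step defaults to the window width).

    The trailing partial window is scored over its actual length. A sliding
    step < window gives a smoother profile for plotting.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    step = window if step is None else step
    starts = np.arange(0, len(seq), step)
    starts = starts[starts < len(seq)]
    fractions = np.array(
        [gc_fraction(seq[s : s + window]) for s in starts], dtype=float
    )
    return GcProfile(window, starts, fractions)


class FastaGenome:
    """Indexed FASTA access presenting the same GC interface as a synthetic
    genome (uses pyfaidx; the index file is built on first use)."""

    def __init__(self, path: str | Path):
        from pyfaidx import Fasta

        self.fasta = Fasta(str(path))

    def region_seq(self, interval: GenomicInterval) -> str:
        return str(self.fasta[interval.chrom][interval.start : interval.end])

    @property
    def gc_fraction(self) -> float:
        gc = at = 0
        for name in self.fasta.keys():
            seq = str(self.fasta[name][:]).upper()
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
        return gc / (gc + at)

    def chrom_length(self, chrom: str) -> int:
        return len(self.fasta[chrom])


def _region_seq(genome: SyntheticGenome | FastaGenome, iv: GenomicInterval) -> str:
    if isinstance(genome, SyntheticGenome):
        iv.validate_against(genome.build)
        return genome.sequence(iv.chrom)[iv.start : iv.end]
    if iv.end > genome.chrom_length(iv.chrom):
        raise ValueError(f"{iv} exceeds chromosome bounds")
    return genome.region_seq(iv)


def region_vs_genome(
    events: Sequence[CnvEvent | GenomicInterval],
    genome: SyntheticGenome | FastaGenome,
    genome_average: float | None = None,
) -> pd.DataFrame:
    """Per-event GC context: region GC, genome GC, and their difference.

    ``excess`` > 0 marks an event in a GC-rich neighbourhood relative to the
    genome average (computed from the supplied genome unless given). The
    returned frame also carries ``n_positive_excess`` in ``df.attrs``.
    """
    if genome_average is None:
        genome_average = genome.gc_fraction
    rows = []
    for e in events:
        iv = e.interval if isinstance(e, CnvEvent) else e
        region_gc = gc_fraction(_region_seq(genome, iv))
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "region_gc": region_gc,
                "genome_gc": genome_average,
                "excess": region_gc - genome_average,
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "region_gc", "genome_gc", "excess"]
    )
    df.attrs["n_positive_excess"] = int((df["excess"] > 0).sum()) if len(df) else 0
    return df


def probe_gc(
    genome: SyntheticGenome,
    probe_map,
    window: int = 500,
) -> np.ndarray:
    """Local GC fraction for each probe: a centred ``window`` bp around the
    probe midpoint (neighbourhood GC, not probe-sequence GC, drives the
    wave artifact)."""
    df = probe_map.df
    out = np.empty(len(df))
    for chrom, idx in df.groupby("chrom", sort=False).indices.items():
        mids = (df["start"].to_numpy()[idx] + df["end"].to_numpy()[idx]) // 2
        out[idx] = genome.local_gc(str(chrom), mids, window=window)
    return out
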