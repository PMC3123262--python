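"""Genomic interval data model and arithmetic.

Coordinates are 0-based half-open throughout, so ``span = end - start``.
Published event tables that print Length = End - Start are ingested as-is,
without any coordinate shift. Unplaced scaffolds (e.g. ``chrU``) are ordinary
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO


@dataclass(frozen=True)
class GenomeBuild:
    """Named assembly: an ordered list of (chromosome, length) pairs."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for chrom, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, name: str | None = None) -> "GenomeBuild":
        """Read a UCSC-style two-column chrom.sizes file."""
        path = Path(path)
        chroms = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            chroms.append((chrom, int(size)))
        return cls(name or path.stem, tuple(chroms))

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{n}\n" for c, n in self.chromosomes)
        )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self}")

    @property
    def span(self) -> int:
        return self.end - self.start

    def validate_against(self, build: GenomeBuild) -> None:
        size = build.sizes.get(self.chrom)
        if size is None:
            raise ValueError(f"{self.chrom!r} not in build {build.name!r}")
        if self.end > size:
            raise ValueError(f"{self} exceeds {self.chrom} length {size}")

    def __str__(self) -> str:  # chr1:100-200
        return f"{self.chrom}:{self.start}-{self.end}"


def span(interval: GenomicInterval) -> int:
    """Length in bp of a half-open interval (end - start)."""
    return interval.span


def overlaps(a: GenomicInterval, b: GenomicInterval, max_gap: int = 0) -> bool:
    """True iff the intervals share a chromosome and overlap.

    With ``max_gap > 0`` intervals separated by at most that many bases also
    count; the default requires >= 1 bp of genuine overlap (abutting half-open
    intervals do not overlap).
    """
    if a.chrom != b.chrom:
        return False
    if max_gap <= 0:
        return a.start < b.end and b.start < a.end
    return a.start <= b.end + max_gap and b.start <= a.end + max_gap


def merge_intervals(
    intervals: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Union of intervals as a minimal sorted list of disjoint intervals.

    Idempotent; empty input gives empty output. ``max_gap`` additionally fuses
    intervals separated by at most that many bases.
    """
    items = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end + max_gap:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


# ---------------------------------------------------------------------------
# BED I/O (BED3 / BED6; array CGH is strandless so strand is written as ".")

def read_bed(source: str | Path | TextIO) -> list[tuple[GenomicInterval, str, float]]:
    """Read BED3+ records as (interval, name, score) tuples."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    records = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
        name = parts[3] if len(parts) > 3 else "."
        score = float(parts[4]) if len(parts) > 4 else 0.0
        records.append((iv, name, score))
    return records


def write_bed(
    records: Sequence[tuple[GenomicInterval, str, float]] | Sequence[GenomicInterval],
    dest: str | Path | TextIO,
) -> None:
    """Write BED6 (or BED3 when given bare intervals)."""
    lines = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            lines.append(f"{rec.chrom}\t{rec.start}\t{rec.end}")
        else:
            iv, name, score = rec
            lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t.")
    text = "\n".join(lines) + ("\n" if lines else "")
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)
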