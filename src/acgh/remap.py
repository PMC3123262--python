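"""Minimal UCSC chain-file interval remapping between assemblies.

Implements enough of the liftOver model to migrate event intervals from one
assembly to another: parse block-structured chain alignments, pick the
best-scoring chain covering an interval, and map it when at least
``min_match`` of its bases fall inside aligned blocks of that single chain.
Split mappings (bases aligned by more than one chain but no single chain
sufficient) and deletions (bases falling in alignment gaps) are reported as
distinct failure reasons rather than patched together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .intervals import GenomicInterval


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped alignment block, in chain-local coordinates."""

    size: int
    dt: int  # gap on the source (target-assembly "t" side of the header) after the block
    dq: int  # gap on the destination ("q" side) after the block


@dataclass
class ChainAlignment:
    """A UCSC chain record: colinear blocks aligning source to destination.

    Coordinates follow the chain-format convention: ``q_start``/``q_end``
    count from the 5' end of the + strand, or of the reverse-complement when
    ``q_strand`` is '-'.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    blocks: tuple[ChainBlock, ...]
    chain_id: int = 0

    def __post_init__(self) -> None:
        if self.q_strand not in "+-":
            raise ValueError(f"bad strand {self.q_strand!r}")
        if not (0 <= self.t_start < self.t_end <= self.t_size):
            raise ValueError(f"chain {self.chain_id}: t coordinates out of range")
        if not (0 <= self.q_start < self.q_end <= self.q_size):
            raise ValueError(f"chain {self.chain_id}: q coordinates out of range")
        t_span = sum(b.size + b.dt for b in self.blocks)
        q_span = sum(b.size + b.dq for b in self.blocks)
        if t_span != self.t_end - self.t_start or q_span != self.q_end - self.q_start:
            raise ValueError(f"chain {self.chain_id}: blocks do not sum to spans")

    def aligned_pairs(self) -> Iterable[tuple[int, int, int]]:
        """Yield (t_block_start, q_block_start, size) in forward coordinates
        of each assembly's + strand (q flipped for - strand chains)."""
        t = self.t_start
        q = self.q_start
        for b in self.blocks:
            if self.q_strand == "+":
                yield t, q, b.size
            else:
                yield t, self.q_size - (q + b.size), b.size
            t += b.size + b.dt
            q += b.size + b.dq


class ChainParseError(ValueError):
    pass


def read_chain(source: str | Path | TextIO) -> list[ChainAlignment]:
    """Parse a UCSC chain file; malformed lines are reported with numbers."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []
    header_line = 0

    def finish() -> None:
        nonlocal header, blocks
        if header is None:
            return
        try:
            (_, score, t_name, t_size, t_strand, t_start, t_end,
             q_name, q_size, q_strand, q_start, q_end, *rest) = header
            if t_strand != "+":
                raise ValueError("source strand must be '+' per chain format")
            chains.append(
                ChainAlignment(
                    float(score), t_name, int(t_size), int(t_start), int(t_end),
                    q_name, int(q_size), q_strand, int(q_start), int(q_end),
                    tuple(blocks), int(rest[0]) if rest else 0,
                )
            )
        except (ValueError, IndexError) as exc:
            raise ChainParseError(f"line {header_line}: {exc}") from exc
        header, blocks = None, []

    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            finish()
            header = line.split()
            header_line = lineno
            if len(header) < 12:
                raise ChainParseError(f"line {lineno}: truncated chain header")
        else:
            parts = line.split()
            if header is None:
                raise ChainParseError(f"line {lineno}: block line outside a chain")
            try:
                if len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ValueError("expected 1 or 3 fields")
            except ValueError as exc:
                raise ChainParseError(f"line {lineno}: {exc}") from exc
    finish()
    return chains


def write_chain(chains: Sequence[ChainAlignment], dest: str | Path | TextIO) -> None:
    lines = []
    for c in chains:
        lines.append(
            f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} {c.t_end} "
            f"{c.q_name} {c.q_size} {c.q_strand} {c.q_start} {c.q_end} {c.chain_id}"
        )
        for b in c.blocks[:-1]:
            lines.append(f"{b.size}\t{b.dt}\t{b.dq}")
        lines.append(f"{c.blocks[-1].size}")
        lines.append("")
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        Path(dest).write_text(text)


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap source and destination of a +/+ chain (used for round trips)."""
    if chain.q_strand != "+":
        raise ValueError("only +/+ chains can be inverted directly")
    return ChainAlignment(
        chain.score, chain.q_name, chain.q_size, chain.q_start, chain.q_end,
        chain.t_name, chain.t_size, "+", chain.t_start, chain.t_end,
        tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks),
        chain.chain_id,
    )


@dataclass(frozen=True)
class RemapResult:
    mapped: GenomicInterval | None
    reason: str  # "mapped" | "unmapped" | "deleted" | "split" | "partial"
    chain_id: int | None = None
    matched_fraction: float = 0.0

    @property
    def ok(self) -> bool:
        return self.mapped is not None


def _chain_overlap(chain: ChainAlignment, iv: GenomicInterval) -> int:
    """Bases of ``iv`` inside aligned blocks of ``chain``."""
    total = 0
    for t0, _, size in chain.aligned_pairs():
        lo = max(t0, iv.start)
        hi = min(t0 + size, iv.end)
        if hi > lo:
            total += hi - lo
    return total


def remap_interval(
    chains: Sequence[ChainAlignment],
    interval: GenomicInterval,
    min_match: float = 0.95,
) -> RemapResult:
    """Map an interval to the destination assembly via the best single chain.

    Succeeds iff at least ``min_match`` of the interval's bases lie in
    aligned blocks of one chain (the highest-scoring chain overlapping the
    interval). The mapped interval spans the extreme destination positions
    of the intersected blocks. Failure reasons:

    - ``unmapped``: no chain's span touches the interval;
    - ``deleted``: the interval sits inside one chain's span but too much of
      it falls in alignment gaps;
    - ``split``: no single chain suffices but a second chain also aligns
      part of the interval.
    """
    candidates = [
        (c, _chain_overlap(c, interval))
        for c in chains
        if c.t_name == interval.chrom
        and c.t_start < interval.end
        and interval.start < c.t_end
    ]
    if not candidates:
        return RemapResult(None, "unmapped")
    candidates.sort(key=lambda pair: (-pair[0].score, -pair[1]))
    best, best_ov = candidates[0]
    frac = best_ov / interval.span
    if frac < min_match:
        others = sum(ov for _, ov in candidates[1:])
        reason = "split" if others > 0 else "deleted"
        return RemapResult(None, reason, best.chain_id, frac)
    if best_ov == 0:
        return RemapResult(None, "deleted", best.chain_id, 0.0)
    q_positions: list[int] = []
    for t0, q0, size in best.aligned_pairs():
        lo = max(t0, interval.start)
        hi = min(t0 + size, interval.end)
        if hi > lo:
            if best.q_strand == "+":
                q_positions.extend((q0 + (lo - t0), q0 + (hi - t0)))
            else:
                # q0 is already the forward-strand start of the flipped block
                q_positions.extend(
                    (q0 + (t0 + size - hi), q0 + (t0 + size - lo))
                )
    mapped = GenomicInterval(best.q_name, min(q_positions), max(q_positions))
    return RemapResult(mapped, "mapped", best.chain_id, frac)


def remap_bed(
    chains: Sequence[ChainAlignment],
    intervals: Sequence[GenomicInterval],
    min_match: float = 0.95,
) -> tuple[list[tuple[GenomicInterval, GenomicInterval]], list[tuple[GenomicInterval, str]]]:
    """Batch remap: returns (mapped pairs, unmapped with reasons)."""
    mapped, failed = [], []
    for iv in intervals:
        res = remap_interval(chains, iv, min_match=min_match)
        if res.ok:
            assert res.mapped is not None
            mapped.append((iv, res.mapped))
        else:
            failed.append((iv, res.reason))
    return mapped, failed
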