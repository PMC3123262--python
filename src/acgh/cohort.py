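"""Cross-hybridization triage of called events.

Events recurring across independent hybridizations — same locus called in
different test/reference pairs — are unlikely to be genuine sample
differences and point to systematic artifacts (dye bias, GC waves). This
module flags shared events, merges the pooled event list into unique loci,
applies the >10 kb size class, and summarizes per-hybridization counts.

The shared flag is sign-agnostic: the published large-event table marks
loci shared between gains in one hybridization and losses in another (e.g.
the recurrent chr25:32.4 Mb locus), so requiring matching direction would
not reproduce it. Direction agreement is reported separately as
``same_type``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .caller import CnvEvent
from .intervals import GenomicInterval, merge_intervals, overlaps
from .tracks import role_of


@dataclass
class EventCohort:
    """Event sets keyed by hybridization id, with role labels."""

    events: dict[str, list[CnvEvent]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hyb_id, evs in self.events.items():
            for e in evs:
                if e.hyb_id != hyb_id:
                    raise ValueError(
                        f"event {e.interval} carries hyb_id {e.hyb_id!r} under key {hyb_id!r}"
                    )
            self.roles.setdefault(hyb_id, role_of(hyb_id))

    @classmethod
    def from_events(cls, events: Iterable[CnvEvent],
                    roles: Mapping[str, str] | None = None) -> "EventCohort":
        by_hyb: dict[str, list[CnvEvent]] = {}
        for e in events:
            by_hyb.setdefault(e.hyb_id, []).append(e)
        return cls(by_hyb, dict(roles) if roles else {})

    @property
    def all_events(self) -> list[CnvEvent]:
        return [e for evs in self.events.values() for e in evs]

    def subset(self, hyb_ids: Sequence[str]) -> "EventCohort":
        return EventCohort(
            {h: list(self.events[h]) for h in hyb_ids},
            {h: self.roles[h] for h in hyb_ids},
        )

    def counts(self) -> pd.Series:
        return pd.Series({h: len(evs) for h, evs in self.events.items()}, name="events")


@dataclass(frozen=True)
class SharedAnnotation:
    """Per-event sharing flags, aligned with ``cohort.all_events`` order."""

    shared: tuple[bool, ...]
    partners: tuple[tuple[str, ...], ...]
    same_type: tuple[bool, ...]


def classify_shared(cohort: EventCohort, max_gap: int = 0) -> SharedAnnotation:
    """Flag events that overlap an event from a *different* hybridization.

    Overlap (optionally within ``max_gap`` bp) on the same chromosome
    suffices regardless of gain/loss direction; ``same_type`` is True when
    the event is shared and every partner has the same direction. Symmetric:
    if A lists B as a partner, B lists A.
    """
    events = cohort.all_events
    shared = [False] * len(events)
    partners: list[set[str]] = [set() for _ in events]
    same_type = [False] * len(events)
    by_chrom: dict[str, list[int]] = {}
    for idx, e in enumerate(events):
        by_chrom.setdefault(e.interval.chrom, []).append(idx)
    for idxs in by_chrom.values():
        for ai in range(len(idxs)):
            for bi in range(ai + 1, len(idxs)):
                a, b = events[idxs[ai]], events[idxs[bi]]
                if a.hyb_id == b.hyb_id:
                    continue
                if overlaps(a.interval, b.interval, max_gap=max_gap):
                    shared[idxs[ai]] = shared[idxs[bi]] = True
                    partners[idxs[ai]].add(b.hyb_id)
                    partners[idxs[bi]].add(a.hyb_id)
    for idx, e in enumerate(events):
        if shared[idx]:
            partner_kinds = {
                p.kind
                for j, p in enumerate(events)
                if p.hyb_id in partners[idx]
                and overlaps(p.interval, e.interval, max_gap=max_gap)
            }
            same_type[idx] = partner_kinds == {e.kind}
    return SharedAnnotation(
        tuple(shared),
        tuple(tuple(sorted(p)) for p in partners),
        tuple(same_type),
    )


@dataclass(frozen=True)
class Locus:
    interval: GenomicInterval
    members: tuple[CnvEvent, ...]


def unique_loci(cohort: EventCohort, max_gap: int = 0) -> list[Locus]:
    """Merge the pooled event list into unique loci with member events."""
    events = cohort.all_events
    merged = merge_intervals([e.interval for e in events], max_gap=max_gap)
    loci = []
    for iv in merged:
        members = tuple(
            e for e in events if overlaps(e.interval, iv, max_gap=max_gap)
        )
        loci.append(Locus(iv, members))
    return loci


def size_filter(events: Sequence[CnvEvent], min_span: int = 10_000) -> list[CnvEvent]:
    """Keep events strictly larger than ``min_span`` bp; order preserved."""
    return [e for e in events if e.span > min_span]


def summarize(cohort: EventCohort, max_gap: int = 0,
              large_span: int = 10_000) -> dict:
    """Headline cohort statistics.

    Returns per-hybridization counts plus totals, the unique-locus count,
    and shared fractions overall and among events larger than
    ``large_span`` bp.
    """
    counts = cohort.counts()
    roles = pd.Series(cohort.roles)
    comparative = counts[roles.reindex(counts.index).isin(["high", "low"])]
    events = cohort.all_events
    ann = classify_shared(cohort, max_gap=max_gap)
    n_shared = int(sum(ann.shared))
    large_idx = [i for i, e in enumerate(events) if e.span > large_span]
    n_large_shared = int(sum(ann.shared[i] for i in large_idx))
    summary = {
        "per_hyb": counts.to_dict(),
        "total_events": int(counts.sum()),
        "n_hybridizations": int(len(counts)),
        "unique_loci": len(unique_loci(cohort, max_gap=max_gap)),
        "shared_events": n_shared,
        "shared_fraction": n_shared / len(events) if events else 0.0,
        "large_events": len(large_idx),
        "large_shared_events": n_large_shared,
        "large_shared_fraction": (
            n_large_shared / len(large_idx) if large_idx else 0.0
        ),
    }
    if len(comparative):
        summary["comparative"] = {
            "min": int(comparative.min()),
            "max": int(comparative.max()),
            "mean": float(comparative.mean()),
        }
    selfs = counts[roles.reindex(counts.index) == "self"]
    if len(selfs):
        summary["self"] = {
            "min": int(selfs.min()),
            "max": int(selfs.max()),
            "mean": float(selfs.mean()),
        }
    return summary


# -- manifest I/O -----------------------------------------------------------

def write_manifest(cohort_paths: Mapping[str, tuple[str, str]], path: str | Path) -> None:
    """TSV manifest of (hyb_id, role, events-file path)."""
    with open(path, "w") as fh:
        fh.write("hyb_id\trole\tevents_path\n")
        for hyb_id, (role, events_path) in cohort_paths.items():
            fh.write(f"{hyb_id}\t{role}\t{events_path}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
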