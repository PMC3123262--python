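"""Criterion selection against self-self control hybridizations.

Self-self hybridizations compare a sample against itself, so every event
called on them is a false positive by construction. The calibration sweep
counts false-positive events over a grid of (log2-shift, probe-count)
criteria and picks the least stringent criterion whose false-positive total
fits a budget — reproducing the procedure that selected (0.5, 5) for the
real arrays, where that criterion left minimal false positives on the
controls.

The self tracks contain no true events, so a false-discovery *rate* has no
denominator here; the grid stores false-positive event counts, and an
empirical FDR proxy (mean self-track events / mean comparative-track
events) is available when comparative tracks are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import CallingCriterion, call_events, segment_track
from .tracks import RatioTrack

DEFAULT_SHIFTS = (0.3, 0.4, 0.5, 0.6, 0.7)
DEFAULT_PROBE_COUNTS = (3, 4, 5, 6, 7)


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationGrid:
    """False-positive event totals per (shift, probe-count) cell."""

    shift_values: tuple[float, ...]
    probe_counts: tuple[int, ...]
    fp_counts: np.ndarray  # shape (len(shifts), len(probe_counts))
    n_self_tracks: int

    def count(self, shift: float, probes: int) -> int:
        i = self.shift_values.index(shift)
        j = self.probe_counts.index(probes)
        return int(self.fp_counts[i, j])

    def validate_monotone(self) -> None:
        """Counts must be non-increasing along both axes (stricter criterion,
        fewer events)."""
        if np.any(np.diff(self.fp_counts, axis=0) > 0) or np.any(
            np.diff(self.fp_counts, axis=1) > 0
        ):
            raise CalibrationError("false-positive counts are not monotone in the grid")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fp_counts,
            index=pd.Index(self.shift_values, name="min_abs_shift"),
            columns=pd.Index(self.probe_counts, name="min_probes"),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def sweep(
    self_tracks: Sequence[RatioTrack],
    shift_values: Sequence[float] = DEFAULT_SHIFTS,
    probe_counts: Sequence[int] = DEFAULT_PROBE_COUNTS,
    segment_penalty: float | None = None,
) -> CalibrationGrid:
    """Count false-positive events on self tracks for every grid cell.

    Each track is segmented once (segmentation does not depend on the
    criterion); each cell then applies its criterion to the same segments.
    The default segmentation penalty is matched to the laxest grid cell
    (half the squared-error gain of its marginal event,
    0.5·min_probes·min_shift²) so that candidate events at every cell's
    scale can surface — a variance-based penalty would suppress
    sub-threshold segments and leave the sweep vacuous.
    """
    if not self_tracks:
        raise CalibrationError("at least one self track required")
    for track in self_tracks:
        if track.role != "self":
            raise CalibrationError(
                f"track {track.hyb_id!r} has role {track.role!r}; sweep expects self-self controls"
            )
    shifts = tuple(sorted(shift_values))
    probes = tuple(sorted(probe_counts))
    if segment_penalty is None:
        segment_penalty = 0.5 * probes[0] * shifts[0] ** 2
    counts = np.zeros((len(shifts), len(probes)), dtype=int)
    for track in self_tracks:
        segments = segment_track(track, penalty=segment_penalty)
        for i, s in enumerate(shifts):
            for j, p in enumerate(probes):
                crit = CallingCriterion(min_abs_shift=s, min_probes=p)
                counts[i, j] += len(call_events(segments, track, crit))
    grid = CalibrationGrid(shifts, probes, counts, len(self_tracks))
    grid.validate_monotone()
    return grid


def select_criterion(grid: CalibrationGrid, fp_budget: int = 0) -> CallingCriterion:
    """Least-stringent criterion meeting the false-positive budget.

    Cells are scanned in increasing shift, then increasing probe count; the
    first cell with total false positives ≤ ``fp_budget`` wins (the chosen
    criterion limits resolution as little as possible). If no cell meets the
    budget, the global-minimum cell is returned, ties broken the same way.
    """
    for i, s in enumerate(grid.shift_values):
        for j, p in enumerate(grid.probe_counts):
            if grid.fp_counts[i, j] <= fp_budget:
                return CallingCriterion(min_abs_shift=s, min_probes=p)
    i, j = np.unravel_index(int(np.argmin(grid.fp_counts)), grid.fp_counts.shape)
    return CallingCriterion(
        min_abs_shift=grid.shift_values[int(i)], min_probes=grid.probe_counts[int(j)]
    )


def empirical_fdr_proxy(
    self_tracks: Sequence[RatioTrack],
    comparative_tracks: Sequence[RatioTrack],
    criterion: CallingCriterion = CallingCriterion(),
    segment_penalty: float | None = None,
) -> float:
    """Mean self-track events / mean comparative-track events.

    A crude upper-bound proxy for the fraction of comparative calls
    attributable to noise; NaN when the comparative mean is zero.
    """
    def mean_events(tracks: Sequence[RatioTrack]) -> float:
        counts = [
            len(call_events(segment_track(t, penalty=segment_penalty), t, criterion))
            for t in tracks
        ]
        return float(np.mean(counts)) if counts else float("nan")

    denom = mean_events(comparative_tracks)
    if not denom:
        return float("nan")
    return mean_events(self_tracks) / denom
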