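"""Probe maps and per-probe log2-ratio tracks, with their text formats.

A hybridization is represented by a :class:`RatioTrack`: one log2(test/ref)
value per probe of a shared :class:`ProbeMap`. Tracks are exchanged as a
5-column TSV (probe id, chrom, start, end, log2 ratio) or as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("self", "high", "low")


@dataclass
class ProbeMap:
    """Ordered, non-overlapping genomic probe positions.

    ``df`` has columns ``probe, chrom, start, end``, sorted by chromosome
    (in map order) then start.
    """

    df: pd.DataFrame
    chrom_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        required = {"probe", "chrom", "start", "end"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"probe map needs columns {sorted(required)}")
        if not self.chrom_order:
            self.chrom_order = tuple(dict.fromkeys(self.df["chrom"]))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def mean_spacing(self) -> float:
        """Mean start-to-start distance between adjacent probes, per chromosome."""
        gaps = []
        for _, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            if len(starts) > 1:
                gaps.append(np.diff(starts))
        if not gaps:
            return float("nan")
        return float(np.concatenate(gaps).mean())

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.df["start"].to_numpy() + self.df["end"].to_numpy()) // 2)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class RatioTrack:
    """Per-probe log2 ratios for one hybridization.

    ``role`` follows the hybridization-plan vocabulary: ``self`` for
    same-sample control hybridizations (any call is a false positive by
    construction), ``high``/``low`` for comparative hybridizations against
    derived lines of high or low cloning efficiency.
    """

    probes: ProbeMap
    values: np.ndarray
    hyb_id: str
    role: str
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.probes):
            raise ValueError("one value per probe required")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray, note: str | None = None) -> "RatioTrack":
        new = replace(self, values=np.asarray(values, dtype=float),
                      notes=dict(self.notes))
        if note:
            steps = list(new.notes.get("steps", []))
            steps.append(note)
            new.notes["steps"] = steps
        return new

    # -- text formats -------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.probes.df.copy()
        out["log2_ratio"] = self.values
        with open(path, "w") as fh:
            fh.write(f"# hyb_id={self.hyb_id} role={self.role}")
            for key, val in sorted(self.notes.items()):
                if np.isscalar(val):
                    fh.write(f" {key}={val}")
            fh.write("\n")
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RatioTrack":
        header = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        header[key] = val
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        values = df.pop("log2_ratio").to_numpy()
        return cls(ProbeMap(df), values,
                   hyb_id=header.get("hyb_id", "unknown"),
                   role=header.get("role", "self"),
                   notes={k: v for k, v in header.items()
                          if k not in ("hyb_id", "role")})

    def to_bedgraph(self, path: str | Path) -> None:
        df = self.probes.df
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="{self.hyb_id}"\n')
            for chrom, start, end, val in zip(
                df["chrom"], df["start"], df["end"], self.values
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{val:.6g}\n")


def role_of(hyb_id: str) -> str:
    """Map a hybridization label like ``Self3``/``High1``/``Low2`` to its role."""
    for role in ROLES:
        if hyb_id.lower().startswith(role):
            return role
    raise ValueError(f"cannot infer role from hybridization id {hyb_id!r}")
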