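"""Packaged reference tables from the published bovine cell-line study.

Two small fixtures ship with the package:

* the hybridization plan — ten test/reference pairs (three founder
  self-self controls plus the sequenced-reference Dominette control, and six
  founder-vs-derived comparisons) with their genome-wide event counts;
* the large-event table — the 58 called events larger than 10 kb, with
  coordinates, segment-mean log2 ratio ("Log R") and the printed
  shared-across-hybridizations flag.

Loaders verify structural integrity on every load: row counts, the
Length = End − Start identity for all 58 events, and the role vocabulary.
Coordinates keep their printed thousands separators in the files and are
parsed leniently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .caller import CnvEvent
from .cohort import EventCohort
from .intervals import GenomicInterval

TABLE1 = "table1_hybridizations.tsv"
TABLE2 = "table2_events.tsv"


class FixtureIntegrityError(ValueError):
    pass


def _read(name: str) -> pd.DataFrame:
    with resources.files("acgh.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def _parse_int(value: str) -> int:
    return int(str(value).replace(",", ""))


def load_table1_fixture() -> pd.DataFrame:
    """Hybridization plan: No, Test, Ref, Type, Events (10 rows)."""
    df = _read(TABLE1)
    if len(df) != 10:
        raise FixtureIntegrityError(f"expected 10 hybridizations, found {len(df)}")
    df["No"] = df["No"].map(_parse_int)
    df["Events"] = df["Events"].map(_parse_int)
    selfs = df[df["Test"] == df["Ref"]]
    if not selfs["Type"].str.startswith("Self").all():
        raise FixtureIntegrityError("self-self rows must be typed Self*")
    return df


@dataclass
class LargeEventTable:
    """The packaged >10 kb event table as an :class:`EventCohort` plus the
    printed Shared flags (aligned with ``cohort.all_events``)."""

    cohort: EventCohort
    frame: pd.DataFrame
    printed_shared: tuple[bool, ...]


def load_table2_fixture() -> LargeEventTable:
    """Load and verify the 58 large (>10 kb) events across 10 hybridizations."""
    df = _read(TABLE2)
    if len(df) != 58:
        raise FixtureIntegrityError(f"expected 58 events, found {len(df)}")
    for col in ("Start", "End", "Length"):
        df[col] = df[col].map(_parse_int)
    df["Log R"] = df["Log R"].astype(float)
    bad = df[df["Length"] != df["End"] - df["Start"]]
    if len(bad):
        raise FixtureIntegrityError(
            f"Length != End - Start for rows {bad.index.tolist()}"
        )
    if set(df["Shared"]) - {"Yes", "No"}:
        raise FixtureIntegrityError("Shared column must be Yes/No")
    events: dict[str, list[CnvEvent]] = {}
    for _, row in df.iterrows():
        ev = CnvEvent(
            GenomicInterval(row["Chr"], row["Start"], row["End"]),
            float(row["Log R"]),
            "gain" if row["Log R"] > 0 else "loss",
            n_probes=0,  # probe counts are not published
            hyb_id=row["Type"],
        )
        events.setdefault(row["Type"], []).append(ev)
    if len(events) != 10:
        raise FixtureIntegrityError(f"expected 10 hybridizations, found {len(events)}")
    cohort = EventCohort(events)
    return LargeEventTable(
        cohort=cohort,
        frame=df,
        printed_shared=tuple(df["Shared"] == "Yes"),
    )
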