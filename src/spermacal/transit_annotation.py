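"""Transit timing, phenotype classification, and population-assay tables.

Each ovulation is annotated with up to four timepoints: (1) start of oocyte
entry, (2) distal neck closure, (3) sp-ut valve opening, (4) sp-ut valve
closure.  From these the entry, dwell, exit and total transit times are
derived.  Dwell time (neck closure to valve opening) can legitimately be
negative when the valve starts opening before the neck has fully closed.

Population assays score each spermatheca into one of four categories
(unoccupied / occupied / small piece or liquid / emo); the statistics
downstream compare unoccupied against the pooled rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "EventRecord",
    "TransitTimes",
    "TransitPhenotype",
    "PopulationTable",
    "POPULATION_CATEGORIES",
    "compute_transit_times",
    "classify_transit",
    "score_population",
    "read_events_csv",
    "write_transits_csv",
    "read_population_csv",
]

POPULATION_CATEGORIES = ("unoccupied", "occupied", "small_piece_or_liquid", "emo")


class TransitPhenotype(str, Enum):
    EXITED_SUCCESSFULLY = "exited_successfully"
    TRAPPED = "trapped"
    RETURNED_TO_GONAD_ARM = "returned_to_gonad_arm"
    VALVE_OPENS_NO_EXIT = "valve_opens_no_exit"


@dataclass
class EventRecord:
    """Annotated timepoints (frame indices) and outcome flags for one ovulation."""

    entry_start: int | None = None
    neck_close: int | None = None
    valve_open: int | None = None
    valve_close: int | None = None
    embryo_exited: bool = False
    returned_to_gonad: bool = False
    observation_end: int | None = None

    def __post_init__(self) -> None:
        if self.valve_close is not None and self.valve_open is None:
            raise ValueError("valve_close requires valve_open")
        if (
            self.entry_start is not None
            and self.observation_end is not None
            and self.entry_start > self.observation_end
        ):
            raise ValueError("entry_start must not exceed observation_end")


@dataclass
class TransitTimes:
    """Entry/dwell/exit/total intervals in seconds; missing timepoints give None."""

    entry_time: float | None
    dwell_time: float | None
    exit_time: float | None
    total_transit: float | None


def compute_transit_times(events: EventRecord, dt: float = 1.0) -> TransitTimes:
    """Convert the four annotated timepoints into interval durations.

    entry = neck_close - entry_start; dwell = valve_open - neck_close (may be
    negative); exit = valve_close - valve_open; total = valve_close -
    entry_start.  Any interval whose endpoints are not both annotated is None.
    """
    if events.entry_start is None:
        raise ValueError("entry_start annotation is required")
    e, n, o, c = events.entry_start, events.neck_close, events.valve_open, events.valve_close
    entry = (n - e) * dt if n is not None else None
    dwell = (o - n) * dt if (o is not None and n is not None) else None
    exit_ = (c - o) * dt if (c is not None and o is not None) else None
    total = (c - e) * dt if c is not None else None
    return TransitTimes(entry, dwell, exit_, total)


def classify_transit(events: EventRecord) -> TransitPhenotype:
    """Assign exactly one transit phenotype to an ovulation.

    Rule order: a reflux into the gonad arm dominates; otherwise an opened
    valve with a confirmed exit is a successful transit; an opened valve
    without exit is its own category; and with the valve never opening the
    embryo is trapped.
    """
    if events.embryo_exited and events.valve_open is None:
        raise ValueError("inconsistent annotation: embryo_exited requires valve_open")
    if events.returned_to_gonad:
        return TransitPhenotype.RETURNED_TO_GONAD_ARM
    if events.valve_open is not None and events.embryo_exited:
        return TransitPhenotype.EXITED_SUCCESSFULLY
    if events.valve_open is not None:
        return TransitPhenotype.VALVE_OPENS_NO_EXIT
    return TransitPhenotype.TRAPPED


@dataclass
class PopulationTable:
    """Per-condition category counts from a population assay."""

    counts: dict[str, dict[str, int]]

    def n(self, condition: str) -> int:
        return sum(self.counts[condition].values())

    def occupancy_fraction(self, condition: str) -> float:
        """1 - unoccupied/n: the fraction of spermathecae showing any occupancy."""
        n = self.n(condition)
        return 1.0 - self.counts[condition]["unoccupied"] / n

    def unoccupied_vs_rest(self, condition: str) -> tuple[int, int]:
        row = self.counts[condition]
        unocc = row["unoccupied"]
        return unocc, self.n(condition) - unocc

    @property
    def conditions(self) -> list[str]:
        return list(self.counts)


def score_population(records) -> PopulationTable:
    """Tabulate (condition, category) records into per-condition counts.

    `records` is an iterable of (condition, category) pairs, one spermatheca
    each.  Unknown categories and an empty input are errors.
    """
    counts: dict[str, dict[str, int]] = {}
    total = 0
    for condition, category in records:
        if category not in POPULATION_CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {POPULATION_CATEGORIES}"
            )
        row = counts.setdefault(condition, {c: 0 for c in POPULATION_CATEGORIES})
        row[category] += 1
        total += 1
    if total == 0:
        raise ValueError("no records to score")
    return PopulationTable(counts)


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def read_events_csv(path) -> dict[str, EventRecord]:
    """Read per-ovulation event annotations.

    Columns: ovulation_id, entry_start, neck_close, valve_open, valve_close,
    exited, returned, observation_end.  Empty cells mean "not annotated".
    """
    df = pd.read_csv(path, dtype={"ovulation_id": str})
    records = {}
    for _, row in df.iterrows():
        records[row["ovulation_id"]] = EventRecord(
            entry_start=_opt_int(row.get("entry_start")),
            neck_close=_opt_int(row.get("neck_close")),
            valve_open=_opt_int(row.get("valve_open")),
            valve_close=_opt_int(row.get("valve_close")),
            embryo_exited=bool(_opt_int(row.get("exited")) or 0),
            returned_to_gonad=bool(_opt_int(row.get("returned")) or 0),
            observation_end=_opt_int(row.get("observation_end")),
        )
    return records


def write_transits_csv(records: dict[str, EventRecord], path, dt: float = 1.0) -> pd.DataFrame:
    """Compute times + phenotype for every record and write one CSV row each."""
    rows = []
    for ovid, ev in records.items():
        tt = compute_transit_times(ev, dt)
        rows.append(
            {
                "ovulation_id": ovid,
                "entry_time_s": tt.entry_time,
                "dwell_time_s": tt.dwell_time,
                "exit_time_s": tt.exit_time,
                "total_transit_s": tt.total_transit,
                "phenotype": classify_transit(ev).value,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_population_csv(path) -> PopulationTable:
    """Read a long-format population CSV (condition, category, count)."""
    df = pd.read_csv(path)
    counts: dict[str, dict[str, int]] = {}
    for _, row in df.iterrows():
        category = str(row["category"])
        if category not in POPULATION_CATEGORIES:
            raise ValueError(
                f"unknown category {category!r}; expected one of {POPULATION_CATEGORIES}"
            )
        cond = counts.setdefault(str(row["condition"]), {c: 0 for c in POPULATION_CATEGORIES})
        cond[category] += int(row["count"])
    if not counts:
        raise ValueError("population table is empty")
    return PopulationTable(counts)
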