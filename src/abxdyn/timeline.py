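"""Timeline tables of antibacterial drug classes and censored interval sets.

A timeline table holds one row per drug class with three calendar years:
the year the class was first discovered, the year it entered clinical use
(optional) and the year resistance to it was first detected (optional).
A class with no recorded resistance year is right-censored: by the chosen
observation year it had accrued exposure time but no event.

Years are integer calendar years and durations are integer year
differences — the resolution of the underlying historical record.
Fractional years are rejected on input.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import TimelineFormatError, TimelineValidationError

REQUIRED_COLUMNS = ("class_name", "discovery_year", "clinical_use_year", "resistance_year")


@dataclass(frozen=True)
class TimelineRecord:
    """One drug class: discovery, optional clinical use, optional resistance."""

    class_name: str
    discovery_year: int
    clinical_use_year: int | None = None
    resistance_year: int | None = None


@dataclass
class TimelineTable:
    """A validated collection of :class:`TimelineRecord`, order-preserving.

    Invariants (enforced on construction):

    * class names are non-empty and unique;
    * every record has an integer discovery year;
    * clinical_use_year and resistance_year, when present, are >= the
      discovery year.
    """

    records: list[TimelineRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, TimelineTable) and self.records == other.records

    @property
    def discovery_years(self) -> np.ndarray:
        return np.array([r.discovery_year for r in self.records], dtype=int)

    @property
    def resistance_years(self) -> np.ndarray:
        """Resistance years of the uncensored records only."""
        return np.array(
            [r.resistance_year for r in self.records if r.resistance_year is not None],
            dtype=int,
        )

    def max_year(self) -> int:
        """Largest calendar year appearing anywhere in the table."""
        if not self.records:
            raise TimelineValidationError("empty table has no years")
        years: list[int] = []
        for r in self.records:
            years.append(r.discovery_year)
            if r.clinical_use_year is not None:
                years.append(r.clinical_use_year)
            if r.resistance_year is not None:
                years.append(r.resistance_year)
        return max(years)

    def to_frame(self) -> pd.DataFrame:
        """Render as a pandas DataFrame with nullable integer year columns."""
        return pd.DataFrame(
            {
                "class_name": [r.class_name for r in self.records],
                "discovery_year": pd.array(
                    [r.discovery_year for r in self.records], dtype="Int64"
                ),
                "clinical_use_year": pd.array(
                    [r.clinical_use_year for r in self.records], dtype="Int64"
                ),
                "resistance_year": pd.array(
                    [r.resistance_year for r in self.records], dtype="Int64"
                ),
            }
        )


def validate_records(records: Sequence[TimelineRecord]) -> None:
    """Raise :class:`TimelineValidationError` on any invariant violation."""
    seen: set[str] = set()
    for i, r in enumerate(records):
        where = f"row {i} ({r.class_name!r})"
        if not r.class_name:
            raise TimelineValidationError(f"row {i}: empty class_name")
        if r.class_name in seen:
            raise TimelineValidationError(f"{where}: duplicate class_name")
        seen.add(r.class_name)
        for fieldname in ("discovery_year", "clinical_use_year", "resistance_year"):
            v = getattr(r, fieldname)
            if v is not None and not isinstance(v, (int, np.integer)):
                raise TimelineValidationError(f"{where}: {fieldname} is not an integer year")
        if r.clinical_use_year is not None and r.clinical_use_year < r.discovery_year:
            raise TimelineValidationError(
                f"{where}: clinical_use_year {r.clinical_use_year} precedes "
                f"discovery_year {r.discovery_year}"
            )
        if r.resistance_year is not None and r.resistance_year < r.discovery_year:
            raise TimelineValidationError(
                f"{where}: resistance_year {r.resistance_year} precedes "
                f"discovery_year {r.discovery_year}"
            )


def _parse_year(text: str, column: str, row: int, required: bool) -> int | None:
    text = text.strip()
    if text == "":
        if required:
            raise TimelineValidationError(f"row {row}: missing {column}")
        return None
    try:
        return int(text)
    except ValueError:
        raise TimelineValidationError(
            f"row {row}: non-integer {column} value {text!r}"
        ) from None


def read_timelines(path: str | Path) -> TimelineTable:
    """Read a class-timeline CSV into a validated :class:`TimelineTable`.

    The canonical dialect is UTF-8, comma-separated, with a required header
    row ``class_name,discovery_year,clinical_use_year,resistance_year``;
    an empty cell encodes a missing value. Row order is preserved.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise TimelineFormatError(f"{path}: empty file, no header") from None
        header = [h.strip() for h in header]
        if len(set(header)) != len(header):
            raise TimelineFormatError(f"{path}: duplicate header columns in {header}")
        missing = set(REQUIRED_COLUMNS) - set(header)
        if missing:
            raise TimelineFormatError(f"{path}: missing header columns {sorted(missing)}")
        col = {name: header.index(name) for name in REQUIRED_COLUMNS}
        records: list[TimelineRecord] = []
        for i, row in enumerate(reader):
            if len(row) < len(header):
                raise TimelineFormatError(f"{path}: row {i} has {len(row)} cells, expected {len(header)}")
            records.append(
                TimelineRecord(
                    class_name=row[col["class_name"]].strip(),
                    discovery_year=_parse_year(row[col["discovery_year"]], "discovery_year", i, True),
                    clinical_use_year=_parse_year(row[col["clinical_use_year"]], "clinical_use_year", i, False),
                    resistance_year=_parse_year(row[col["resistance_year"]], "resistance_year", i, False),
                )
            )
    return TimelineTable(records)


def write_timelines(table: TimelineTable, path: str | Path) -> None:
    """Write a table in the canonical CSV dialect (empty cell = missing).

    ``read_timelines(write_timelines(t))`` reproduces ``t`` exactly, and the
    write is byte-stable across round trips.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for r in table.records:
            writer.writerow(
                [
                    r.class_name,
                    r.discovery_year,
                    "" if r.clinical_use_year is None else r.clinical_use_year,
                    "" if r.resistance_year is None else r.resistance_year,
                ]
            )


@dataclass
class IntervalSet:
    """Discovery-to-resistance durations with right-censoring flags.

    ``durations[i]`` is years from discovery to resistance detection when
    ``censored[i]`` is False, otherwise years of resistance-free exposure
    up to ``observation_year``.
    """

    durations: np.ndarray
    censored: np.ndarray
    class_names: tuple[str, ...]
    observation_year: int

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored must have the same length")
        if np.any(self.durations < 0):
            raise TimelineValidationError("negative duration in interval set")

    def __len__(self) -> int:
        return len(self.durations)

    @property
    def n_events(self) -> int:
        return int(np.sum(~self.censored))

    @property
    def n_censored(self) -> int:
        return int(np.sum(self.censored))

    @property
    def total_exposure(self) -> float:
        return float(np.sum(self.durations))

    def events_only(self) -> "IntervalSet":
        """The uncensored subset (observed resistance intervals)."""
        keep = ~self.censored
        return IntervalSet(
            self.durations[keep],
            self.censored[keep],
            tuple(n for n, k in zip(self.class_names, keep) if k),
            self.observation_year,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_name": list(self.class_names),
                "duration": self.durations.astype(int),
                "censored": self.censored,
            }
        )


def compute_intervals(table: TimelineTable, observation_year: int | None = None) -> IntervalSet:
    """Derive censored discovery-to-resistance intervals from a table.

    Records with a resistance year contribute an event of duration
    ``resistance_year - discovery_year``; the rest are right-censored at
    ``observation_year`` (default: the maximum year anywhere in the table).
    Zero-duration events (resistance detected in the discovery year) are
    kept — pre-existing environmental resistance makes them biologically
    meaningful.
    """
    if not table.records:
        raise TimelineValidationError("cannot derive intervals from an empty table")
    if observation_year is None:
        observation_year = table.max_year()
    max_disc = int(table.discovery_years.max())
    if observation_year < max_disc:
        raise TimelineValidationError(
            f"observation_year {observation_year} precedes a discovery year ({max_disc}); "
            "cannot censor before discovery"
        )
    durations, censored, names = [], [], []
    for r in table.records:
        if r.resistance_year is not None:
            durations.append(r.resistance_year - r.discovery_year)
            censored.append(False)
        else:
            durations.append(observation_year - r.discovery_year)
            censored.append(True)
        names.append(r.class_name)
    return IntervalSet(np.array(durations, float), np.array(censored, bool), tuple(names), int(observation_year))
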