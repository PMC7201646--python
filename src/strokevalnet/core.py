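"""OMOP-lite longitudinal data model and its CSV interchange format.

A "database" in the network study is three tables:

* ``person.csv``              — ``person_id,sex,year_of_birth``
* ``observation_period.csv``  — ``person_id,start_date,end_date``
* ``event.csv``               — ``person_id,date,code,domain,visit_context``

Dates are ISO-8601 calendar dates; all window arithmetic downstream is in
whole days. ``visit_context`` is denormalised onto the event because the only
visit distinction the validation needs is inpatient/ER versus everything else.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import pandas as pd

PERSON_TABLE = "person.csv"
PERIOD_TABLE = "observation_period.csv"
EVENT_TABLE = "event.csv"

PERSON_COLUMNS = ("person_id", "sex", "year_of_birth")
PERIOD_COLUMNS = ("person_id", "start_date", "end_date")
EVENT_COLUMNS = ("person_id", "date", "code", "domain", "visit_context")

SEXES = ("female", "male")
DOMAINS = ("condition", "drug", "procedure", "measurement", "observation")
VISIT_CONTEXTS = ("inpatient", "er", "outpatient", "none")

MIN_BIRTH_YEAR = 1900


class DatabaseFormatError(ValueError):
    """A CSV table is missing, malformed, or violates referential integrity."""


@dataclasses.dataclass
class LongitudinalDatabase:
    """Persons, observation periods, and dated coded events with visit context."""

    name: str
    persons: pd.DataFrame
    periods: pd.DataFrame
    events: pd.DataFrame

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LongitudinalDatabase):
            return NotImplemented
        return (
            self.name == other.name
            and self.persons.reset_index(drop=True).equals(other.persons.reset_index(drop=True))
            and self.periods.reset_index(drop=True).equals(other.periods.reset_index(drop=True))
            and self.events.reset_index(drop=True).equals(other.events.reset_index(drop=True))
        )


@dataclasses.dataclass(frozen=True)
class Violation:
    """One data-integrity violation; violations are data, not exceptions."""

    person_id: str
    rule: str
    detail: str


def _parse_dates(series: pd.Series, table: str, column: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # header line is 1
        raise DatabaseFormatError(
            f"{table}: malformed date {series[bad.idxmax()]!r} in column "
            f"{column!r} at line {row} (expected YYYY-MM-DD)"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise DatabaseFormatError(f"{table}: missing date in column {column!r} at line {row}")
    return parsed


def _check_columns(df: pd.DataFrame, expected: tuple, table: str) -> None:
    if tuple(df.columns) != expected:
        raise DatabaseFormatError(
            f"{table}: expected header {','.join(expected)}, found {','.join(df.columns)}"
        )


def _check_membership(series: pd.Series, allowed: tuple, table: str, column: str) -> None:
    bad = ~series.isin(allowed)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise DatabaseFormatError(
            f"{table}: unknown {column} {series[bad.idxmax()]!r} at line {row}; "
            f"allowed: {', '.join(allowed)}"
        )


def load_database(path: Union[str, Path], name: str | None = None) -> LongitudinalDatabase:
    """Load the three CSV tables from ``path`` and enforce referential integrity.

    Raises :class:`DatabaseFormatError` (with table and line number) for a
    missing table, malformed date, unknown sex/domain/visit_context, or an
    event/period referencing an unknown ``person_id``.
    """
    path = Path(path)
    for table in (PERSON_TABLE, PERIOD_TABLE, EVENT_TABLE):
        if not (path / table).is_file():
            raise DatabaseFormatError(f"missing table {table} in {path}")

    persons = pd.read_csv(path / PERSON_TABLE, dtype=str, keep_default_na=False)
    _check_columns(persons, PERSON_COLUMNS, PERSON_TABLE)
    _check_membership(persons["sex"], SEXES, PERSON_TABLE, "sex")
    try:
        persons["year_of_birth"] = persons["year_of_birth"].astype(int)
    except ValueError as exc:
        raise DatabaseFormatError(f"{PERSON_TABLE}: malformed year_of_birth ({exc})") from exc

    periods = pd.read_csv(path / PERIOD_TABLE, dtype=str, keep_default_na=False)
    _check_columns(periods, PERIOD_COLUMNS, PERIOD_TABLE)
    periods["start_date"] = _parse_dates(periods["start_date"], PERIOD_TABLE, "start_date")
    periods["end_date"] = _parse_dates(periods["end_date"], PERIOD_TABLE, "end_date")

    events = pd.read_csv(path / EVENT_TABLE, dtype=str, keep_default_na=False)
    _check_columns(events, EVENT_COLUMNS, EVENT_TABLE)
    events["date"] = _parse_dates(events["date"], EVENT_TABLE, "date")
    _check_membership(events["domain"], DOMAINS, EVENT_TABLE, "domain")
    _check_membership(events["visit_context"], VISIT_CONTEXTS, EVENT_TABLE, "visit_context")

    known = set(persons["person_id"])
    if len(known) != len(persons):
        dupes = persons.loc[persons["person_id"].duplicated(), "person_id"].unique()
        raise DatabaseFormatError(f"{PERSON_TABLE}: duplicate person_id {', '.join(dupes)}")
    for table, frame in ((PERIOD_TABLE, periods), (EVENT_TABLE, events)):
        unknown = sorted(set(frame["person_id"]) - known)
        if unknown:
            raise DatabaseFormatError(
                f"{table}: unknown person_id {', '.join(unknown[:5])}"
                + (" ..." if len(unknown) > 5 else "")
            )

    return LongitudinalDatabase(name or path.name, persons, periods, events)


def save_database(db: LongitudinalDatabase, path: Union[str, Path]) -> Path:
    """Write the canonical CSV dialect: UTF-8, comma-separated, LF, YYYY-MM-DD."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    persons = db.persons.loc[:, list(PERSON_COLUMNS)]
    persons.to_csv(path / PERSON_TABLE, index=False, lineterminator="\n")

    periods = db.periods.loc[:, list(PERIOD_COLUMNS)].copy()
    for col in ("start_date", "end_date"):
        periods[col] = periods[col].dt.strftime("%Y-%m-%d")
    periods.to_csv(path / PERIOD_TABLE, index=False, lineterminator="\n")

    events = db.events.loc[:, list(EVENT_COLUMNS)].copy()
    events["date"] = events["date"].dt.strftime("%Y-%m-%d")
    events.to_csv(path / EVENT_TABLE, index=False, lineterminator="\n")
    return path


def validate_database(db: LongitudinalDatabase) -> list[Violation]:
    """Check every structural invariant; empty list iff the database is consistent.

    Rules reported: ``duplicate-person``, ``birth-year-implausible``,
    ``unknown-person``, ``period-date-order``, ``periods-overlap``,
    ``event-in-period``, ``bad-domain``, ``bad-visit-context``.
    """
    out: list[Violation] = []
    persons, periods, events = db.persons, db.periods, db.events

    for pid in persons.loc[persons["person_id"].duplicated(), "person_id"].unique():
        out.append(Violation(pid, "duplicate-person", "person_id appears more than once"))

    current_year = pd.Timestamp.now().year
    bad_year = persons[
        (persons["year_of_birth"] < MIN_BIRTH_YEAR) | (persons["year_of_birth"] > current_year)
    ]
    for _, row in bad_year.iterrows():
        out.append(
            Violation(row["person_id"], "birth-year-implausible", f"year_of_birth={row['year_of_birth']}")
        )

    known = set(persons["person_id"])
    for label, frame in (("observation period", periods), ("event", events)):
        for pid in sorted(set(frame["person_id"]) - known):
            out.append(Violation(pid, "unknown-person", f"{label} references unknown person_id"))

    rev = periods[periods["start_date"] > periods["end_date"]]
    for _, row in rev.iterrows():
        out.append(
            Violation(
                row["person_id"],
                "period-date-order",
                f"start {row['start_date'].date()} after end {row['end_date'].date()}",
            )
        )

    srt = periods.sort_values(["person_id", "start_date"])
    same = srt["person_id"] == srt["person_id"].shift()
    overlap = same & (srt["start_date"] <= srt["end_date"].shift())
    for _, row in srt[overlap].iterrows():
        out.append(
            Violation(
                row["person_id"],
                "periods-overlap",
                f"period starting {row['start_date'].date()} overlaps the previous period",
            )
        )

    if len(events):
        ev = events.reset_index(drop=True).reset_index(names="_row")
        merged = ev[["_row", "person_id", "date"]].merge(
            periods[["person_id", "start_date", "end_date"]], on="person_id", how="left"
        )
        inside = (merged["start_date"] <= merged["date"]) & (merged["date"] <= merged["end_date"])
        covered = inside.groupby(merged["_row"]).any()
        for row_idx in covered.index[~covered]:
            row = ev.iloc[int(row_idx)]
            if row["person_id"] not in known:
                continue  # already reported as unknown-person
            out.append(
                Violation(
                    row["person_id"],
                    "event-in-period",
                    f"event {row['code']} on {row['date'].date()} outside all observation periods",
                )
            )

        for _, row in events[~events["domain"].isin(DOMAINS)].iterrows():
            out.append(Violation(row["person_id"], "bad-domain", f"domain={row['domain']!r}"))
        for _, row in events[~events["visit_context"].isin(VISIT_CONTEXTS)].iterrows():
            out.append(
                Violation(row["person_id"], "bad-visit-context", f"visit_context={row['visit_context']!r}")
            )

    return out
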