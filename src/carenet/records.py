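"""Reading, validating and writing care-activity record tables.

A record table has one row per documented application of one care activity to
one case (an inpatient stay), with the columns

    Patient_ID, Care_Activity, Date_Time, N_Provider, Care_Time

where ``Care_Time`` is the duration of the application in minutes and
``Date_Time`` is a timestamp at minute resolution.  This is the granularity at
which standardized care-activity catalogs (LEP-style systems) document care in
electronic health records.

Validation never raises: implausible rows are excluded and logged, so the
caller always sees exactly which rows were dropped and why.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import RecordParseError, SchemaError

#: Column order of the canonical CSV schema.
SCHEMA = ("Patient_ID", "Care_Activity", "Date_Time", "N_Provider", "Care_Time")

#: Single declared timestamp dialect; override via ``timestamp_format=``.
DEFAULT_TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

#: Default per-application plausibility cap, in minutes.
DEFAULT_MAX_CARE_TIME = 340.0


@dataclass(frozen=True)
class CareActivityRecord:
    """One documented application of one care activity to one case."""

    case_id: str
    activity: str
    timestamp: datetime
    n_providers: int
    care_time: float  # minutes


@dataclass
class RecordSet:
    """An ordered collection of :class:`CareActivityRecord` with provenance."""

    records: tuple[CareActivityRecord, ...]
    source: str = ""

    def __post_init__(self) -> None:
        self.records = tuple(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CareActivityRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def total_care_time(self) -> float:
        return sum(r.care_time for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Return the records as a DataFrame in schema column order."""
        return pd.DataFrame(
            {
                "Patient_ID": [r.case_id for r in self.records],
                "Care_Activity": [r.activity for r in self.records],
                "Date_Time": [r.timestamp for r in self.records],
                "N_Provider": [r.n_providers for r in self.records],
                "Care_Time": [r.care_time for r in self.records],
            }
        )


@dataclass(frozen=True)
class ValidationRules:
    """Exclusion rules applied by :func:`validate_records`.

    ``max_care_time`` is a plausibility bound on a single application; the
    default mirrors the largest per-activity care time observed in routine
    maternity data.  Set it to ``None`` to disable the cap.  Values are never
    imputed — implausible rows are dropped.
    """

    max_care_time: float | None = DEFAULT_MAX_CARE_TIME


@dataclass(frozen=True)
class Exclusion:
    """One excluded record together with its position and the reason."""

    index: int  # position within the input RecordSet
    record: CareActivityRecord
    reason: str


def read_records(
    path: str | Path,
    *,
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT,
    source: str | None = None,
) -> RecordSet:
    """Read a care-activity record CSV into a :class:`RecordSet`.

    Raises :class:`SchemaError` if a schema column is missing and
    :class:`RecordParseError` (carrying the 1-based data-row index) if a
    timestamp, provider count or care time cannot be parsed.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in SCHEMA if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            records.append(_parse_row(row, i, timestamp_format))
    return RecordSet(tuple(records), source=source if source is not None else str(path))


def _parse_row(row: dict, index: int, timestamp_format: str) -> CareActivityRecord:
    try:
        ts = datetime.strptime(row["Date_Time"], timestamp_format)
    except (TypeError, ValueError) as exc:
        raise RecordParseError(index, f"unparseable Date_Time {row['Date_Time']!r}") from exc
    try:
        n_prov = int(row["N_Provider"])
    except (TypeError, ValueError) as exc:
        raise RecordParseError(index, f"non-integer N_Provider {row['N_Provider']!r}") from exc
    try:
        care_time = float(row["Care_Time"])
    except (TypeError, ValueError) as exc:
        raise RecordParseError(index, f"non-numeric Care_Time {row['Care_Time']!r}") from exc
    return CareActivityRecord(
        case_id=row["Patient_ID"],
        activity=row["Care_Activity"],
        timestamp=ts,
        n_providers=n_prov,
        care_time=care_time,
    )


def validate_records(
    rs: RecordSet, rules: ValidationRules | None = None
) -> tuple[RecordSet, list[Exclusion]]:
    """Drop implausible records, returning the kept set and an exclusion log.

    Excluded are records with nonpositive care time, care time above the
    configurable cap, or fewer than one provider.  Validation is idempotent.
    """
    rules = rules or ValidationRules()
    kept: list[CareActivityRecord] = []
    log: list[Exclusion] = []
    for i, rec in enumerate(rs):
        if rec.care_time <= 0:
            log.append(Exclusion(i, rec, "nonpositive care_time"))
        elif rules.max_care_time is not None and rec.care_time > rules.max_care_time:
            log.append(Exclusion(i, rec, "exceeds cap"))
        elif rec.n_providers < 1:
            log.append(Exclusion(i, rec, "n_providers < 1"))
        else:
            kept.append(rec)
    return RecordSet(tuple(kept), source=rs.source), log


def write_records(
    rs: RecordSet,
    path: str | Path,
    *,
    timestamp_format: str = DEFAULT_TIMESTAMP_FORMAT,
) -> Path:
    """Write a :class:`RecordSet` as CSV; round-trips through :func:`read_records`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEMA)
        for r in rs:
            writer.writerow(
                [
                    r.case_id,
                    r.activity,
                    r.timestamp.strftime(timestamp_format),
                    r.n_providers,
                    _format_minutes(r.care_time),
                ]
            )
    return path


def _format_minutes(x: float) -> str:
    # integers without a trailing ".0"; other floats via repr so they
    # round-trip exactly
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def concat(record_sets: Iterable[RecordSet], source: str = "") -> RecordSet:
    """Concatenate several record sets preserving order."""
    recs: list[CareActivityRecord] = []
    for rs in record_sets:
        recs.extend(rs.records)
    return RecordSet(tuple(recs), source=source)
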