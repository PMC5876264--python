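"""CSV readers/writers for injury records, with row-level validation.

Dialect: UTF-8, comma-separated, mandatory header row.  Column order is
documented but parsing is order-insensitive; missing values are empty
cells.  Rows violating record invariants are excluded with row-numbered
reasons rather than aborting the whole read, and every exclusion is logged
so the input -> analyzed + excluded accounting can be reconstructed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .errors import SchemaError, ValidationError
from .rubric import ComponentScores, InjuryRecord, Location, Muscle

__all__ = [
    "COLUMNS",
    "SCORE_COLUMNS",
    "Exclusion",
    "ReadResult",
    "read_records",
    "load_records",
    "write_records",
    "write_scored_records",
]

log = logging.getLogger(__name__)

#: Documented column order of the record CSV.
COLUMNS = (
    "athlete_id",
    "age",
    "mri_positive",
    "n_muscles",
    "primary_muscle",
    "location",
    "insertion_involved",
    "transverse_pct",
    "retraction_cm",
    "sagittal_extent_cm",
    "rts_days",
)

SCORE_COLUMNS = (
    "age_score",
    "muscles_score",
    "location_score",
    "insertion_score",
    "transverse_score",
    "retraction_score",
    "sagittal_score",
    "total_score",
)

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n", ""}


def _parse_bool(cell: str, field: str) -> bool:
    v = cell.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValidationError(f"cannot parse boolean {cell!r}", field=field)


def _parse_float(cell: str, field: str) -> Optional[float]:
    v = cell.strip()
    if not v:
        return None
    try:
        return float(v)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number {cell!r}", field=field) from exc


def _parse_int(cell: str, field: str) -> Optional[int]:
    v = _parse_float(cell, field)
    if v is None:
        return None
    if not float(v).is_integer():
        raise ValidationError(f"{field} must be an integer, got {cell!r}", field=field)
    return int(v)


@dataclass(frozen=True)
class Exclusion:
    row: int  # 1-based data-row number (header not counted)
    athlete_id: str
    reason: str


@dataclass(frozen=True)
class ReadResult:
    records: list[InjuryRecord]
    exclusions: list[Exclusion]

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.exclusions)


def _row_to_record(row: dict[str, str]) -> InjuryRecord:
    mri_positive = _parse_bool(row["mri_positive"], "mri_positive")
    age = _parse_float(row["age"], "age")
    if age is None:
        raise ValidationError("missing age", field="age")
    transverse = _parse_float(row["transverse_pct"], "transverse_pct")
    if transverse is None:
        if mri_positive:
            # mirrors the clinical exclusion of scans lacking this reading
            raise ValidationError("missing cross-sectional area", field="transverse_pct")
        transverse = 0.0
    muscle_cell = row["primary_muscle"].strip()
    location_cell = row["location"].strip()
    try:
        primary = Muscle(muscle_cell) if muscle_cell else None
    except ValueError as exc:
        raise ValidationError(f"unknown muscle {muscle_cell!r}", field="primary_muscle") from exc
    try:
        location = Location(location_cell) if location_cell else None
    except ValueError as exc:
        raise ValidationError(f"unknown location {location_cell!r}", field="location") from exc
    record = InjuryRecord(
        athlete_id=row["athlete_id"].strip(),
        age=age,
        mri_positive=mri_positive,
        n_muscles=_parse_int(row["n_muscles"], "n_muscles") or 0,
        primary_muscle=primary,
        location=location,
        insertion_involved=_parse_bool(row["insertion_involved"], "insertion_involved"),
        transverse_pct=transverse,
        retraction_cm=_parse_float(row["retraction_cm"], "retraction_cm") or 0.0,
        sagittal_extent_cm=_parse_float(row["sagittal_extent_cm"], "sagittal_extent_cm") or 0.0,
        rts_days=_parse_int(row["rts_days"], "rts_days"),
    )
    record.validate()
    return record


def load_records(path: str | Path) -> ReadResult:
    """Read a record CSV, excluding invalid rows with row-numbered reasons."""
    path = Path(path)
    records: list[InjuryRecord] = []
    exclusions: list[Exclusion] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_row_to_record(row))
            except ValidationError as exc:
                excl = Exclusion(row=i, athlete_id=row.get("athlete_id", "").strip(), reason=str(exc))
                exclusions.append(excl)
                log.warning("%s row %d (%s): excluded: %s", path.name, i, excl.athlete_id, excl.reason)
    n_negative = sum(1 for r in records if not r.mri_positive)
    log.info(
        "%s: %d rows read, %d records kept (%d MRI-negative), %d excluded",
        path.name, len(records) + len(exclusions), len(records), n_negative, len(exclusions),
    )
    return ReadResult(records=records, exclusions=exclusions)


def read_records(path: str | Path) -> list[InjuryRecord]:
    """Convenience wrapper returning only the valid records."""
    return load_records(path).records


def _record_to_row(record: InjuryRecord) -> dict[str, object]:
    return {
        "athlete_id": record.athlete_id,
        "age": record.age if record.age != int(record.age) else int(record.age),
        "mri_positive": "true" if record.mri_positive else "false",
        "n_muscles": record.n_muscles,
        "primary_muscle": record.primary_muscle.value if record.primary_muscle else "",
        "location": record.location.value if record.location else "",
        "insertion_involved": "true" if record.insertion_involved else "false",
        "transverse_pct": record.transverse_pct,
        "retraction_cm": record.retraction_cm,
        "sagittal_extent_cm": record.sagittal_extent_cm,
        "rts_days": record.rts_days if record.rts_days is not None else "",
    }


def write_records(records: Sequence[InjuryRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(COLUMNS))
        writer.writeheader()
        for record in records:
            writer.writerow(_record_to_row(record))


def write_scored_records(
    records: Sequence[InjuryRecord],
    scores: Sequence[ComponentScores],
    path: str | Path,
) -> None:
    """Records plus their per-component and total scores, one row each."""
    if len(records) != len(scores):
        raise ValidationError("records and scores must align")
    fields = list(COLUMNS) + list(SCORE_COLUMNS)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for record, score in zip(records, scores):
            row = _record_to_row(record)
            for name in SCORE_COLUMNS[:-1]:
                row[name] = getattr(score, name)
            row["total_score"] = score.total
            writer.writerow(row)
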