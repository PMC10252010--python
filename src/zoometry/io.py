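"""Reading and writing per-animal record tables.

The interchange format is plain CSV with a mandatory header and a
decimal point regardless of locale.  The canonical column order is
``animal_id, biotype, sex, live_weight`` followed by the 17 measurement
codes in schema order; missing measurements are empty cells (never 0).
Unknown columns survive a round trip as string annotations.

A small YAML mapping can rename non-standard input headers onto the
standard codes, e.g. ``height_at_withers: HaW``.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from . import calibration
from .schema import AnimalRecord, Biotype, MeasurementError, SchemaError, Sex

MANDATORY_COLUMNS = ("animal_id", "biotype", "sex")
WEIGHT_COLUMN = "live_weight"

#: Canonical header for record CSVs.
CANONICAL_COLUMNS = (
    MANDATORY_COLUMNS + (WEIGHT_COLUMN,) + calibration.MEASUREMENTS
)


def load_aliases(path: str | Path) -> dict[str, str]:
    """Load a ``{input_header: standard_code}`` alias map from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"alias file {path} must be a flat mapping")
    aliases = {str(k): str(v) for k, v in data.items()}
    bad = set(aliases.values()) - set(CANONICAL_COLUMNS)
    if bad:
        raise SchemaError(f"aliases target unknown columns: {sorted(bad)}")
    return aliases


def _parse_float(cell: str, *, row: int, column: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise SchemaError(
            f"row {row}: non-numeric value {cell!r} in column {column!r}"
        ) from None


def read_records(
    source: str | Path,
    *,
    aliases: Mapping[str, str] | None = None,
) -> list[AnimalRecord]:
    """Parse a record CSV into :class:`AnimalRecord` objects.

    Row order is preserved; one record per data row.  Raises
    :class:`SchemaError` for missing mandatory columns or unparseable
    cells (with the 1-based data row index), and
    :class:`MeasurementError` for values violating hard invariants.
    """
    aliases = dict(aliases or {})
    with open(source, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise SchemaError(f"{source}: empty file, header required") from None
        header = [aliases.get(h, h) for h in raw_header]
        missing = [c for c in MANDATORY_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{source}: missing mandatory columns {missing}")
        if not any(c in calibration.MEASUREMENTS for c in header):
            raise SchemaError(
                f"{source}: no measurement columns found "
                f"(expected at least one of {list(calibration.MEASUREMENTS)})"
            )
        records: list[AnimalRecord] = []
        for i, row in enumerate(reader, start=1):
            if not row or all(not cell.strip() for cell in row):
                continue
            cells = dict(zip(header, row))
            biotype_token = cells["biotype"].strip()
            sex_token = cells["sex"].strip()
            try:
                biotype = Biotype(biotype_token.upper())
            except ValueError:
                raise SchemaError(
                    f"row {i}: unknown biotype {biotype_token!r} "
                    f"(expected one of {[b.value for b in Biotype]})"
                ) from None
            try:
                sex = Sex(sex_token.upper())
            except ValueError:
                raise SchemaError(
                    f"row {i}: unknown sex {sex_token!r} "
                    f"(expected one of {[s.value for s in Sex]})"
                ) from None
            measurements = {}
            annotations = {}
            weight = None
            for column, cell in cells.items():
                if column in MANDATORY_COLUMNS:
                    continue
                cell = cell.strip()
                if column == WEIGHT_COLUMN:
                    if cell:
                        weight = _parse_float(cell, row=i, column=column)
                elif column in calibration.MEASUREMENTS:
                    if cell:
                        measurements[column] = _parse_float(
                            cell, row=i, column=column
                        )
                else:
                    annotations[column] = cell
            try:
                records.append(
                    AnimalRecord(
                        animal_id=cells["animal_id"].strip(),
                        biotype=biotype,
                        sex=sex,
                        measurements=measurements,
                        live_weight=weight,
                        annotations=annotations,
                    )
                )
            except MeasurementError as exc:
                raise MeasurementError(f"row {i}: {exc}") from None
    return records


def _format_number(value: float) -> str:
    # repr round-trips float64 exactly; integers render without a trailing .0
    if math.isfinite(value) and value == int(value):
        return str(int(value))
    return repr(value)


def write_records(
    records: Sequence[AnimalRecord],
    sink: str | Path,
    *,
    extra_columns: Iterable[str] = (),
) -> None:
    """Write records as canonical CSV (empty cells for missing values).

    Annotation keys listed in ``extra_columns`` — or present on any
    record when unspecified — are appended after the measurement block.
    """
    extra = list(extra_columns)
    if not extra:
        seen: dict[str, None] = {}
        for record in records:
            for key in record.annotations:
                seen.setdefault(key)
        extra = list(seen)
    header = list(CANONICAL_COLUMNS) + extra
    path = Path(sink)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for record in records:
            row = [record.animal_id, record.biotype.value, record.sex.value]
            row.append(
                "" if record.live_weight is None
                else _format_number(record.live_weight)
            )
            for code in calibration.MEASUREMENTS:
                value = record.measurements.get(code)
                row.append("" if value is None else _format_number(value))
            for key in extra:
                row.append(record.annotations.get(key, ""))
            writer.writerow(row)


def records_to_frame(records: Sequence[AnimalRecord]):
    """Records as a tidy DataFrame (one row per animal)."""
    import pandas as pd

    rows = []
    for record in records:
        row: dict[str, object] = {
            "animal_id": record.animal_id,
            "biotype": record.biotype.value,
            "sex": record.sex.value,
            "live_weight": record.live_weight,
        }
        for code in calibration.MEASUREMENTS:
            row[code] = record.measurements.get(code)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
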