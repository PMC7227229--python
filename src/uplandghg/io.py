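"""Reading and writing activity tables, emission-factor configs and reports.

Activity CSV schema (UTF-8, comma-separated, ``.`` decimal, header
required)::

    province,crop,year,area_ha,yield_kg,n_urea,n_cf,n_dap,n_abc

One row per (province, crop, year); N rates are kg N ha^-1 per product.
Parsing is strict: every offending row is reported with its line number
and field, and nothing is silently coerced.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    ActivityRecord,
    Crop,
    EFRegistry,
    FertilizerProduct,
    InventoryError,
    RegionMap,
    UnknownProvinceError,
    ValidationError,
)

__all__ = [
    "ACTIVITY_COLUMNS",
    "ActivityParseError",
    "read_activity_csv",
    "write_activity_csv",
    "read_ef_config",
    "write_ef_config",
    "read_region_map_csv",
]

ACTIVITY_COLUMNS = [
    "province",
    "crop",
    "year",
    "area_ha",
    "yield_kg",
    "n_urea",
    "n_cf",
    "n_dap",
    "n_abc",
]

_RATE_COLUMNS = {
    "n_urea": FertilizerProduct.UREA,
    "n_cf": FertilizerProduct.CF,
    "n_dap": FertilizerProduct.DAP,
    "n_abc": FertilizerProduct.ABC,
}


class ActivityParseError(ValidationError):
    """One or more rows of an activity CSV failed validation."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(self.errors)} invalid row(s) in activity table:\n"
            + "\n".join(self.errors)
        )


def read_activity_csv(
    path: str | Path, region_map: RegionMap | None = None
) -> list[ActivityRecord]:
    """Parse and validate an activity CSV into records.

    Regions are resolved through ``region_map`` (default: the shipped
    19-province map).  All row errors are collected and reported together,
    each tagged with its file line number and field.
    """
    region_map = region_map or RegionMap.default()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in ACTIVITY_COLUMNS if c not in header]
        if missing:
            raise ActivityParseError(
                [f"{path.name}: missing column(s) {', '.join(missing)}"]
            )
        records: list[ActivityRecord] = []
        errors: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, lineno, region_map))
            except InventoryError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise ActivityParseError(errors)
    return records


def _parse_row(row: dict, lineno: int, region_map: RegionMap) -> ActivityRecord:
    def number(fieldname: str) -> float:
        raw = (row.get(fieldname) or "").strip()
        try:
            return float(raw)
        except ValueError:
            raise ValidationError(f"field {fieldname!r}: not a number: {raw!r}") from None

    province_raw = (row.get("province") or "").strip()
    if not province_raw:
        raise ValidationError("field 'province': empty")
    try:
        province = region_map.canonical_name(province_raw)
        region = region_map.resolve(province_raw)
    except UnknownProvinceError:
        raise
    crop_raw = (row.get("crop") or "").strip().lower()
    try:
        crop = Crop(crop_raw)
    except ValueError:
        raise ValidationError(f"field 'crop': must be wheat or maize, got {crop_raw!r}") from None
    year_raw = (row.get("year") or "").strip()
    try:
        year = int(year_raw)
    except ValueError:
        raise ValidationError(f"field 'year': not an integer: {year_raw!r}") from None
    area = number("area_ha")
    if not area > 0:
        raise ValidationError(f"field 'area_ha': must be > 0, got {area}")
    yield_kg = number("yield_kg")
    if yield_kg < 0:
        raise ValidationError(f"field 'yield_kg': must be >= 0, got {yield_kg}")
    n_rate = {}
    for col, product in _RATE_COLUMNS.items():
        v = number(col)
        if v < 0:
            raise ValidationError(f"field {col!r}: must be >= 0, got {v}")
        n_rate[product] = v
    return ActivityRecord(
        province=province,
        crop=crop,
        year=year,
        area=area,
        yield_total=yield_kg,
        n_rate=n_rate,
        region=region,
    )


def write_activity_csv(records: Iterable[ActivityRecord], path: str | Path) -> None:
    """Write records to the activity CSV schema.

    Floats are written with ``repr`` so a write/read round trip restores
    bit-identical values, and identical inputs produce byte-identical
    files.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ACTIVITY_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.province,
                    rec.crop.value,
                    rec.year,
                    repr(float(rec.area)),
                    repr(float(rec.yield_total)),
                    repr(float(rec.n_rate[FertilizerProduct.UREA])),
                    repr(float(rec.n_rate[FertilizerProduct.CF])),
                    repr(float(rec.n_rate[FertilizerProduct.DAP])),
                    repr(float(rec.n_rate[FertilizerProduct.ABC])),
                ]
            )


def read_ef_config(path: str | Path) -> EFRegistry:
    """Load an emission-factor registry from its YAML config format."""
    return EFRegistry.from_yaml(Path(path).read_text(encoding="utf-8"))


def write_ef_config(registry: EFRegistry, path: str | Path) -> None:
    Path(path).write_text(registry.to_yaml(), encoding="utf-8")


def read_region_map_csv(path: str | Path) -> RegionMap:
    """Load a province -> region map from a two-column CSV."""
    df = pd.read_csv(path)
    for col in ("province", "region"):
        if col not in df.columns:
            raise ValidationError(f"region map is missing column {col!r}")
    return RegionMap(dict(zip(df["province"], df["region"])))
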