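"""End-to-end pipeline: activity CSV -> per-record results -> reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import engine, io
from .aggregate import build_report, render_table_markdown, rollup, KG_TO_GG, KG_TO_MT
from .core import Crop, EFRegistry, RegionMap, ValidationError

__all__ = ["PipelineResult", "run_pipeline", "national_summary", "write_reports"]

log = logging.getLogger("uplandghg")


@dataclass
class PipelineResult:
    """Everything a pipeline run produces, in memory."""

    results: pd.DataFrame  # per-record, base units (kg, ha)
    tables: dict[str, pd.DataFrame]  # report tables, reporting units
    summary: dict  # national totals, reporting units
    reconciliation: pd.DataFrame | None = None


def national_summary(results: pd.DataFrame) -> dict:
    """National mean ± SD of the headline quantities, reporting units."""
    out: dict = {}
    for crop in Crop:
        if crop.value not in set(results["crop"]):
            continue
        entry: dict = {}
        for quantity, scale, unit in (
            ("e_m_total", KG_TO_MT, "Mt CO2-eq/yr"),
            ("e_d_n2o", KG_TO_GG, "Gg N2O/yr"),
            ("total_co2eq", KG_TO_MT, "Mt CO2-eq/yr"),
        ):
            agg = rollup(results, "national", crop, quantity)
            entry[quantity] = {
                "mean": agg.mean * scale,
                "sd": agg.sd * scale,
                "unit": unit,
                "n_years": agg.n_years,
            }
        for quantity, scale, unit in (
            ("area_scaled", 1e-3, "t CO2-eq/ha"),
            ("yield_scaled", 1.0, "kg CO2-eq/kg grain"),
        ):
            agg = rollup(results, "national", crop, quantity)
            entry[quantity] = {
                "mean": agg.mean * scale,
                "sd": agg.sd * scale,
                "unit": unit,
                "n_years": agg.n_years,
            }
        out[crop.value] = entry
    return out


def run_pipeline(
    activity_path: str | Path,
    ef_config_path: str | Path | None = None,
    *,
    crop: Crop | str | None = None,
    region_map_path: str | Path | None = None,
    units: str = "report",
    expected_tables: dict[str, pd.DataFrame] | None = None,
) -> PipelineResult:
    """Run the full inventory on an activity CSV.

    Parameters
    ----------
    activity_path : path to the activity CSV.
    ef_config_path : optional emission-factor YAML; defaults to the
        shipped registry (the provenance is logged either way).
    crop : optionally restrict the run to one crop.
    region_map_path : optional custom province -> region CSV.
    units : 'report' (Mt/Gg/t tables) or 'kg'.
    expected_tables : optional expected provincial tables (same shape as
        the report tables, mean columns compared) to reconcile against.
    """
    if ef_config_path is not None:
        registry = io.read_ef_config(ef_config_path)
        log.info("emission factors: user-supplied (%s)", ef_config_path)
    else:
        registry = EFRegistry.default()
        log.info("emission factors: shipped defaults")
    region_map = (
        io.read_region_map_csv(region_map_path) if region_map_path else RegionMap.default()
    )
    records = io.read_activity_csv(activity_path, region_map)
    if crop is not None:
        crop = Crop(crop)
        records = [r for r in records if r.crop == crop]
    if not records:
        raise ValidationError("no records in activity table")
    log.info("loaded %d activity records from %s", len(records), activity_path)

    results = engine.run_records(records, registry)
    tables = build_report(results, units=units)

    reconciliation = None
    if expected_tables:
        rows = []
        for name, expected in expected_tables.items():
            computed = tables[name].set_index(tables[name].columns[0])
            exp = expected.set_index(expected.columns[0])
            for idx in exp.index:
                for col in exp.columns:
                    if not col.endswith("_mean") or col not in computed.columns:
                        continue
                    e = exp.loc[idx, col]
                    c = computed.loc[idx, col] if idx in computed.index else float("nan")
                    rows.append(
                        {
                            "table": name,
                            "row": idx,
                            "column": col,
                            "computed": c,
                            "expected": e,
                            "abs_diff": abs(c - e),
                        }
                    )
        reconciliation = pd.DataFrame(rows)

    return PipelineResult(
        results=results,
        tables=tables,
        summary=national_summary(results),
        reconciliation=reconciliation,
    )


def write_reports(
    result: PipelineResult,
    out_dir: str | Path,
    fmt: str = "both",
    ndigits: int = 2,
) -> list[Path]:
    """Write per-record results, report tables and the JSON summary.

    ``fmt`` selects table formats: 'csv', 'markdown' or 'both'.  CSV
    tables keep full precision; markdown rounds to ``ndigits``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = out_dir / "results.csv"
    result.results.to_csv(p, index=False)
    written.append(p)

    for name, table in result.tables.items():
        if fmt in ("csv", "both"):
            p = out_dir / f"{name}.csv"
            table.to_csv(p, index=False)
            written.append(p)
        if fmt in ("markdown", "both"):
            p = out_dir / f"{name}.md"
            p.write_text(render_table_markdown(table, ndigits), encoding="utf-8")
            written.append(p)

    p = out_dir / "national_summary.json"
    p.write_text(json.dumps(result.summary, indent=2, sort_keys=True), encoding="utf-8")
    written.append(p)

    if result.reconciliation is not None:
        p = out_dir / "reconciliation.csv"
        result.reconciliation.to_csv(p, index=False)
        written.append(p)
    return written
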