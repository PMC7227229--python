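"""Multi-year averaging, regional/national rollups and report tables.

Aggregation follows two rules that matter for correctness:

* **Extensive quantities** (emissions, area, yield) are summed over the
  spatial units *within each year*, and the interannual mean and sample
  standard deviation of those yearly sums are reported.  Interannual
  variation is the inventory's stated uncertainty, so a national SD is
  the SD of yearly national totals, never a sum of provincial SDs.
* **Intensities** (area-/yield-scaled emissions) are recomputed at the
  aggregate level from pooled totals, ``sum(total CO2-eq) / sum(area or
  yield)`` per year — never averaged across provinces, which would weight
  small and large provinces equally.

Rounding to reporting precision happens strictly at render time.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ActivityRecord,
    AggregateResult,
    Crop,
    ValidationError,
)

__all__ = [
    "EXTENSIVE_QUANTITIES",
    "INTENSITY_QUANTITIES",
    "DEFAULT_RATE_BIN_EDGES",
    "mean_sd_over_years",
    "rollup",
    "share_of_total",
    "rate_class_area_fractions",
    "build_report",
    "render_table_markdown",
    "format_mean_sd",
]

#: Quantities that add over spatial units (kg or ha per year).
EXTENSIVE_QUANTITIES = frozenset(
    {
        "e_m_urea",
        "e_m_cf",
        "e_m_dap",
        "e_m_abc",
        "e_m_total",
        "e_d_n2o",
        "total_co2eq",
        "area_ha",
        "yield_kg",
    }
)

#: Ratio quantities, recomputed from pooled numerator/denominator.
INTENSITY_QUANTITIES: Mapping[str, tuple[str, str]] = {
    "area_scaled": ("total_co2eq", "area_ha"),
    "yield_scaled": ("total_co2eq", "yield_kg"),
}

#: Fertilization-rate classes, kg N ha^-1, left-closed right-open,
#: 50 kg steps up to 300 with an open top class.
DEFAULT_RATE_BIN_EDGES: tuple[float, ...] = (
    0.0,
    50.0,
    100.0,
    150.0,
    200.0,
    250.0,
    300.0,
    math.inf,
)


def mean_sd_over_years(
    values: Sequence[float] | pd.Series,
    *,
    scope: str = "national",
    name: str = "national",
    crop: Crop | None = None,
    quantity: str = "value",
) -> AggregateResult:
    """Interannual mean and sample SD (n-1 denominator) of yearly values.

    A single year yields sd = 0 by convention.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot aggregate an empty series of yearly values")
    mean = float(arr.mean())
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return AggregateResult(
        scope=scope,
        name=name,
        crop=crop,
        quantity=quantity,
        mean=mean,
        sd=sd,
        n_years=int(arr.size),
    )


def _crop_value(crop: Crop | str) -> str:
    return Crop(crop).value


def _yearly_series(group: pd.DataFrame, quantity: str) -> pd.Series:
    """Yearly value of ``quantity`` on a (already spatially filtered) frame."""
    if quantity in EXTENSIVE_QUANTITIES:
        return group.groupby("year")[quantity].sum()
    if quantity in INTENSITY_QUANTITIES:
        num, den = INTENSITY_QUANTITIES[quantity]
        by_year = group.groupby("year")[[num, den]].sum()
        return by_year[num] / by_year[den]
    raise ValidationError(f"unknown quantity {quantity!r}")


def rollup(
    results: pd.DataFrame,
    level: str,
    crop: Crop | str,
    quantity: str,
):
    """Aggregate per-record results to region or national scope.

    Parameters
    ----------
    results : DataFrame
        Per-record inventory output (see ``engine.run_records``); must at
        least carry ``province``, ``region``, ``crop``, ``year`` and the
        requested quantity columns.
    level : {'province', 'region', 'national'}
    crop : Crop
        Records are filtered to this crop; aggregating across crops is
        rejected because rates and factors are crop-specific.
    quantity : str
        An extensive metric (summed within years) or an intensity
        (recomputed from pooled totals within years).

    Returns
    -------
    AggregateResult (``level='national'``) or dict mapping region/province
    name to AggregateResult.
    """
    crop_val = _crop_value(crop)
    sub = results[results["crop"] == crop_val]
    if sub.empty:
        raise ValidationError(f"no records for crop {crop_val!r}")
    if level == "national":
        return mean_sd_over_years(
            _yearly_series(sub, quantity),
            scope="national",
            name="national",
            crop=Crop(crop),
            quantity=quantity,
        )
    if level in ("region", "province"):
        out: dict[str, AggregateResult] = {}
        for name, group in sub.groupby(level, sort=True):
            out[str(name)] = mean_sd_over_years(
                _yearly_series(group, quantity),
                scope=level,
                name=str(name),
                crop=Crop(crop),
                quantity=quantity,
            )
        return out
    raise ValidationError(f"level must be 'province', 'region' or 'national', got {level!r}")


def share_of_total(part: AggregateResult, whole: AggregateResult) -> float:
    """Percentage contribution of ``part`` to ``whole`` (same quantity)."""
    if part.quantity != whole.quantity:
        raise ValidationError(
            f"cannot compare quantities {part.quantity!r} and {whole.quantity!r}"
        )
    if not whole.mean > 0:
        raise ValidationError(f"total must be > 0, got {whole.mean}")
    return 100.0 * part.mean / whole.mean


def rate_class_area_fractions(
    records: Iterable[ActivityRecord],
    bin_edges: Sequence[float] = DEFAULT_RATE_BIN_EDGES,
) -> dict[tuple[float, float], float]:
    """Fraction of sown area per total-N-rate class.

    Records are binned by their total synthetic N rate into left-closed,
    right-open intervals ``[edge_i, edge_{i+1})`` and weighted by area;
    fractions sum to 1.  A rate outside every bin is an error (extend the
    edges instead of silently dropping area).
    """
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be ascending with at least two values")
    bins = list(zip(edges[:-1], edges[1:]))
    areas = {b: 0.0 for b in bins}
    total = 0.0
    for rec in records:
        rate = rec.total_n_rate
        for lo, hi in bins:
            if lo <= rate < hi:
                areas[(lo, hi)] += rec.area
                break
        else:
            raise ValidationError(
                f"total N rate {rate} kg ha^-1 falls outside the bin edges {edges}"
            )
        total += rec.area
    if total == 0.0:
        raise ValidationError("no records to bin")
    return {b: a / total for b, a in areas.items()}


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

KG_TO_MT = 1e-9
KG_TO_GG = 1e-6
KG_TO_T = 1e-3

_PRODUCT_ROWS = [
    ("e_m_urea", "GHG emissions from urea manufacture (Mt CO2-eq yr-1)"),
    ("e_m_cf", "GHG emissions from CF manufacture (Mt CO2-eq yr-1)"),
    ("e_m_dap", "GHG emissions from DAP manufacture (Mt CO2-eq yr-1)"),
    ("e_m_abc", "GHG emissions from ABC manufacture (Mt CO2-eq yr-1)"),
]


def _crops_present(results: pd.DataFrame) -> list[Crop]:
    return [c for c in Crop if c.value in set(results["crop"])]


def _by_unit_table(
    results: pd.DataFrame,
    level: str,
    quantity: str,
    scale: float,
) -> pd.DataFrame:
    """Wide mean/sd table of one quantity by province or region, per crop."""
    crops = _crops_present(results)
    names: list[str] = []
    if level == "province":
        # keep region next to province, in region-map order of appearance
        meta = results[["province", "region"]].drop_duplicates("province")
        names = list(meta["province"])
        region_of = dict(zip(meta["province"], meta["region"]))
    else:
        names = sorted(set(results[level]))
    rows = []
    for name in names:
        row: dict[str, object] = {level: name}
        if level == "province":
            row["region"] = region_of[name]
        for crop in crops:
            sub = results[results["crop"] == crop.value]
            if name not in set(sub[level]):
                row[f"{crop.value}_mean"] = math.nan
                row[f"{crop.value}_sd"] = math.nan
                continue
            agg = mean_sd_over_years(
                _yearly_series(sub[sub[level] == name], quantity),
                scope=level,
                name=name,
                crop=crop,
                quantity=quantity,
            )
            row[f"{crop.value}_mean"] = agg.mean * scale
            row[f"{crop.value}_sd"] = agg.sd * scale
        rows.append(row)
    cols = [level] + (["region"] if level == "province" else [])
    for crop in crops:
        cols += [f"{crop.value}_mean", f"{crop.value}_sd"]
    return pd.DataFrame(rows, columns=cols)


def build_report(results: pd.DataFrame, units: str = "report") -> dict[str, pd.DataFrame]:
    """Standard report tables from per-record inventory results.

    Returns four tables:

    * ``manufacture_by_province`` — total manufacture emissions per
      province and crop (Mt CO2-eq yr-1);
    * ``n2o_by_province`` — direct soil N2O per province and crop
      (Gg N2O yr-1);
    * ``national_components`` — national per-product manufacture (Mt),
      direct N2O (Gg) and total CO2-eq (Mt) per crop;
    * ``regional_intensity`` — area-scaled (t CO2-eq ha-1) and
      yield-scaled (kg CO2-eq kg grain-1) intensities by region and crop.

    ``units='kg'`` leaves every emission quantity in base kg.
    All values are mean over years with the interannual sample SD.
    """
    if units not in ("report", "kg"):
        raise ValidationError(f"units must be 'report' or 'kg', got {units!r}")
    mt = KG_TO_MT if units == "report" else 1.0
    gg = KG_TO_GG if units == "report" else 1.0
    t = KG_TO_T if units == "report" else 1.0

    if results.empty:
        empty_prov = pd.DataFrame(
            columns=["province", "region", "wheat_mean", "wheat_sd", "maize_mean", "maize_sd"]
        )
        return {
            "manufacture_by_province": empty_prov.copy(),
            "n2o_by_province": empty_prov.copy(),
            "national_components": pd.DataFrame(columns=["component"]),
            "regional_intensity": pd.DataFrame(columns=["region"]),
        }

    crops = _crops_present(results)

    manufacture = _by_unit_table(results, "province", "e_m_total", mt)
    n2o = _by_unit_table(results, "province", "e_d_n2o", gg)

    nat_rows = []
    for key, label in _PRODUCT_ROWS:
        row: dict[str, object] = {"component": label if units == "report" else key}
        for crop in crops:
            agg = rollup(results, "national", crop, key)
            row[f"{crop.value}_mean"] = agg.mean * mt
            row[f"{crop.value}_sd"] = agg.sd * mt
        nat_rows.append(row)
    row = {"component": "Direct N2O emissions from the soil (Gg N2O yr-1)" if units == "report" else "e_d_n2o"}
    for crop in crops:
        agg = rollup(results, "national", crop, "e_d_n2o")
        row[f"{crop.value}_mean"] = agg.mean * gg
        row[f"{crop.value}_sd"] = agg.sd * gg
    nat_rows.append(row)
    row = {"component": "Total national GHG emissions (Mt CO2-eq yr-1)" if units == "report" else "total_co2eq"}
    for crop in crops:
        agg = rollup(results, "national", crop, "total_co2eq")
        row[f"{crop.value}_mean"] = agg.mean * mt
        row[f"{crop.value}_sd"] = agg.sd * mt
    nat_rows.append(row)
    national = pd.DataFrame(nat_rows)

    intensity_rows = []
    for region in sorted(set(results["region"])):
        row = {"region": region}
        for crop in crops:
            sub = results[(results["crop"] == crop.value) & (results["region"] == region)]
            for quantity, scale, tag in (
                ("area_scaled", t, "area"),
                ("yield_scaled", 1.0, "yield"),
            ):
                if sub.empty:
                    row[f"{tag}_{crop.value}_mean"] = math.nan
                    row[f"{tag}_{crop.value}_sd"] = math.nan
                    continue
                agg = mean_sd_over_years(
                    _yearly_series(sub, quantity),
                    scope="region",
                    name=region,
                    crop=crop,
                    quantity=quantity,
                )
                row[f"{tag}_{crop.value}_mean"] = agg.mean * scale
                row[f"{tag}_{crop.value}_sd"] = agg.sd * scale
        intensity_rows.append(row)
    regional_intensity = pd.DataFrame(intensity_rows)

    return {
        "manufacture_by_province": manufacture,
        "n2o_by_province": n2o,
        "national_components": national,
        "regional_intensity": regional_intensity,
    }


def format_mean_sd(mean: float, sd: float, ndigits: int = 2) -> str:
    """Render ``mean ± sd`` at reporting precision; NaN renders as a dash."""
    if mean != mean:  # NaN
        return "–"
    return f"{mean:.{ndigits}f} ± {sd:.{ndigits}f}"


def render_table_markdown(table: pd.DataFrame, ndigits: int = 2) -> str:
    """Render a report table to GitHub-style markdown.

    Paired ``*_mean``/``*_sd`` columns are collapsed into single
    ``mean ± sd`` cells; rounding happens here, never in the stored
    numbers.
    """
    mean_cols = [c for c in table.columns if c.endswith("_mean")]
    plain_cols = [c for c in table.columns if not c.endswith(("_mean", "_sd"))]
    headers = plain_cols + [c[: -len("_mean")] for c in mean_cols]
    lines = [
        "| " + " | ".join(headers) + " |",
        "| " + " | ".join("---" for _ in headers) + " |",
    ]
    for _, row in table.iterrows():
        cells = [str(row[c]) for c in plain_cols]
        for mc in mean_cols:
            sc = mc[: -len("_mean")] + "_sd"
            cells.append(format_mean_sd(row[mc], row.get(sc, 0.0), ndigits))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"
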