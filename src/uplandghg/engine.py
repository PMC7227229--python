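"""Per-record emission calculations.

Four quantities are computed for each activity record, all in kg:

* manufacture emissions per product, ``E_M[p] = NR[p] * A * EF_M[p]``
  (kg CO2-eq);
* direct soil N2O, ``E_D = (sum_p NR[p]) * A * EF_D * 44/28`` (kg N2O) —
  the direct factor applies to synthetic N as a class, summed over
  products, not per product;
* the CO2-equivalent total, ``E_M_total + E_D * GWP`` — the GWP applies
  to the N2O term only, since manufacture emissions are already expressed
  in CO2-eq;
* area- and yield-scaled intensities of that total.

All computation stays in kg and ha; unit conversion to Mt/Gg/t happens
only in reporting.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    ActivityRecord,
    Crop,
    EFRegistry,
    EmissionResult,
    FertilizerProduct,
    ValidationError,
)

__all__ = [
    "manufacture_emissions",
    "direct_n2o_emissions",
    "co2eq_of_n2o",
    "area_scaled",
    "yield_scaled",
    "run_record",
    "run_records",
    "RESULT_COLUMNS",
]


def manufacture_emissions(
    rec: ActivityRecord, registry: EFRegistry
) -> dict[FertilizerProduct, float]:
    """Manufacture GHG emissions per product for one record, kg CO2-eq.

    ``E_M[p] = NR[p] * A * EF_M[p]``; linear in both the rate and the
    area.  A product with zero rate contributes zero and does not require
    a factor; a positive rate without a manufacture factor is a
    configuration error.
    """
    out: dict[FertilizerProduct, float] = {}
    for product in FertilizerProduct:
        rate = rec.n_rate[product]
        if rate == 0.0:
            out[product] = 0.0
        else:
            out[product] = rate * rec.area * registry.manufacture_factor(product)
    return out


def direct_n2o_emissions(rec: ActivityRecord, registry: EFRegistry) -> float:
    """Direct soil N2O from synthetic N fertilization, kg N2O.

    ``E_D = NR_total * A * EF_D(region, crop) * 44/28``.  Raises
    :class:`~uplandghg.core.MissingEmissionFactorError` when the record's
    (region, crop) has no direct factor (e.g. wheat in NEC).
    """
    ef_d = registry.direct_factor(rec.region, rec.crop)
    return rec.total_n_rate * rec.area * ef_d * registry.n_to_n2o


def co2eq_of_n2o(e_d: float, registry: EFRegistry) -> float:
    """Convert an N2O mass to CO2-equivalents via the registry GWP."""
    return e_d * registry.gwp_n2o


def area_scaled(
    e_m_total: float, e_d: float, area: float, registry: EFRegistry
) -> float:
    """Area-scaled emission intensity, kg CO2-eq ha^-1.

    ``(E_M_total + E_D * GWP) / A``.
    """
    if not area > 0:
        raise ValidationError(f"area must be > 0, got {area}")
    return (e_m_total + co2eq_of_n2o(e_d, registry)) / area


def yield_scaled(
    e_m_total: float, e_d: float, yield_total: float, registry: EFRegistry
) -> float:
    """Yield-scaled emission intensity, kg CO2-eq per kg grain.

    Returns NaN when ``yield_total`` is not positive: the intensity is
    undefined for a failed (zero-yield) harvest, and callers get a
    sentinel rather than a ZeroDivisionError.
    """
    if not yield_total > 0:
        return math.nan
    return (e_m_total + co2eq_of_n2o(e_d, registry)) / yield_total


def run_record(rec: ActivityRecord, registry: EFRegistry) -> EmissionResult:
    """Full inventory for one record: manufacture, soil N2O, total, intensities."""
    e_m = manufacture_emissions(rec, registry)
    e_d = direct_n2o_emissions(rec, registry)
    e_m_total = sum(e_m.values())
    total = e_m_total + co2eq_of_n2o(e_d, registry)
    return EmissionResult(
        province=rec.province,
        crop=rec.crop,
        year=rec.year,
        region=rec.region,
        e_m_by_product=e_m,
        e_d=e_d,
        total_co2eq=total,
        area_scaled=area_scaled(e_m_total, e_d, rec.area, registry),
        yield_scaled=yield_scaled(e_m_total, e_d, rec.yield_total, registry),
    )


RESULT_COLUMNS = [
    "province",
    "region",
    "crop",
    "year",
    "area_ha",
    "yield_kg",
    "n_rate_total",
    "e_m_urea",
    "e_m_cf",
    "e_m_dap",
    "e_m_abc",
    "e_m_total",
    "e_d_n2o",
    "total_co2eq",
    "area_scaled",
    "yield_scaled",
]


def run_records(
    records: Iterable[ActivityRecord], registry: EFRegistry
) -> pd.DataFrame:
    """Run the inventory over a batch of records.

    Returns one row per record with activity data and all emission
    quantities in base units (kg, ha); see :data:`RESULT_COLUMNS`.
    """
    rows = []
    for rec in records:
        res = run_record(rec, registry)
        rows.append(
            {
                "province": rec.province,
                "region": rec.region.value if rec.region else "",
                "crop": rec.crop.value,
                "year": rec.year,
                "area_ha": rec.area,
                "yield_kg": rec.yield_total,
                "n_rate_total": rec.total_n_rate,
                "e_m_urea": res.e_m_by_product[FertilizerProduct.UREA],
                "e_m_cf": res.e_m_by_product[FertilizerProduct.CF],
                "e_m_dap": res.e_m_by_product[FertilizerProduct.DAP],
                "e_m_abc": res.e_m_by_product[FertilizerProduct.ABC],
                "e_m_total": res.e_m_total,
                "e_d_n2o": res.e_d,
                "total_co2eq": res.total_co2eq,
                "area_scaled": res.area_scaled,
                "yield_scaled": res.yield_scaled,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
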