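"""Desk-scale reconciliation of the inventory against published aggregates.

Every published headline number is recomputable from other published
numbers (rates, emission factors, totals), so the whole chain can be
checked without the undeposited provincial statistics:

* arithmetic identities among printed totals (N consumption, GWP
  conversion, manufacture + fertilization sums);
* recomputation of national manufacture emissions from printed rates,
  factors and the implied sown area — agreement is bounded by the
  rounding of the printed inputs, so tolerances are fractions of a
  percent, not exact;
* regional rollups of the printed provincial tables against the printed
  regional totals (printed values are rounded to 0.01 before summation,
  so sums may differ by ±0.02);
* national emission intensities from printed totals and implied areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import engine
from .core import Crop
from .synth import ReferenceFixture, reference_fixture

__all__ = ["ReconciliationCheck", "reconcile_reference", "reconciliation_frame"]


@dataclass(frozen=True)
class ReconciliationCheck:
    name: str
    computed: float
    expected: float
    tolerance: float  # absolute, on the reported scale
    passed: bool


def _check(name: str, computed: float, expected: float, tol: float) -> ReconciliationCheck:
    return ReconciliationCheck(
        name=name,
        computed=computed,
        expected=expected,
        tolerance=tol,
        passed=abs(computed - expected) <= tol,
    )


def reconcile_reference(fixture: ReferenceFixture | None = None) -> list[ReconciliationCheck]:
    """Run all reconciliation checks against the published fixture."""
    fx = fixture or reference_fixture()
    reg = fx.registry
    checks: list[ReconciliationCheck] = []

    # -- identities among printed national numbers --------------------
    n_total_mt = sum(fx.national_n_consumption_kg.values()) * 1e-9
    checks.append(_check("total synthetic N consumption (Mt N)", n_total_mt, 12.63, 0.005))
    for crop, e_d_gg, e_m_mt, total_mt in (
        (Crop.WHEAT, 35.82, 41.44, 52.11),
        (Crop.MAIZE, 69.44, 59.71, 80.40),
    ):
        n2o_co2eq_mt = engine.co2eq_of_n2o(e_d_gg * 1e6, reg) * 1e-9
        checks.append(
            _check(
                f"{crop.value}: printed soil N2O as CO2-eq (Mt)",
                n2o_co2eq_mt,
                round(total_mt - e_m_mt, 2),
                0.005,
            )
        )
        checks.append(
            _check(
                f"{crop.value}: manufacture + fertilization total (Mt)",
                e_m_mt + round(n2o_co2eq_mt, 2),
                total_mt,
                0.005,
            )
        )

    # -- national manufacture recomputed from printed inputs ----------
    # tolerance reflects rounding of the printed rates/consumption
    for crop, printed_mt, rel_tol in ((Crop.WHEAT, 41.44, 0.005), (Crop.MAIZE, 59.71, 0.01)):
        rec = fx.national_records[crop]
        e_m = sum(engine.manufacture_emissions(rec, reg).values()) * 1e-9
        checks.append(
            _check(
                f"{crop.value}: national manufacture emissions (Mt)",
                e_m,
                printed_mt,
                printed_mt * rel_tol,
            )
        )

    # -- per-product national manufacture vs published table ----------
    for crop in Crop:
        rec = fx.national_records[crop]
        e_m = engine.manufacture_emissions(rec, reg)
        for key, product in (
            ("e_m_urea", "urea"),
            ("e_m_cf", "cf"),
            ("e_m_dap", "dap"),
            ("e_m_abc", "abc"),
        ):
            printed = fx.national_components[key][crop.value][0]
            p = engine.FertilizerProduct(product)
            computed = e_m[p] * 1e-9
            # printed rates are rounded to the unit (a ±0.5/rate relative
            # bound, large for the small DAP/ABC rates) and the printed
            # consumption to 0.01 Mt (~1%)
            rate = fx.national_rates[crop][p]
            tol = printed * (0.5 / rate + 0.01)
            checks.append(
                _check(
                    f"{crop.value}: {product} manufacture (Mt)",
                    computed,
                    printed,
                    tol,
                )
            )

    # -- regional rollups of printed provincial tables ----------------
    for table, regional, unit, label in (
        (fx.manufacture_by_province, fx.regional_manufacture, "Mt", "manufacture"),
        (fx.n2o_by_province, fx.regional_n2o, "Gg", "soil N2O"),
    ):
        for crop in Crop:
            col = f"{crop.value}_mean"
            sums = table.groupby("region")[col].sum(min_count=1)
            for region, printed in regional[crop].items():
                checks.append(
                    _check(
                        f"{crop.value}: {region} {label} rollup ({unit})",
                        float(sums[region]),
                        printed,
                        0.02,  # printed provincial values are pre-rounded
                    )
                )

    # -- national intensities from printed totals ---------------------
    for crop in Crop:
        rec = fx.national_records[crop]
        total_mt = fx.national_components["total_co2eq"][crop.value][0]
        e_m_mt = total_mt - round(
            fx.national_components["e_d_n2o"][crop.value][0] * 1e6 * reg.gwp_n2o * 1e-9, 2
        )
        e_d_kg = fx.national_components["e_d_n2o"][crop.value][0] * 1e6
        a_scaled = engine.area_scaled(e_m_mt * 1e9, e_d_kg, rec.area, reg) * 1e-3
        checks.append(
            _check(
                f"{crop.value}: national area-scaled intensity (t CO2-eq/ha)",
                a_scaled,
                fx.national_area_scaled_t_ha[crop],
                0.01,
            )
        )
        y_scaled = engine.yield_scaled(e_m_mt * 1e9, e_d_kg, rec.yield_total, reg)
        checks.append(
            _check(
                f"{crop.value}: national yield-scaled intensity (kg CO2-eq/kg)",
                y_scaled,
                fx.national_yield_scaled[crop],
                0.01,
            )
        )

    # -- published provincial shares of national manufacture ----------
    shares = {
        "Henan": 21.1,
        "Shandong": 16.0,
        "Hebei": 12.1,
        "Jiangsu": 11.7,
        "Anhui": 10.0,
    }
    wheat_total = 41.44
    table = fx.manufacture_by_province.set_index("province")
    for province, printed in shares.items():
        computed = 100.0 * float(table.loc[province, "wheat_mean"]) / wheat_total
        checks.append(
            _check(
                f"wheat: {province} share of national manufacture (%)",
                computed,
                printed,
                0.05,
            )
        )

    return checks


def reconciliation_frame(fixture: ReferenceFixture | None = None) -> pd.DataFrame:
    """Reconciliation checks as a DataFrame (one row per check)."""
    checks = reconcile_reference(fixture)
    return pd.DataFrame(
        [
            {
                "check": c.name,
                "computed": c.computed,
                "expected": c.expected,
                "tolerance": c.tolerance,
                "passed": c.passed,
            }
            for c in checks
        ]
    )
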