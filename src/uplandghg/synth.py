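"""Synthetic provincial activity data and the published reference fixture.

The real activity inputs of this inventory — provincial sown areas and
yields from national statistics, per-product fertilization rates from the
price-survey yearbooks — are not deposited in machine-readable form.  This
module provides two substitutes:

* :func:`generate_activity` draws seeded synthetic datasets with the same
  structure (13 wheat / 19 maize provinces, five regions, three years,
  per-product N rates centred on the published national means), so every
  pipeline stage can be exercised end to end;
* :func:`reference_fixture` bundles the published 2015–2017 national and
  provincial aggregates (emission factors, national rates and N
  consumption, provincial manufacture and N2O tables, regional rollups,
  national intensities) as expected-output tables for reconciliation.

Distributional choices (truncated normal rates across provinces,
log-normal areas, multiplicative shared year effects) are documented
conventions: the published statistics report means, not distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ActivityRecord,
    Crop,
    DEFAULT_MAIZE_PROVINCES,
    DEFAULT_WHEAT_PROVINCES,
    EFRegistry,
    FertilizerProduct,
    Region,
    RegionMap,
    ValidationError,
)

__all__ = [
    "GeneratorConfig",
    "generate_activity",
    "reweight_rate_class",
    "generate_calibrated_activity",
    "RATE_CLASS_TARGETS",
    "DEFAULT_RATE_MEANS",
    "ReferenceFixture",
    "reference_fixture",
]

P = FertilizerProduct

#: Published national mean application rates, kg N ha^-1 per product.
#: Wheat totals 222; the maize products total 196 against a printed
#: national mean of 197 (the printed per-product rates are rounded).
DEFAULT_RATE_MEANS: dict[tuple[Crop, FertilizerProduct], float] = {
    (Crop.WHEAT, P.UREA): 124.0,
    (Crop.WHEAT, P.CF): 72.0,
    (Crop.WHEAT, P.DAP): 17.0,
    (Crop.WHEAT, P.ABC): 9.0,
    (Crop.MAIZE, P.UREA): 111.0,
    (Crop.MAIZE, P.CF): 62.0,
    (Crop.MAIZE, P.DAP): 15.0,
    (Crop.MAIZE, P.ABC): 8.0,
}

#: Rate classes holding the largest share of sown area, with that share:
#: wheat 200–250 kg N ha^-1 at 42.5%, maize 150–200 at 64.0%.
RATE_CLASS_TARGETS: dict[Crop, tuple[tuple[float, float], float]] = {
    Crop.WHEAT: ((200.0, 250.0), 0.425),
    Crop.MAIZE: ((150.0, 200.0), 0.640),
}

_CROP_PROVINCES = {
    Crop.WHEAT: DEFAULT_WHEAT_PROVINCES,
    Crop.MAIZE: DEFAULT_MAIZE_PROVINCES,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic activity generator.

    Defaults emulate the structure of the 2015–2017 provincial statistics:
    three years, both crops, rates centred on the published national
    per-product means with a 25% cross-province coefficient of variation
    and a 5% shared interannual perturbation, log-normal provincial sown
    areas (median 1.2 Mha, sigma 0.9 — national totals of the right order)
    and per-ha grain yields uniform on 4,000–7,500 kg ha^-1.
    """

    seed: int = 0
    n_years: int = 3
    start_year: int = 2015
    crops: tuple[Crop, ...] = (Crop.WHEAT, Crop.MAIZE)
    provinces: tuple[str, ...] | None = None
    rate_means: Mapping[tuple[Crop, FertilizerProduct], float] = field(
        default_factory=lambda: dict(DEFAULT_RATE_MEANS)
    )
    rate_cv: float = 0.25
    interannual_cv: float = 0.05
    area_median_ha: float = 1.2e6
    area_sigma: float = 0.9
    yield_per_ha_range: tuple[float, float] = (4000.0, 7500.0)

    def __post_init__(self):
        object.__setattr__(self, "crops", tuple(Crop(c) for c in self.crops))
        object.__setattr__(self, "rate_means", dict(self.rate_means))
        if self.n_years < 1:
            raise ValidationError(f"n_years must be >= 1, got {self.n_years}")
        if not self.crops:
            raise ValidationError("at least one crop required")
        if self.provinces is not None:
            object.__setattr__(self, "provinces", tuple(self.provinces))
            if not self.provinces:
                raise ValidationError("province selection must not be empty")
        if self.rate_cv < 0 or self.interannual_cv < 0:
            raise ValidationError("coefficients of variation must be >= 0")
        for key, v in self.rate_means.items():
            if v < 0:
                raise ValidationError(f"rate mean for {key} must be >= 0, got {v}")
        lo, hi = self.yield_per_ha_range
        if not (0 < lo <= hi):
            raise ValidationError(
                f"yield_per_ha_range must be 0 < lo <= hi, got {self.yield_per_ha_range}"
            )


def _crop_provinces(config: GeneratorConfig, crop: Crop, region_map: RegionMap) -> list[str]:
    grown = _CROP_PROVINCES[crop]
    if config.provinces is None:
        return list(grown)
    canon = [region_map.canonical_name(p) for p in config.provinces]
    return [p for p in canon if p in grown]


def generate_activity(
    config: GeneratorConfig, region_map: RegionMap | None = None
) -> list[ActivityRecord]:
    """Draw one synthetic activity dataset.

    One record per (province, crop, year) for provinces growing that crop.
    Per province and crop, base rates are drawn once from a normal
    distribution truncated at zero (mean = configured national mean,
    sd = ``rate_cv`` x mean); each year applies a multiplicative effect
    shared across products within the province, capturing correlated
    interannual variation.  Areas are log-normal per province with mild
    year-to-year noise; per-ha yields are uniform on the configured range.

    Identical config (including seed) reproduces the identical dataset.
    """
    region_map = region_map or RegionMap.default()
    rng = np.random.default_rng(config.seed)
    records: list[ActivityRecord] = []
    years = range(config.start_year, config.start_year + config.n_years)

    for crop in config.crops:
        provinces = _crop_provinces(config, crop, region_map)
        if not provinces:
            raise ValidationError(
                f"no selected province grows {crop.value!r}; check the province list"
            )
        for province in provinces:
            region = region_map.resolve(province)
            base_rates = {}
            for product in FertilizerProduct:
                mean = config.rate_means[(crop, product)]
                draw = rng.normal(mean, config.rate_cv * mean) if mean > 0 else 0.0
                base_rates[product] = max(0.0, draw)
            base_area = config.area_median_ha * math.exp(
                rng.normal(0.0, config.area_sigma)
            )
            yield_per_ha = rng.uniform(*config.yield_per_ha_range)
            for year in years:
                year_effect = max(0.0, rng.normal(1.0, config.interannual_cv))
                area = base_area * max(0.5, rng.normal(1.0, 0.03))
                harvest = max(0.0, rng.normal(1.0, 0.05))
                records.append(
                    ActivityRecord(
                        province=province,
                        crop=crop,
                        year=year,
                        area=area,
                        yield_total=area * yield_per_ha * harvest,
                        n_rate={p: r * year_effect for p, r in base_rates.items()},
                        region=region,
                    )
                )
    return records


def reweight_rate_class(
    records: Sequence[ActivityRecord],
    crop: Crop,
    rate_range: tuple[float, float],
    target_fraction: float,
) -> list[ActivityRecord]:
    """Rescale areas so one rate class holds a target share of crop area.

    Areas (and yields, proportionally) of the crop's records whose total N
    rate falls in ``[lo, hi)`` are multiplied by the unique factor that
    makes the class hold ``target_fraction`` of the crop's total area.
    Rates are untouched, so class membership is unchanged and the target
    is met exactly.  Other crops' records pass through unmodified.
    """
    crop = Crop(crop)
    lo, hi = rate_range
    if not 0 < target_fraction < 1:
        raise ValidationError(
            f"target fraction must be in (0, 1), got {target_fraction}"
        )
    in_class = [
        r for r in records if r.crop == crop and lo <= r.total_n_rate < hi
    ]
    out_class = [
        r for r in records if r.crop == crop and not lo <= r.total_n_rate < hi
    ]
    s_in = sum(r.area for r in in_class)
    s_out = sum(r.area for r in out_class)
    if s_in == 0:
        raise ValidationError(
            f"no {crop.value} record falls in the rate class [{lo}, {hi}); "
            "cannot calibrate its area share"
        )
    if s_out == 0:
        raise ValidationError(
            f"all {crop.value} area already lies in [{lo}, {hi}); "
            "a fractional target is unreachable"
        )
    factor = target_fraction * s_out / ((1.0 - target_fraction) * s_in)
    scaled = {
        id(r): replace(r, area=r.area * factor, yield_total=r.yield_total * factor)
        for r in in_class
    }
    return [scaled.get(id(r), r) for r in records]


def generate_calibrated_activity(
    config: GeneratorConfig, region_map: RegionMap | None = None
) -> list[ActivityRecord]:
    """Generate activity data with published modal rate-class area shares.

    After drawing a dataset, the sown areas are reweighted so that for
    each generated crop the published dominant rate class holds its
    published share of total crop area (wheat: 42.5% in 200–250 kg N
    ha^-1; maize: 64.0% in 150–200).
    """
    records = generate_activity(config, region_map)
    for crop in config.crops:
        (rate_range, fraction) = RATE_CLASS_TARGETS[crop]
        records = reweight_rate_class(records, crop, rate_range, fraction)
    return records


# ---------------------------------------------------------------------------
# published reference fixture
# ---------------------------------------------------------------------------

# Provincial mean ± SD tables of the published 2015–2017 inventory.
# None marks crops not grown in a province ("–" in the published tables).
# (region, province, wheat_mean, wheat_sd, maize_mean, maize_sd)

#: Manufacture GHG emissions, Mt CO2-eq yr^-1.
_MANUFACTURE_TABLE = [
    ("NEC", "Liaoning", None, None, 3.32, 0.09),
    ("NEC", "Jilin", None, None, 5.14, 0.10),
    ("NEC", "Heilongjiang", None, None, 7.94, 0.68),
    ("NC", "Hebei", 5.01, 0.12, 4.23, 0.22),
    ("NC", "Shanxi", 1.16, 0.12, 2.65, 0.14),
    ("NC", "Shandong", 6.65, 0.10, 5.12, 0.29),
    ("NC", "Henan", 8.74, 0.20, 3.99, 0.06),
    ("NC", "Inner Mongolia", 1.94, 0.19, 6.35, 0.59),
    ("MLYR", "Jiangsu", 4.86, 0.38, 1.02, 0.12),
    ("MLYR", "Anhui", 4.14, 0.56, 1.61, 0.20),
    ("MLYR", "Hubei", 1.22, 0.01, 1.19, 0.05),
    ("NWC", "Shaanxi", 2.03, 0.20, 2.64, 0.17),
    ("NWC", "Gansu", 1.36, 0.07, 2.64, 0.17),
    ("NWC", "Xinjiang", 2.98, 0.18, 2.49, 0.12),
    ("SSWC", "Chongqing", None, None, 0.75, 0.04),
    ("SSWC", "Sichuan", 0.86, 0.26, 2.14, 0.34),
    ("SSWC", "Guizhou", None, None, 1.62, 0.30),
    ("SSWC", "Yunnan", 0.49, 0.09, 3.84, 0.36),
    ("SSWC", "Guangxi", None, None, 1.04, 0.06),
]

#: Direct soil N2O emissions, Gg N2O yr^-1.
_N2O_TABLE = [
    ("NEC", "Liaoning", None, None, 3.38, 0.10),
    ("NEC", "Jilin", None, None, 5.32, 0.16),
    ("NEC", "Heilongjiang", None, None, 7.78, 0.66),
    ("NC", "Hebei", 2.71, 0.07, 5.78, 0.27),
    ("NC", "Shanxi", 0.63, 0.07, 3.65, 0.20),
    ("NC", "Shandong", 3.68, 0.05, 7.12, 0.44),
    ("NC", "Henan", 4.92, 0.10, 5.71, 0.12),
    ("NC", "Inner Mongolia", 1.01, 0.10, 8.42, 0.78),
    ("MLYR", "Jiangsu", 8.32, 0.64, 1.34, 0.14),
    ("MLYR", "Anhui", 7.22, 0.96, 2.17, 0.27),
    ("MLYR", "Hubei", 2.20, 0.01, 1.63, 0.06),
    ("NWC", "Shaanxi", 1.22, 0.13, 2.96, 0.19),
    ("NWC", "Gansu", 0.82, 0.04, 2.85, 0.18),
    ("NWC", "Xinjiang", 1.74, 0.10, 2.59, 0.12),
    ("SSWC", "Chongqing", None, None, 0.71, 0.04),
    ("SSWC", "Sichuan", 0.89, 0.27, 2.06, 0.32),
    ("SSWC", "Guizhou", None, None, 1.50, 0.28),
    ("SSWC", "Yunnan", 0.48, 0.09, 3.50, 0.32),
    ("SSWC", "Guangxi", None, None, 0.97, 0.06),
]

#: National components (mean, sd) per crop: manufacture per product (Mt),
#: direct N2O (Gg), total (Mt).
_NATIONAL_TABLE = {
    "e_m_urea": {"wheat": (23.42, 0.19), "maize": (34.07, 1.00)},
    "e_m_cf": {"wheat": (12.47, 0.70), "maize": (17.49, 2.34)},
    "e_m_dap": {"wheat": (4.03, 0.13), "maize": (5.89, 0.34)},
    "e_m_abc": {"wheat": (1.53, 0.43), "maize": (2.25, 0.12)},
    "e_d_n2o": {"wheat": (35.82, 1.20), "maize": (69.44, 4.26)},
    "total_co2eq": {"wheat": (52.11, 0.93), "maize": (80.40, 4.88)},
}

#: Regional manufacture totals, Mt CO2-eq yr^-1 (no NEC wheat).
_REGIONAL_MANUFACTURE = {
    Crop.WHEAT: {"NC": 23.49, "MLYR": 10.23, "NWC": 6.37, "SSWC": 1.35},
    Crop.MAIZE: {"NC": 22.34, "NEC": 16.39, "SSWC": 9.38, "NWC": 7.77, "MLYR": 3.82},
}

#: Regional direct N2O totals, Gg N2O yr^-1.
_REGIONAL_N2O = {
    Crop.WHEAT: {"MLYR": 17.73, "NC": 12.94, "NWC": 3.78, "SSWC": 1.37},
    Crop.MAIZE: {"NC": 30.68, "NEC": 16.48, "SSWC": 8.74, "NWC": 8.40, "MLYR": 5.14},
}

#: Regional intensities: (area-scaled t CO2-eq ha^-1, yield-scaled
#: kg CO2-eq kg grain^-1), each (mean, sd).
_REGIONAL_INTENSITY = [
    # region, area wheat, area maize, yield wheat, yield maize
    ("NEC", None, (1.78, 0.04), None, (0.27, 0.01)),
    ("NC", (2.10, 0.03), (2.04, 0.07), (0.35, 0.01), (0.34, 0.02)),
    ("MLYR", (2.60, 0.07), (2.48, 0.10), (0.50, 0.01), (0.48, 0.02)),
    ("NWC", (2.47, 0.03), (3.26, 0.10), (0.54, 0.01), (0.56, 0.02)),
    ("SSWC", (1.29, 0.06), (2.37, 0.03), (0.39, 0.02), (0.47, 0.01)),
]

#: Published national mean total rates, kg N ha^-1.
_NATIONAL_TOTAL_RATE = {Crop.WHEAT: 222.0, Crop.MAIZE: 197.0}

#: Published national synthetic-N consumption, kg N yr^-1.
_NATIONAL_N_CONSUMPTION_KG = {Crop.WHEAT: 5.18e9, Crop.MAIZE: 7.45e9}

#: Published national intensities.
_NATIONAL_AREA_SCALED_T_HA = {Crop.WHEAT: 2.23, Crop.MAIZE: 2.13}
_NATIONAL_YIELD_SCALED = {Crop.WHEAT: 0.41, Crop.MAIZE: 0.35}


def _table_frame(rows: list[tuple]) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["region", "province", "wheat_mean", "wheat_sd", "maize_mean", "maize_sd"],
    ).astype({"wheat_mean": float, "wheat_sd": float, "maize_mean": float, "maize_sd": float})


@dataclass(frozen=True)
class ReferenceFixture:
    """Published constants and aggregates of the 2015–2017 inventory.

    ``national_records`` are national-average pseudo-records (region-less:
    a national record has no single direct-N2O factor): the sown area is
    implied by printed national N consumption divided by the mean rate,
    the total yield by printed total emissions divided by the printed
    yield-scaled intensity.
    """

    registry: EFRegistry
    national_records: Mapping[Crop, ActivityRecord]
    national_components: Mapping[str, Mapping[str, tuple[float, float]]]
    manufacture_by_province: pd.DataFrame  # Mt CO2-eq / yr
    n2o_by_province: pd.DataFrame  # Gg N2O / yr
    regional_manufacture: Mapping[Crop, Mapping[str, float]]  # Mt
    regional_n2o: Mapping[Crop, Mapping[str, float]]  # Gg
    regional_intensity: pd.DataFrame
    national_rates: Mapping[Crop, Mapping[FertilizerProduct, float]]
    national_total_rate: Mapping[Crop, float]
    national_n_consumption_kg: Mapping[Crop, float]
    national_area_scaled_t_ha: Mapping[Crop, float]
    national_yield_scaled: Mapping[Crop, float]
    rate_class_targets: Mapping[Crop, tuple[tuple[float, float], float]]


def reference_fixture() -> ReferenceFixture:
    """Bundle of all published constants needed for reconciliation tests."""
    registry = EFRegistry.default()
    national_records = {}
    for crop in Crop:
        area = _NATIONAL_N_CONSUMPTION_KG[crop] / _NATIONAL_TOTAL_RATE[crop]
        total_mt = _NATIONAL_TABLE["total_co2eq"][crop.value][0]
        yield_total = total_mt * 1e9 / _NATIONAL_YIELD_SCALED[crop]
        national_records[crop] = ActivityRecord(
            province="National",
            crop=crop,
            year=0,
            area=area,
            yield_total=yield_total,
            n_rate={p: DEFAULT_RATE_MEANS[(crop, p)] for p in FertilizerProduct},
            region=None,
        )
    intensity_rows = []
    for region, aw, am, yw, ym in _REGIONAL_INTENSITY:
        intensity_rows.append(
            {
                "region": region,
                "area_wheat_mean": aw[0] if aw else math.nan,
                "area_wheat_sd": aw[1] if aw else math.nan,
                "area_maize_mean": am[0] if am else math.nan,
                "area_maize_sd": am[1] if am else math.nan,
                "yield_wheat_mean": yw[0] if yw else math.nan,
                "yield_wheat_sd": yw[1] if yw else math.nan,
                "yield_maize_mean": ym[0] if ym else math.nan,
                "yield_maize_sd": ym[1] if ym else math.nan,
            }
        )
    return ReferenceFixture(
        registry=registry,
        national_records=national_records,
        national_components=_NATIONAL_TABLE,
        manufacture_by_province=_table_frame(_MANUFACTURE_TABLE),
        n2o_by_province=_table_frame(_N2O_TABLE),
        regional_manufacture=_REGIONAL_MANUFACTURE,
        regional_n2o=_REGIONAL_N2O,
        regional_intensity=pd.DataFrame(intensity_rows),
        national_rates={
            crop: {p: DEFAULT_RATE_MEANS[(crop, p)] for p in FertilizerProduct}
            for crop in Crop
        },
        national_total_rate=dict(_NATIONAL_TOTAL_RATE),
        national_n_consumption_kg=dict(_NATIONAL_N_CONSUMPTION_KG),
        national_area_scaled_t_ha=dict(_NATIONAL_AREA_SCALED_T_HA),
        national_yield_scaled=dict(_NATIONAL_YIELD_SCALED),
        rate_class_targets=dict(RATE_CLASS_TARGETS),
    )
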