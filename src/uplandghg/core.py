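"""Domain model for a synthetic-nitrogen greenhouse-gas inventory.

The inventory covers the two main upland grain crops of China (wheat and
maize) and the four synthetic nitrogen fertilizer products that dominate
their nutrient supply: urea, compound fertilizer (CF, N-P2O5-K2O), diammonium
phosphate (DAP) and ammonium bicarbonate (ABC).  Nineteen major producing
provinces are partitioned into five agricultural regions (NEC, NC, MLYR,
NWC, SSWC) which index the region- and crop-specific direct N2O emission
factors.

Two emission-factor families drive the inventory:

* ``EF_M`` -- manufacture factors, kg CO2-eq per kg fertilizer-N, one per
  product, charged for the full industrial chain (fuel mining/transport,
  ammonia synthesis, product conversion);
* ``EF_D`` -- direct soil N2O factors, kg N2O-N per kg N applied, one per
  (region, crop).  Some combinations genuinely have no factor (wheat in
  Northeast China); looking one up is an error, never silently zero.

N2O is expressed in CO2-equivalents with a 100-year global warming
potential of 298, and applied N mass is converted to N2O mass with the
exact stoichiometric ratio 44/28.
"""

from __future__ import annotations

import csv
import functools
import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "InventoryError",
    "ValidationError",
    "UnknownProvinceError",
    "MissingEmissionFactorError",
    "FertilizerProduct",
    "Crop",
    "Region",
    "RegionMap",
    "ActivityRecord",
    "EFRegistry",
    "EmissionResult",
    "AggregateResult",
    "cf_n_from_nutrient",
    "resolve_region",
    "normalize_province",
    "N_TO_N2O",
    "DEFAULT_WHEAT_PROVINCES",
    "DEFAULT_MAIZE_PROVINCES",
]


class InventoryError(Exception):
    """Base class for all inventory-specific failures."""


class ValidationError(InventoryError, ValueError):
    """An input violated a documented precondition."""


class UnknownProvinceError(InventoryError, KeyError):
    """A province name could not be resolved to an agricultural region."""

    def __init__(self, province: str):
        super().__init__(f"unknown province: {province!r}")
        self.province = province


class MissingEmissionFactorError(InventoryError, KeyError):
    """A required emission factor is absent from the registry.

    Raised in particular for (region, crop) pairs that have no direct-N2O
    factor, such as wheat in Northeast China; the absence is meaningful
    and must never be coerced to zero.
    """


class FertilizerProduct(str, Enum):
    """The four synthetic nitrogen fertilizer products of the inventory."""

    UREA = "urea"
    CF = "cf"
    DAP = "dap"
    ABC = "abc"

    @property
    def label(self) -> str:
        return _PRODUCT_LABELS[self]


_PRODUCT_LABELS = {
    FertilizerProduct.UREA: "Urea",
    FertilizerProduct.CF: "Compound fertilizer (N-P2O5-K2O)",
    FertilizerProduct.DAP: "Diammonium phosphate",
    FertilizerProduct.ABC: "Ammonium bicarbonate",
}


class Crop(str, Enum):
    WHEAT = "wheat"
    MAIZE = "maize"


class Region(str, Enum):
    """Agricultural regions of the main upland-crop provinces."""

    NEC = "NEC"  # Northeast China
    NC = "NC"  # North China
    MLYR = "MLYR"  # Middle and lower reaches of the Yangtze River
    NWC = "NWC"  # Northwest China
    SSWC = "SSWC"  # South and Southwest China


#: Exact N -> N2O mass conversion (44/28), evaluated once in binary floating
#: point rather than stored as a rounded decimal.
N_TO_N2O: float = float(Fraction(44, 28))


def _norm_key(name: str) -> str:
    """Whitespace/case-insensitive lookup key for a province name."""
    return "".join(str(name).split()).lower()


# Alternate spellings seen in national statistics and the literature,
# mapped to the canonical spelling used by the default region map.
# "Shannxi" is a common variant of Shaanxi (distinct from Shanxi).
_PROVINCE_ALIASES = {
    "shannxi": "shaanxi",
    "neimongol": "innermongolia",
    "neimenggu": "innermongolia",
}


def normalize_province(name: str) -> str:
    """Collapse a province spelling to a canonical lookup key."""
    key = _norm_key(name)
    return _PROVINCE_ALIASES.get(key, key)


@dataclass(frozen=True)
class RegionMap:
    """Fixed assignment of provinces to agricultural regions.

    The default map covers the 19 provinces of the inventory; every
    province belongs to exactly one region.
    """

    entries: Mapping[str, Region]

    def __post_init__(self):
        object.__setattr__(self, "entries", dict(self.entries))
        index: dict[str, str] = {}
        for province in self.entries:
            key = normalize_province(province)
            if key in index:
                raise ValidationError(f"duplicate province in region map: {province!r}")
            index[key] = province
        object.__setattr__(self, "_index", index)

    def resolve(self, province: str) -> Region:
        """Return the agricultural region of ``province``.

        Lookup is case- and whitespace-insensitive and accepts the
        alternate spellings of the canonical table (e.g. ``Shannxi`` for
        Shaanxi).  Unknown provinces raise :class:`UnknownProvinceError`.
        """
        key = normalize_province(province)
        try:
            return self.entries[self._index[key]]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownProvinceError(province) from None

    def canonical_name(self, province: str) -> str:
        """Canonical spelling of ``province`` as stored in the map."""
        key = normalize_province(province)
        try:
            return self._index[key]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownProvinceError(province) from None

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @staticmethod
    @functools.lru_cache(maxsize=1)
    def default() -> "RegionMap":
        """The shipped 19-province map."""
        text = resources.files("uplandghg.data").joinpath("region_map.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
        return RegionMap({r["province"]: Region(r["region"]) for r in rows})


def resolve_region(province: str, region_map: RegionMap | None = None) -> Region:
    """Resolve a province name to its agricultural region.

    Uses the default 19-province map when ``region_map`` is not given.
    """
    return (region_map or RegionMap.default()).resolve(province)


#: Provinces with wheat activity in the default dataset (13) and maize
#: activity (all 19).  Wheat is absent from Northeast China and from
#: Chongqing, Guizhou and Guangxi.
DEFAULT_WHEAT_PROVINCES: tuple[str, ...] = (
    "Hebei",
    "Shanxi",
    "Shandong",
    "Henan",
    "Inner Mongolia",
    "Jiangsu",
    "Anhui",
    "Hubei",
    "Shaanxi",
    "Gansu",
    "Xinjiang",
    "Sichuan",
    "Yunnan",
)

DEFAULT_MAIZE_PROVINCES: tuple[str, ...] = (
    "Liaoning",
    "Jilin",
    "Heilongjiang",
    "Hebei",
    "Shanxi",
    "Shandong",
    "Henan",
    "Inner Mongolia",
    "Jiangsu",
    "Anhui",
    "Hubei",
    "Shaanxi",
    "Gansu",
    "Xinjiang",
    "Chongqing",
    "Sichuan",
    "Guizhou",
    "Yunnan",
    "Guangxi",
)


def cf_n_from_nutrient(total_nutrient: float) -> float:
    """Nitrogen content of a compound-fertilizer (CF) nutrient dose.

    The most common CF formulation carries N, P2O5 and K2O in equal
    proportion (1:1:1), so the N share of a total nutrient mass is one
    third.  Input and output are kg per hectare (or any consistent mass
    unit).

    This is an input-preparation helper: activity tables already carry
    per-product N in kg N ha^-1.
    """
    if total_nutrient < 0:
        raise ValidationError(f"total nutrient must be >= 0, got {total_nutrient}")
    return total_nutrient / 3.0


@dataclass(frozen=True)
class ActivityRecord:
    """One (province, crop, year) observation of cultivation activity.

    Parameters
    ----------
    province : str
        Province name (canonical spelling preferred; aliases accepted by
        :class:`RegionMap`).
    crop : Crop
    year : int
        Calendar year.
    area : float
        Sown area, ha (symbol ``A``).  Strictly positive.
    yield_total : float
        Total grain yield, kg (symbol ``Y``).  Non-negative.
    n_rate : mapping FertilizerProduct -> float
        Applied nitrogen per product, kg N ha^-1 (symbol ``NR``).  All
        four products must be present; zero is allowed.
    region : Region or None
        Agricultural region, normally resolved through a
        :class:`RegionMap`.  ``None`` marks a record (e.g. a national
        pseudo-record) for which region-indexed factors are undefined.
    """

    province: str
    crop: Crop
    year: int
    area: float
    yield_total: float
    n_rate: Mapping[FertilizerProduct, float]
    region: Region | None = None

    def __post_init__(self):
        object.__setattr__(self, "crop", Crop(self.crop))
        if self.region is not None:
            object.__setattr__(self, "region", Region(self.region))
        rates = {FertilizerProduct(p): float(v) for p, v in dict(self.n_rate).items()}
        object.__setattr__(self, "n_rate", rates)
        if not (self.area > 0) or math.isnan(self.area):
            raise ValidationError(
                f"{self.province}/{self.crop.value}/{self.year}: area must be > 0, got {self.area}"
            )
        if self.yield_total < 0 or math.isnan(self.yield_total):
            raise ValidationError(
                f"{self.province}/{self.crop.value}/{self.year}: yield must be >= 0, got {self.yield_total}"
            )
        missing = [p.value for p in FertilizerProduct if p not in rates]
        if missing:
            raise ValidationError(
                f"{self.province}/{self.crop.value}/{self.year}: n_rate missing products {missing}"
            )
        for p, v in rates.items():
            if v < 0 or math.isnan(v):
                raise ValidationError(
                    f"{self.province}/{self.crop.value}/{self.year}: n_rate[{p.value}] must be >= 0, got {v}"
                )

    @property
    def total_n_rate(self) -> float:
        """Total synthetic N rate over all four products, kg N ha^-1."""
        return sum(self.n_rate[p] for p in FertilizerProduct)


@dataclass(frozen=True)
class EFRegistry:
    """Registry of emission factors and conversion constants.

    ``ef_m`` maps each fertilizer product to its manufacture factor
    (kg CO2-eq per kg N); ``ef_d`` maps (region, crop) to the direct soil
    N2O factor (kg N2O-N per kg N).  ``gwp_n2o`` is the 100-year GWP of
    N2O and ``n_to_n2o`` the stoichiometric N -> N2O mass ratio.
    """

    ef_m: Mapping[FertilizerProduct, float]
    ef_d: Mapping[tuple[Region, Crop], float]
    gwp_n2o: float = 298.0
    n_to_n2o: float = N_TO_N2O

    def __post_init__(self):
        ef_m = {FertilizerProduct(p): float(v) for p, v in dict(self.ef_m).items()}
        ef_d = {
            (Region(r), Crop(c)): float(v) for (r, c), v in dict(self.ef_d).items()
        }
        object.__setattr__(self, "ef_m", ef_m)
        object.__setattr__(self, "ef_d", ef_d)
        for p, v in ef_m.items():
            if not v > 0:
                raise ValidationError(f"ef_m[{p.value}] must be > 0, got {v}")
        for (r, c), v in ef_d.items():
            if v < 0:
                raise ValidationError(f"ef_d[{r.value},{c.value}] must be >= 0, got {v}")
        if not self.gwp_n2o > 0:
            raise ValidationError(f"gwp_n2o must be > 0, got {self.gwp_n2o}")
        if not self.n_to_n2o > 0:
            raise ValidationError(f"n_to_n2o must be > 0, got {self.n_to_n2o}")

    def manufacture_factor(self, product: FertilizerProduct) -> float:
        try:
            return self.ef_m[FertilizerProduct(product)]
        except KeyError:
            raise MissingEmissionFactorError(
                f"no manufacture emission factor for product {FertilizerProduct(product).value!r}"
            ) from None

    def direct_factor(self, region: Region | None, crop: Crop) -> float:
        """Direct N2O factor for (region, crop).

        Absence of a factor (wheat in NEC, or a record without a region)
        is an error, not zero.
        """
        if region is None:
            raise MissingEmissionFactorError(
                f"record has no agricultural region; cannot look up a direct N2O "
                f"factor for crop {Crop(crop).value!r}"
            )
        key = (Region(region), Crop(crop))
        try:
            return self.ef_d[key]
        except KeyError:
            raise MissingEmissionFactorError(
                f"no direct N2O emission factor for region {key[0].value!r}, "
                f"crop {key[1].value!r}"
            ) from None

    # -- configuration round-trip ------------------------------------

    def to_yaml(self) -> str:
        """Serialise the registry to the YAML configuration format."""
        if self.n_to_n2o == N_TO_N2O:
            n_to_n2o: object = "44/28"
        else:
            n_to_n2o = self.n_to_n2o
        ef_d_nested: dict[str, dict[str, float]] = {}
        for (r, c), v in self.ef_d.items():
            ef_d_nested.setdefault(r.value, {})[c.value] = v
        payload = {
            "gwp_n2o": self.gwp_n2o,
            "n_to_n2o": n_to_n2o,
            "ef_m": {p.value: v for p, v in self.ef_m.items()},
            "ef_d": ef_d_nested,
        }
        return yaml.safe_dump(payload, sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "EFRegistry":
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValidationError("emission-factor config must be a mapping")
        for section in ("ef_m", "ef_d"):
            if section not in raw:
                raise ValidationError(f"emission-factor config missing section {section!r}")
        n_to_n2o = raw.get("n_to_n2o", N_TO_N2O)
        if isinstance(n_to_n2o, str):
            n_to_n2o = float(Fraction(n_to_n2o.replace(" ", "")))
        ef_d = {
            (Region(r), Crop(c)): float(v)
            for r, crops in raw["ef_d"].items()
            for c, v in crops.items()
        }
        return cls(
            ef_m={FertilizerProduct(p): float(v) for p, v in raw["ef_m"].items()},
            ef_d=ef_d,
            gwp_n2o=float(raw.get("gwp_n2o", 298.0)),
            n_to_n2o=float(n_to_n2o),
        )

    @staticmethod
    @functools.lru_cache(maxsize=1)
    def default() -> "EFRegistry":
        """The shipped default registry."""
        text = (
            resources.files("uplandghg.data")
            .joinpath("emission_factors.yaml")
            .read_text()
        )
        return EFRegistry.from_yaml(text)


@dataclass(frozen=True)
class EmissionResult:
    """Per-record inventory output, all masses in kg.

    ``yield_scaled`` is NaN when the record's total yield is zero (the
    intensity is undefined, never a division error).
    """

    province: str
    crop: Crop
    year: int
    region: Region | None
    e_m_by_product: Mapping[FertilizerProduct, float]  # kg CO2-eq
    e_d: float  # kg N2O
    total_co2eq: float  # kg CO2-eq
    area_scaled: float  # kg CO2-eq ha^-1
    yield_scaled: float  # kg CO2-eq kg grain^-1 (NaN if yield == 0)

    def __post_init__(self):
        object.__setattr__(self, "e_m_by_product", dict(self.e_m_by_product))

    @property
    def e_m_total(self) -> float:
        return sum(self.e_m_by_product.values())


_AGGREGATE_SCOPES = ("province", "region", "national")


@dataclass(frozen=True)
class AggregateResult:
    """Mean +/- SD of one emission quantity over years, at some scope."""

    scope: str  # 'province' | 'region' | 'national'
    name: str  # province name, region code, or 'national'
    crop: Crop | None
    quantity: str
    mean: float
    sd: float
    n_years: int

    def __post_init__(self):
        if self.scope not in _AGGREGATE_SCOPES:
            raise ValidationError(f"scope must be one of {_AGGREGATE_SCOPES}, got {self.scope!r}")
        if self.n_years < 1:
            raise ValidationError(f"n_years must be >= 1, got {self.n_years}")
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0, got {self.sd}")
        if self.n_years == 1 and self.sd != 0:
            raise ValidationError("sd must be 0 when n_years == 1")
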