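"""Shared test helpers: a literal-transcription oracle and record factories.

The naive oracle re-implements the four inventory formulas as directly as
possible, independent of the package's engine, so tests can compare the
two routes.
"""

from __future__ import annotations

import math

import numpy as np

from uplandghg.core import (
    ActivityRecord,
    Crop,
    FertilizerProduct,
    Region,
)

P = FertilizerProduct


def naive_inventory(
    n_rate: dict[FertilizerProduct, float],
    area: float,
    yield_total: float,
    ef_m: dict[FertilizerProduct, float],
    ef_d: float,
    gwp: float = 298.0,
):
    """Literal transcription of the inventory formulas.

    E_M[p] = NR[p] * A * EF_M[p]
    E_D    = (sum NR) * A * EF_D * 44/28
    total  = sum E_M + E_D * GWP
    area-scaled  = total / A
    yield-scaled = total / Y
    """
    e_m = {p: n_rate[p] * area * ef_m[p] for p in n_rate}
    e_d = sum(n_rate.values()) * area * ef_d * 44 / 28
    total = sum(e_m.values()) + e_d * gwp
    return {
        "e_m": e_m,
        "e_d": e_d,
        "total": total,
        "area_scaled": total / area,
        "yield_scaled": total / yield_total if yield_total > 0 else math.nan,
    }


def make_record(
    province: str = "Hebei",
    crop: Crop = Crop.WHEAT,
    year: int = 2015,
    area: float = 1000.0,
    yield_total: float = 5_000_000.0,
    rates: tuple[float, float, float, float] = (124.0, 72.0, 17.0, 9.0),
    region: Region | None = Region.NC,
) -> ActivityRecord:
    urea, cf, dap, abc = rates
    return ActivityRecord(
        province=province,
        crop=crop,
        year=year,
        area=area,
        yield_total=yield_total,
        n_rate={P.UREA: urea, P.CF: cf, P.DAP: dap, P.ABC: abc},
        region=region,
    )


def random_record(rng: np.random.Generator) -> ActivityRecord:
    """A random valid record in a region/crop combination that has factors."""
    crop = Crop.WHEAT if rng.random() < 0.5 else Crop.MAIZE
    regions = [r for r in Region if not (r is Region.NEC and crop is Crop.WHEAT)]
    region = regions[int(rng.integers(len(regions)))]
    return make_record(
        province="synthetic",
        crop=crop,
        year=int(rng.integers(2015, 2018)),
        area=float(rng.uniform(1.0, 5e6)),
        yield_total=float(rng.uniform(0.0, 3e10)),
        rates=tuple(rng.uniform(0.0, 200.0, size=4)),
        region=Region(region),
    )
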