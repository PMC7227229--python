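"""The per-record emission equations: examples, invariants, oracle checks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uplandghg import engine
from uplandghg.core import (
    Crop,
    EFRegistry,
    FertilizerProduct,
    MissingEmissionFactorError,
    Region,
    ValidationError,
)

from helpers import make_record, naive_inventory, random_record

P = FertilizerProduct


class TestManufactureEmissions:
    def test_single_product_hand_value(self, registry):
        # 100 kg N/ha of urea on 1000 ha at 8.1 kg CO2-eq per kg N
        rec = make_record(area=1000.0, rates=(100.0, 0.0, 0.0, 0.0))
        e_m = engine.manufacture_emissions(rec, registry)
        assert e_m[P.UREA] == pytest.approx(810_000.0)
        assert e_m[P.CF] == e_m[P.DAP] == e_m[P.ABC] == 0.0

    def test_zero_rates_give_zero(self, registry):
        rec = make_record(rates=(0.0, 0.0, 0.0, 0.0))
        assert all(v == 0.0 for v in engine.manufacture_emissions(rec, registry).values())

    def test_missing_factor_for_used_product(self):
        reg = EFRegistry(
            ef_m={P.UREA: 8.1}, ef_d={(Region.NC, Crop.WHEAT): 0.0028}
        )
        rec = make_record(rates=(100.0, 10.0, 0.0, 0.0))
        with pytest.raises(MissingEmissionFactorError, match="cf"):
            engine.manufacture_emissions(rec, reg)
        # the same product at rate zero needs no factor
        rec = make_record(rates=(100.0, 0.0, 0.0, 0.0))
        assert engine.manufacture_emissions(rec, reg)[P.CF] == 0.0

    def test_national_wheat_record_reproduces_published_urea_total(self, fixture):
        # printed national rates and implied area give ~23.4 Mt for urea
        rec = fixture.national_records[Crop.WHEAT]
        e_m = engine.manufacture_emissions(rec, fixture.registry)
        assert e_m[P.UREA] * 1e-9 == pytest.approx(23.42, rel=2e-3)
        assert sum(e_m.values()) * 1e-9 == pytest.approx(41.44, rel=2e-3)


class TestDirectN2O:
    def test_hand_value(self, registry):
        reg = EFRegistry(ef_m=registry.ef_m, ef_d={(Region.NC, Crop.WHEAT): 0.01})
        rec = make_record(area=1.0, rates=(100.0, 0.0, 0.0, 0.0))
        assert engine.direct_n2o_emissions(rec, reg) == pytest.approx(100 * 0.01 * 44 / 28)

    def test_nc_wheat_at_national_rate(self, registry):
        rec = make_record(area=1.0, rates=(124.0, 72.0, 17.0, 9.0))
        e_d = engine.direct_n2o_emissions(rec, registry)
        assert e_d == pytest.approx(222 * 0.0028 * 44 / 28)
        assert e_d == pytest.approx(0.9768, abs=5e-5)

    def test_zero_factor_gives_zero(self, registry):
        reg = EFRegistry(ef_m=registry.ef_m, ef_d={(Region.NC, Crop.WHEAT): 0.0})
        assert engine.direct_n2o_emissions(make_record(), reg) == 0.0

    def test_nec_wheat_has_no_factor(self, registry):
        rec = make_record(province="Heilongjiang", region=Region.NEC)
        with pytest.raises(MissingEmissionFactorError, match="NEC"):
            engine.direct_n2o_emissions(rec, registry)


class TestIntensities:
    def test_co2eq_conversion_is_gwp_multiple(self, registry):
        assert engine.co2eq_of_n2o(0.0, registry) == 0.0
        assert engine.co2eq_of_n2o(2.0, registry) == 596.0

    def test_yield_scaled_hand_value(self, registry):
        # 1000 kg CO2-eq over 5000 kg grain, no N2O term
        assert engine.yield_scaled(1000.0, 0.0, 5000.0, registry) == 0.2

    def test_yield_scaled_undefined_for_zero_yield(self, registry):
        assert math.isnan(engine.yield_scaled(1000.0, 1.0, 0.0, registry))

    def test_area_scaled_rejects_nonpositive_area(self, registry):
        with pytest.raises(ValidationError):
            engine.area_scaled(1000.0, 1.0, 0.0, registry)

    def test_area_scaled_scale_invariance(self, registry):
        a = engine.area_scaled(1e6, 1e3, 500.0, registry)
        b = engine.area_scaled(2e6, 2e3, 1000.0, registry)
        assert a == pytest.approx(b, rel=1e-14)


class TestRunRecord:
    def test_total_is_definitional(self, registry):
        rec = make_record()
        res = engine.run_record(rec, registry)
        assert res.total_co2eq == pytest.approx(
            res.e_m_total + res.e_d * registry.gwp_n2o, rel=1e-15
        )
        assert res.area_scaled * rec.area == pytest.approx(res.total_co2eq, rel=1e-12)
        assert res.yield_scaled * rec.yield_total == pytest.approx(res.total_co2eq, rel=1e-12)
        # algebraic identity: area-scaled / yield-scaled = yield per ha
        assert res.area_scaled / res.yield_scaled == pytest.approx(
            rec.yield_total / rec.area, rel=1e-12
        )

    def test_all_zero_rates_give_all_zero_result(self, registry):
        res = engine.run_record(make_record(rates=(0, 0, 0, 0)), registry)
        assert res.e_m_total == res.e_d == res.total_co2eq == res.area_scaled == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_linearity_in_rates(self, registry, k):
        """Scaling every N rate by k scales every emission quantity by k."""
        base = make_record(rates=(120.0, 70.0, 20.0, 10.0))
        scaled = make_record(rates=(120.0 * k, 70.0 * k, 20.0 * k, 10.0 * k))
        r0 = engine.run_record(base, registry)
        r1 = engine.run_record(scaled, registry)
        assert r1.e_m_total == pytest.approx(k * r0.e_m_total, rel=1e-12, abs=1e-9)
        assert r1.e_d == pytest.approx(k * r0.e_d, rel=1e-12, abs=1e-9)
        assert r1.total_co2eq == pytest.approx(k * r0.total_co2eq, rel=1e-12, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(split=st.floats(min_value=0.01, max_value=0.99))
    def test_additivity_over_subareas(self, registry, split):
        """A record equals the sum of the record split into two sub-areas."""
        area, yield_total = 1000.0, 6e6
        whole = engine.run_record(make_record(area=area, yield_total=yield_total), registry)
        a = engine.run_record(
            make_record(area=area * split, yield_total=yield_total * split), registry
        )
        b = engine.run_record(
            make_record(area=area * (1 - split), yield_total=yield_total * (1 - split)),
            registry,
        )
        assert a.e_m_total + b.e_m_total == pytest.approx(whole.e_m_total, rel=1e-12)
        assert a.e_d + b.e_d == pytest.approx(whole.e_d, rel=1e-12)
        assert a.total_co2eq + b.total_co2eq == pytest.approx(whole.total_co2eq, rel=1e-12)

    def test_unit_consistency_of_intensities(self, registry):
        """Tonne-based inputs with tonne-based factors give the same intensities."""
        rec = make_record(area=1000.0, yield_total=6e6)
        res = engine.run_record(rec, registry)
        # express emissions in t instead of kg: divide both terms by 1000
        a = engine.area_scaled(res.e_m_total / 1e3, res.e_d / 1e3, rec.area, registry)
        assert a == pytest.approx(res.area_scaled / 1e3, rel=1e-12)

    def test_oracle_equivalence_on_random_records(self, registry):
        """The engine matches a literal formula transcription to <1e-12."""
        rng = np.random.default_rng(2015)
        for _ in range(1000):
            rec = random_record(rng)
            res = engine.run_record(rec, registry)
            ref = naive_inventory(
                rec.n_rate,
                rec.area,
                rec.yield_total,
                registry.ef_m,
                registry.direct_factor(rec.region, rec.crop),
                registry.gwp_n2o,
            )
            assert res.e_m_total == pytest.approx(sum(ref["e_m"].values()), rel=1e-12)
            assert res.e_d == pytest.approx(ref["e_d"], rel=1e-12)
            assert res.total_co2eq == pytest.approx(ref["total"], rel=1e-12)
            assert res.area_scaled == pytest.approx(ref["area_scaled"], rel=1e-12)
            if rec.yield_total > 0:
                assert res.yield_scaled == pytest.approx(ref["yield_scaled"], rel=1e-12)
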