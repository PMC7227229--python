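"""Multi-year aggregation, rollups, shares, rate-class binning, reports."""

import math

import numpy as np
import pandas as pd
import pytest

from uplandghg.aggregate import (
    DEFAULT_RATE_BIN_EDGES,
    build_report,
    format_mean_sd,
    mean_sd_over_years,
    rate_class_area_fractions,
    render_table_markdown,
    rollup,
    share_of_total,
)
from uplandghg.core import AggregateResult, Crop, ValidationError

from helpers import make_record


class TestMeanSd:
    @pytest.mark.parametrize(
        "values,mean,sd,n",
        [
            ((10.0, 10.0, 10.0), 10.0, 0.0, 3),
            ((1.0, 2.0, 3.0), 2.0, 1.0, 3),  # sample SD, n-1 denominator
            ((5.0,), 5.0, 0.0, 1),
        ],
    )
    def test_examples(self, values, mean, sd, n):
        agg = mean_sd_over_years(values)
        assert agg.mean == pytest.approx(mean)
        assert agg.sd == pytest.approx(sd)
        assert agg.n_years == n

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            mean_sd_over_years([])


class TestRollup:
    def test_extensive_conservation(self, results):
        """Provincial sums = regional sums = national totals, unrounded."""
        for crop in Crop:
            national = rollup(results, "national", crop, "e_m_total")
            regional = rollup(results, "region", crop, "e_m_total")
            provincial = rollup(results, "province", crop, "e_m_total")
            assert sum(a.mean for a in regional.values()) == pytest.approx(
                national.mean, rel=1e-12
            )
            assert sum(a.mean for a in provincial.values()) == pytest.approx(
                national.mean, rel=1e-12
            )

    def test_national_sd_is_interannual(self, results):
        """The national SD comes from yearly national totals."""
        sub = results[results["crop"] == "wheat"]
        yearly = sub.groupby("year")["e_m_total"].sum()
        agg = rollup(results, "national", Crop.WHEAT, "e_m_total")
        assert agg.sd == pytest.approx(float(yearly.std(ddof=1)), rel=1e-12)
        assert agg.n_years == yearly.size

    def test_single_province_region_equals_province(self, results):
        """A region with one province rolls up to that province's value."""
        sub = results[results["crop"] == "wheat"]
        one_prov = sub[sub["province"] == "Jiangsu"]
        prov = rollup(one_prov, "province", Crop.WHEAT, "e_d_n2o")["Jiangsu"]
        reg = rollup(one_prov, "region", Crop.WHEAT, "e_d_n2o")["MLYR"]
        assert reg.mean == prov.mean and reg.sd == prov.sd

    def test_intensity_recomputed_from_pooled_totals(self, results):
        """Regional intensity = pooled totals ratio, inside provincial range per year."""
        for crop in Crop:
            sub = results[results["crop"] == crop.value]
            for region, group in sub.groupby("region"):
                for year, g in group.groupby("year"):
                    pooled = g["total_co2eq"].sum() / g["area_ha"].sum()
                    provincial = g["total_co2eq"] / g["area_ha"]
                    assert provincial.min() - 1e-9 <= pooled <= provincial.max() + 1e-9
                agg = rollup(sub, "region", crop, "area_scaled")[region]
                sums = group.groupby("year")[["total_co2eq", "area_ha"]].sum()
                yearly = sums["total_co2eq"] / sums["area_ha"]
                assert agg.mean == pytest.approx(float(yearly.mean()), rel=1e-12)

    def test_unknown_crop_or_quantity_rejected(self, results):
        with pytest.raises(ValidationError):
            rollup(results[results["crop"] == "wheat"], "national", Crop.MAIZE, "e_m_total")
        with pytest.raises(ValidationError):
            rollup(results, "national", Crop.WHEAT, "not_a_metric")


class TestShares:
    def test_part_equal_to_whole_is_100(self):
        whole = mean_sd_over_years([5.0, 6.0], quantity="e_m_total")
        assert share_of_total(whole, whole) == 100.0

    def test_exhaustive_partition_sums_to_100(self, results):
        national = rollup(results, "national", Crop.WHEAT, "e_m_total")
        provincial = rollup(results, "province", Crop.WHEAT, "e_m_total")
        total = sum(share_of_total(p, national) for p in provincial.values())
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_mismatched_quantity_rejected(self):
        a = mean_sd_over_years([1.0], quantity="e_m_total")
        b = mean_sd_over_years([1.0], quantity="e_d_n2o")
        with pytest.raises(ValidationError):
            share_of_total(a, b)

    def test_zero_total_rejected(self):
        part = mean_sd_over_years([1.0], quantity="x")
        whole = mean_sd_over_years([0.0], quantity="x")
        with pytest.raises(ValidationError):
            share_of_total(part, whole)


class TestRateClasses:
    def test_single_record_fills_its_bin(self):
        rec = make_record(rates=(124.0, 72.0, 17.0, 9.0))  # total 222
        fractions = rate_class_area_fractions([rec])
        assert fractions[(200.0, 250.0)] == 1.0
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_two_equal_area_records(self):
        edges = (0.0, 150.0, 200.0, 250.0, math.inf)
        recs = [
            make_record(rates=(120.0, 0.0, 0.0, 0.0)),
            make_record(rates=(220.0, 0.0, 0.0, 0.0)),
        ]
        fractions = rate_class_area_fractions(recs, edges)
        assert fractions == {
            (0.0, 150.0): 0.5,
            (150.0, 200.0): 0.0,
            (200.0, 250.0): 0.5,
            (250.0, math.inf): 0.0,
        }

    def test_left_closed_right_open(self):
        rec = make_record(rates=(200.0, 0.0, 0.0, 0.0))
        fractions = rate_class_area_fractions([rec])
        assert fractions[(200.0, 250.0)] == 1.0
        assert fractions[(150.0, 200.0)] == 0.0

    def test_rate_outside_bins_is_an_error(self):
        rec = make_record(rates=(220.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValidationError, match="outside"):
            rate_class_area_fractions([rec], (0.0, 100.0))

    def test_default_edges_cover_generated_data(self, dataset):
        fractions = rate_class_area_fractions(dataset)
        assert sum(fractions.values()) == pytest.approx(1.0)
        assert list(fractions) == list(
            zip(DEFAULT_RATE_BIN_EDGES[:-1], DEFAULT_RATE_BIN_EDGES[1:])
        )


class TestReportTables:
    def test_provincial_column_sums_to_national(self, results):
        tables = build_report(results)
        national = rollup(results, "national", Crop.WHEAT, "e_m_total")
        col = tables["manufacture_by_province"]["wheat_mean"].dropna()
        assert col.sum() == pytest.approx(national.mean * 1e-9, rel=1e-12)

    def test_national_components_table(self, results):
        tables = build_report(results)
        nat = tables["national_components"]
        assert len(nat) == 6  # four products, soil N2O, total
        urea = rollup(results, "national", Crop.WHEAT, "e_m_urea")
        assert nat.iloc[0]["wheat_mean"] == pytest.approx(urea.mean * 1e-9, rel=1e-12)

    def test_empty_input_yields_empty_tables_with_headers(self):
        tables = build_report(pd.DataFrame(columns=["province", "region", "crop", "year"]))
        for table in tables.values():
            assert table.empty
            assert len(table.columns) > 0

    def test_markdown_rendering(self, results):
        tables = build_report(results)
        md = render_table_markdown(tables["manufacture_by_province"])
        assert md.startswith("| province | region | wheat | maize |")
        assert "±" in md
        # provinces without wheat render as a dash, not NaN
        assert "| Liaoning | NEC | – |" in md

    def test_format_mean_sd(self):
        assert format_mean_sd(5.012, 0.118) == "5.01 ± 0.12"
        assert format_mean_sd(math.nan, math.nan) == "–"
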