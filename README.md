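# uplandghg

Greenhouse-gas accounting for synthetic nitrogen fertilizer in the wheat
and maize systems of China's main upland provinces.

Synthetic N drives crop-production GHG emissions through two channels:
manufacturing the fertilizer (an energy-intensive industrial chain from
fossil-fuel mining through ammonia synthesis to product conversion) and
direct N₂O release from fertilized soil. `uplandghg` implements the
standard emission-factor inventory for both channels, for four products
(urea, compound fertilizer CF, diammonium phosphate DAP, ammonium
bicarbonate ABC), across 19 provinces grouped into five agricultural
regions (NEC, NC, MLYR, NWC, SSWC), with stratified multi-year
aggregation and emission-intensity metrics. It is aimed at researchers
building regional agricultural GHG inventories and at anyone who wants
the published 2015–2017 national numbers to be reproducible from code.

## Model

For a province–crop–year activity record with sown area *A* (ha), grain
yield *Y* (kg) and per-product N rates *NR&#8346;* (kg N ha⁻¹):

- manufacture emissions, per product *p*:
  **E_M[p] = NR₍p₎ · A · EF_M[p]** (kg CO₂-eq), with life-cycle factors
  EF_M = 8.1 (urea), 7.4 (CF), 10.3 (DAP), 7.2 (ABC) kg CO₂-eq per kg N;
- direct soil N₂O:
  **E_D = (Σₚ NR₍p₎) · A · EF_D(region, crop) · 44/28** (kg N₂O), using
  region- and crop-specific factors (e.g. MLYR wheat 0.0086, NC maize
  0.0070 kg N₂O-N per kg N; no factor exists for NEC wheat);
- CO₂-equivalent total: **E = Σₚ E_M[p] + 298 · E_D**, with 298 the
  100-year GWP of N₂O (the GWP multiplies the N₂O term only — E_M is
  already CO₂-eq);
- intensities: area-scaled **E / A** and yield-scaled **E / Y**.

Extensive quantities aggregate province → region → national by summing
within each year; reported values are the interannual mean ± sample SD.
Intensities at any aggregate level are recomputed from pooled totals,
never averaged across provinces.

Because the real provincial statistics behind the published inventory are
not deposited, the package ships a seeded synthetic-data generator with
the same structure (13 wheat / 19 maize provinces, 3 years, rates centred
on the published national means) plus the full set of published national
and provincial aggregates as a built-in reference fixture.

## Worked example

```bash
uplandghg simulate --seed 7 --out activity.csv   # 96 records, 2015–2017
uplandghg run activity.csv --out-dir out
```

prints

```
wheat: total 48.22 ± 1.33 Mt CO2-eq/yr
maize: total 48.42 ± 1.37 Mt CO2-eq/yr
wrote 10 file(s) to out
```

— the national mean ± interannual SD of total CO₂-eq emissions
(manufacture + soil N₂O) per crop for this synthetic draw. `out/`
contains per-record results, provincial/regional/national report tables
in CSV and markdown, and `national_summary.json`; e.g.
`out/national_components.md`:

```
| component                                            | wheat        | maize        |
| GHG emissions from urea manufacture (Mt CO2-eq yr-1) | 19.68 ± 0.50 | 21.01 ± 0.63 |
| GHG emissions from CF manufacture (Mt CO2-eq yr-1)   | 12.38 ± 0.36 | 10.59 ± 0.29 |
| ...                                                  |              |              |
| Direct N2O emissions from the soil (Gg N2O yr-1)     | 36.61 ± 1.13 | 40.73 ± 1.06 |
| Total national GHG emissions (Mt CO2-eq yr-1)        | 48.22 ± 1.33 | 48.42 ± 1.37 |
```

`uplandghg validate` reconciles the method against the published
2015–2017 aggregates without any input data (42 desk-scale checks:
identities among printed totals, recomputed national manufacture
emissions and intensities, regional rollups of the printed provincial
tables, provincial shares) and exits non-zero on any failure.

The same functionality is available as a library:

```python
from uplandghg import GeneratorConfig, generate_activity, EFRegistry, run_records, rollup, Crop

records = generate_activity(GeneratorConfig(seed=7))
results = run_records(records, EFRegistry.default())
national = rollup(results, "national", Crop.WHEAT, "total_co2eq")
print(f"{national.mean * 1e-9:.2f} ± {national.sd * 1e-9:.2f} Mt CO2-eq/yr")
# 48.22 ± 1.33 Mt CO2-eq/yr
```

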