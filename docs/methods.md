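# Methods

## Inventory model

The package implements a tier-1 style emission-factor inventory for
synthetic nitrogen use in upland wheat and maize. The unit of account is
the activity record — one (province, crop, year) observation carrying
sown area *A* (ha), total grain yield *Y* (kg) and per-product N
application rates *NR₍p₎* (kg N ha⁻¹) for urea, compound fertilizer (CF),
diammonium phosphate (DAP) and ammonium bicarbonate (ABC).

Two emission channels are charged:

1. **Manufacture.** `E_M[p] = NR[p] · A · EF_M[p]`, with life-cycle
   factors per kg of fertilizer-N covering fuel mining and transport,
   ammonia synthesis and conversion to product. Defaults: urea 8.1,
   CF 7.4, DAP 10.3, ABC 7.2 kg CO₂-eq (kg N)⁻¹.
2. **Direct soil N₂O.** `E_D = NR_total · A · EF_D(region, crop) · 44/28`
   in kg N₂O. The direct factor applies to synthetic N as a class, so the
   rate is summed over products before the factor is applied. The factor
   table is indexed by five agricultural regions × two crops; the
   (NEC, wheat) cell is genuinely absent, and the registry raises a
   "no factor" error on lookup rather than substituting zero — silent
   zeros would corrupt regional totals undetectably.

The CO₂-equivalent total is `E = ΣE_M + gwp · E_D` with `gwp = 298`
(100-year horizon). The GWP deliberately multiplies only the N₂O term: a
formulation that multiplies the sum `(E_M + E_D)` by 298 is dimensionally
inconsistent, since E_M is already in CO₂-eq, and it is the
`E_M + 298·E_D` form that exactly reproduces the published identities
52.11 = 41.44 + 298 × 0.03582 and 80.40 = 59.71 + 298 × 0.06944 Mt.
Intensities are `E/A` (area-scaled) and `E/Y` (yield-scaled); a
zero-yield record has an undefined yield intensity and returns NaN rather
than raising or dividing by zero.

The 44/28 N→N₂O conversion is stored as the exact rational evaluated in
floating point, not a rounded 1.571, removing avoidable drift. All
internal computation is in kg and ha; Mt/Gg/t conversions happen only at
report rendering, and rounding (2 decimals in the standard tables)
happens strictly at render time.

## Aggregation and uncertainty

Extensive quantities (emissions, area, yield) are summed over provinces
*within each year*; the reported value is the mean of the yearly totals
and the uncertainty is their sample standard deviation (ddof = 1).
Interannual variation is the only uncertainty source the inventory
propagates, so a national SD is the SD of three yearly national totals,
never a combination of provincial SDs. With three years the SD
convention is material; the sample convention is the package's choice
and a population-SD user can scale by √(2/3).

Intensities are never averaged across provinces. At any aggregate level
they are recomputed per year from pooled totals, `Σ E / Σ A` (or `Σ Y`),
then averaged over years — the area-weighted estimate a per-ha intensity
must be. Within each year the pooled regional intensity necessarily lies
between the minimum and maximum provincial intensities, which is the
invariant the tests assert (the analogous statement on multi-year means
can fail marginally when area weights shift between years).

Fertilization-rate structure is summarised as area fractions over
left-closed, right-open rate classes, default 50 kg N ha⁻¹ steps from 0
to 300 with an open top class. A rate falling outside the supplied edges
is an error rather than silently dropped area.

## Synthetic activity data

The provincial statistics behind the published inventory (national
statistical yearbooks and price-survey compilations) are not deposited,
so the generator emulates their structure rather than their values:

- one record per (province, crop, year); 13 wheat provinces (none in
  NEC) and 19 maize provinces, three years (2015–2017 by default);
- per-product rates drawn once per (province, crop) from a normal
  distribution centred on the published national means (wheat
  124/72/17/9, maize 111/62/15/8 kg N ha⁻¹) with a cross-province CV of
  0.25, truncated at zero. The published record gives only national
  means; the 0.25 dispersion is a documented, configurable guess;
- a multiplicative year effect (CV 0.05) shared across products within a
  province, mimicking correlated interannual variation in fertilization
  intensity — this is what generates the interannual SDs the aggregation
  layer reports;
- log-normal provincial sown areas (median 1.2 Mha, σ = 0.9), giving
  national totals of the right order of magnitude (tens of Mha), with
  3% year-to-year noise; per-ha yields uniform on 4,000–7,500 kg ha⁻¹.

Identical configuration (including seed) reproduces the identical
dataset, byte-for-byte through the CSV writer. Because the engine is
exactly linear in `NR·A`, regressing generated `E_M[p]` on `NR[p]·A`
recovers each manufacture factor to machine precision — the parameter-
recovery test.

An optional calibration step reweights sown areas so the published modal
rate classes hold their published area shares (wheat: 42.5% of area in
200–250 kg N ha⁻¹; maize: 64.0% in 150–200). Scaling areas leaves rates,
and hence class membership, unchanged, so the target is met exactly.

What the generator does *not* emulate: true cross-province rate
dispersion and rate–area correlation, systematic regional differences in
rates or yields, trends across years, and reporting error in the
underlying surveys. Tests passing on synthetic data therefore validate
the accounting machinery, not the realism of any particular provincial
estimate.

## Reference fixture and reconciliation

All published constants — the emission-factor registry, national rates
and N consumption, provincial manufacture and soil-N₂O tables, regional
rollups and intensities — are embedded as a fixture. National
pseudo-records are reconstructed from printed values: sown area as
consumption ÷ mean rate (wheat 5.18×10⁹ kg ÷ 222 kg ha⁻¹ ≈ 2.33×10⁷ ha),
total yield as total emissions ÷ printed yield-scaled intensity. These
records carry no region (a national record has no single direct-N₂O
factor), so they exercise the manufacture channel; the N₂O channel is
reconciled through the printed provincial tables.

Reconciliation tolerances follow the provenance of the inputs: identities
among printed values must hold to the printed precision (±0.005 of the
last digit shown); recomputations from rounded printed inputs get the
rounding propagated (e.g. per-product rates printed to the unit imply a
±0.5/rate relative band, large for the 8–17 kg N ha⁻¹ DAP/ABC rates);
regional sums of provincial values rounded to 0.01 may differ from the
printed regional total by up to 0.02 (and do, e.g. MLYR wheat N₂O
17.74 from rows vs 17.73 printed) — the package always sums unrounded
values and notes this in the validation output. The published maize
per-product rates sum to 196 against a printed national mean of 197
kg N ha⁻¹ (input rounding); the implied maize area uses the printed 197.

## Problem sizes

Everything is desk-scale: the default synthetic dataset is 96 records,
the property tests use 10³ random records (oracle equivalence) and ~10³–
10⁴ pooled generated records (factor recovery, mean-rate recovery), and
the full suite plus the reconciliation run completes in a few seconds on
one CPU.

## Known limitations

- Direct soil N₂O only: no indirect N₂O (volatilisation/leaching), no
  background emissions, no manure N, matching the scope of the source
  inventory.
- Emission factors are fixed inputs; the package does not re-estimate
  them from field data, and the GWP horizon is a configurable constant
  rather than a set of alternatives.
- The region map and crop-province lists are the fixed study design;
  custom maps are accepted but carry no climatic logic.
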