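# Methods

## Model scope and structure

flockcarbon simulates one farm-year of a dairy sheep or goat farm as a
deterministic pipeline: the farm description (land parcels, herd
inventory by production class, purchases, milk and meat sold, grazing
schedule, twelve months of climate) fixes an average adult diet; the diet
fixes enteric methane and per-head excreta; excreta, bedding and the
grazing schedule fix the manure pools and the nitrogen cascades (NH₃,
direct and indirect N₂O, nitrate leaching); purchases fix embedded CO₂;
land use fixes silage losses, crop residues and carbon sequestration; and
the resulting emission ledger plus the product flows fix every footprint.
There is no sub-annual herd dynamics: the year is the only horizon, and
months appear only through climate (degree-days, drainage) and the
temperature scenario.

The model is empirical, not mechanistic. Herd flows, excreta and forage
yield are multiple linear regressions with published coefficients,
sample sizes and residual standard errors; everything else is
emission-factor bookkeeping. Where two printed versions of a regression
coefficient disagree, the complete model string was taken as
authoritative, and both readings are kept in
`src/flockcarbon/data/model_coefficients.csv` so either can be selected.

## Key equations and conventions

- **Enteric CH₄** (g/head/day) = DMI · (Ym/100) · (18.55/55.65), with the
  methane conversion factor Ym = 9.75 − 0.05 · OMD (OMD in percent). The
  constants are the gross-energy density of feed DM (18.55 MJ/kg) and the
  energy content of methane (55.65 MJ/kg). `ym()` deliberately rejects
  fractional OMD inputs (≤ 1) to catch unit mistakes, while the excreta
  regression takes OMD as a fraction — the two sub-models inherited
  different conventions from their sources, so both guard their own.
- **Excreta.** Fecal and urinary N are independent regressions in N
  intake; near the trial-mean intake they jointly predict slightly more N
  than is ingested. The raw predictions are returned by default (they are
  the published models); the whole-farm pipeline enables `cap_n`, which
  keeps fecal N and caps urinary N at the residual pool so the farm N
  balance conserves mass. All count/mass predictions are clamped at zero,
  with raw values kept for diagnostics.
- **N₂O factors.** Factors printed per kg of N (soil direct 0.3%/1%/1%,
  volatilization 0.5%, leaching 2.5%, purchased feed 2%/1%) are N₂O-N and
  converted to N₂O mass with 44/28 at ledger entry; factors stated as N₂O
  directly (0.0015 kg per kg NH₃ in housing; 5 g per kg of manufactured
  fertilizer N) are not converted.
- **Drainage** is max(0, rainfall − ETc) summed over months (the
  water-balance convention; the alternative ETc − rainfall is negative in
  a continental-Mediterranean climate and would zero the leaching
  pathway). Leached N = min(0.3, drainage/1000 mm) · applied N; the
  linear-in-drainage rule with a 30% cap is a package default, since only
  the functional dependence (applied N, drained water) is specified.
- **Carbon sequestration** = humification · C · 44/12, with C = 45% of
  residue DM plus 13.4 · applied-manure N (the manure C:N ratio). The
  humification coefficient defaults to 0.1. Cereal residues use 1758 kg
  DM/ha of straw plus stubble; maize residues are 19% and alfalfa 34% of
  harvest.
- **CO₂e** = CO₂ + 28 · CH₄ + 298 · N₂O. TCF = PCF + SY + iLUC − CS holds
  as an exact identity on every run (tested). iLUC charges 143 g
  CO₂/m²·yr on the off-farm area supporting purchased feed; SY charges
  2.98 kg CO₂/kg of imported soybean.
- **FPCM** = liters · (0.25 + 0.085 · fat% + 0.035 · protein%), which
  normalizes to ≈ 1 at the 6.5% fat / 5.8% protein reference. The
  coefficients are configurable; this form was chosen for that
  normalization property.
- **Allocation.** AF = clamp(1 − 5.7717 · R, 0, 1) with R the meat/milk
  mass ratio per hectare (milk mass at 1.034 kg/L). Allocation applies to
  the per-liter functional unit only; per-hectare, per-LU and per-female
  report the unallocated total, which is why the per-ha and per-liter
  columns of the scenario table can move differently.

## Defaults that are package choices (not published values)

- Livestock-unit coefficients: adults 0.15, replacements 0.09,
  lambs/kids 0.05 (standard EU small-ruminant scale; CSV-overridable).
- Manure-CH₄ chain: B₀ = 0.19 m³ CH₄/kg VS, MCF = 2%, VS = 80% of DM,
  CH₄ density 0.67 kg/m³, for solid-stored sheep/goat manure; manure DM
  is 35%.
- Electricity: kWh/yr = 0.2 · lactating females · daily milking minutes,
  so a 100-ewe parlour milking 120 min/day draws 2 400 kWh/yr, inside the
  range reported for small-ruminant parlours. Diesel defaults to
  37 L/LU·yr when no purchase is recorded.
- Housed-manure P and K contents (0.12%, 0.9% fresh weight), bedding
  straw N (0.6%), legume fixation (alfalfa 150, other legumes 60 kg
  N/ha·yr), feed N/P contents of the fixture feed table, water and energy
  factors of imported products, drinking water (7–8 L/head·day): all
  literature-informed defaults, all overridable.
- Atmospheric N deposition (10 kg N/ha·yr) is applied to the whole
  farmland including communal pasture — a stated assumption.
- Round-bale silage plastic (1.2 kg/t) is a default; only bag silage
  (0.68 kg/t) and the 1.3 kg small silo are published.
- The temperature response (0.23% milk loss per °C, weaker fat/protein
  responses) is calibrated so a +2 °C year loses 0.46% of milk, matching
  the reported loss for the Manchega breeding seasons; the six
  season-specific response equations behind that number are not
  published, so the response table is pluggable.

## Whole-farm diet construction

The average adult ration spreads on-farm forage production (at 85%
utilization) and purchased forage, concentrate and soybean over the adult
herd plus replacements at 45% of adult intake. When the farm grazes,
pasture substitutes conserved feed at equal DM intake, with the pasture
share equal to the grazing-time fraction capped at 50%. Replacement-
animal excreta use the metabolic-weight regressions at the Gompertz
weight for 240 days of age. This is deliberately coarse — the model's
feeding module answers "what does the average head eat", not "what should
each batch be fed".

## Synthetic data

`gen_farm` draws each farm field from a left-truncated normal at the
surveyed per-breed-group mean and standard deviation. The sampler solves
for the location parameter so the truncated distribution's **mean equals
the printed mean** — naive rejection sampling would inflate the mean by
up to half a standard deviation on fields where sd ≈ mean (herd size,
communal area). Cross-field consistency is then enforced: lactating ≤
present females, offspring from the demography model, milk sold = per-ewe
yield × census − suckled milk (35 days × 1 L/day per offspring), and live
weight sold derived from culled offspring at the Gompertz slaughter
weight. The flock genetic index is drawn at mean 8 ± 1.5 (the survey
index is not published; this calibration puts the genetic-gain scenarios
in the reported 0.47–2.38% herd-reduction range).

`gen_metabolic_trials` and `gen_forage_trials` draw predictors at the
trial means/SDs and generate responses as model + Gaussian noise at the
published residual SE, so stepwise refitting is a genuine
parameter-recovery exercise. `gen_climate` is a seasonal
continental-Mediterranean template with noise.

What the generators do **not** emulate: between-farm correlation
structure (not published), within-year herd turnover, real feed-market
composition, or spatial climate variation. Passing tests therefore show
that the accounting and the regression machinery are correct under the
stated distributions, not that the model is validated against new field
data.

## Numerical choices

- Stepwise ties on R² break toward fewer predictors, then lexical order;
  the procedure is deterministic for a given data frame.
- Perfectly collinear candidates are skipped (rank check) and reported as
  infinite VIF by the diagnostics rather than crashing the fit.
- Degenerate inputs raise informative errors: zero area for stocking
  density or per-ha balances, zero intake for efficiencies, constant
  observed vectors for EF/r², meat-only farms for allocation.
- The Nash–Sutcliffe efficiency is implemented unbounded below (its
  textbook definition), although it is sometimes described as bounded at
  −1.
- `genetic_value_reduction` floors to whole animals with a 1e-9 epsilon
  to absorb floating-point noise at exact-integer boundaries.

## Problem sizes

The test suite refits each regression sub-model over 50 seeded
replicates at its published sample size (313–510 records for excreta, 59
and 35 for forages, 19–61 for demography) and checks per-coefficient
2-standard-error recovery in ≥ 90% of replicates. The acceptance script
uses 50 replicates × 313 records for the urine-slope recovery. Synthetic
farm population checks use 300 draws. These sizes give stable statistics
while keeping the whole suite in a few seconds.

## Known limitations

- Table-level outputs are only as good as the fixture feed table and the
  emission-factor defaults; for a real farm study every CSV should be
  reviewed.
- Nutritional requirements (net energy, metabolizable protein, Ca/P)
  are simple per-class coefficients, not full requirement systems; DMI is
  taken from the feed supply, not predicted.
- Crop water requirements (ETc) are inputs, not computed; the leaching
  rule is a one-parameter stand-in for a soil-water model.
- The scenario engine reports what the model yields; published
  scenario tables for the original 36-farm survey are not reproducible
  because the underlying farm records are not public, and no calibration
  to them is attempted.
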