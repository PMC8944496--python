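# flockcarbon

Whole-farm greenhouse-gas and multi-footprint simulation for dairy sheep
and goat farms, written for agro-environmental modellers, farm advisers
and researchers who need farm-gate carbon, nitrogen, water, energy and
land-use accounting for small-ruminant dairy systems (autochthonous
Manchega-type sheep flocks, intensive foreign sheep breeds, and dairy
goats) without access to process-level measurements.

## What it computes

The model is empirical: a farm-year (land, herd, purchases, milk, grazing
schedule, monthly climate) is driven through regression sub-models and
emission-factor accounting.

**Empirical sub-models.** Herd flows are linear in the present-female
census PF (e.g. offspring born = −112.1 + 1.91 PF). Excreta per head and
day come from diet composition, e.g. fecal N (g/d) = 1.30 + 0.24 ·
N-intake and urine (mL/d) = −654.1 + 71.3 · N-intake. Winter-cereal forage
yield is linear in plant height, days to ear emergence and basal N. Live
weight follows a Gompertz curve *w(t) = β₁ e^(−β₂ e^(−β₃ t))* (sheep:
β₁ = 68.59 kg). Milk per lactation is linear in the flock genetic index:
198.3 + 5.3 · GV. The `fit_stepwise` routine rebuilds models of this kind
by forward stepwise OLS with a 5% entry threshold, a VIF ≤ 10
collinearity guard and Durbin–Watson reporting.

**Gas flows.** Enteric methane is Tier-2 style:
Ym = 9.75 − 0.05 · OMD (% of gross energy) and
CH₄ (g/d) = DMI · (Ym/100) · (18.55/55.65). Manure CH₄ uses the volatile
solids chain; NH₃ (0.1 and 0.12 kg/kg excreted N housed/grazing) feeds
N₂O cascades; soil N₂O has direct (manure 0.3%, fertilizer 1%, residues
1% of applied N) and indirect (volatilization, leaching) pathways;
purchases carry embedded CO₂ (diesel 3.31 kg/L, N fertilizer 6.2 kg/kg,
concentrate 0.3 kg/kg, ...); crop residues and applied manure sequester
carbon (45% C in biomass, C = 13.4 · N for manure).

**Assessment.** CO₂e uses CH₄ × 28 and N₂O × 298. The partial carbon
footprint PCF sums all operational pathways; the total is
TCF = PCF + SY + iLUC − CS (soybean chain, indirect land-use change,
carbon sequestration). Milk and meat share emissions through the
allocation factor AF = 1 − 5.7717 · R with R the meat/milk mass ratio.
Footprints are reported per hectare, per livestock unit, per present
female and per liter of fat (6.5%)- and protein (5.8%)-corrected milk
(FPCM), alongside acidification (SO₂e), eutrophication (NO₃e), water
(green/blue/grey), energy (direct/indirect), nitrogen (total/reactive)
footprints, land use and farm-gate N and P balances.

**Scenarios.** A catalogue of mitigation scenarios (genetic gain,
herd-inventory cuts, soybean→peas substitution, fibrous by-product
concentrates, milk replacer, silage handling, triticale grazing, milking
energy, +2 °C warming) transforms a baseline farm and reports the percent
change per functional unit.

## Worked example

```python
from flockcarbon import gen_farm, simulate

farm = gen_farm(seed=11, breed_group="Manchega")   # synthetic survey farm
result = simulate(farm)
print(result.report.per_fu)
```

Running `python examples/01_simulate_farm.py` prints (abridged):

```
Farm: Manchega, 1631 present females, 792 ha (39 arable)
Livestock units: 413.1  (stocking 0.52 LU/ha)
Diet: 1385 g DM/head/day, OMD 0.72, Ym 6.13%
...
Partial carbon footprint (PCF): 1,053,532 kg CO2e
Total carbon footprint (TCF = PCF + SY + iLUC - CS): 1,547,662 kg CO2e
Milk/meat allocation: R = 0.115, AF = 0.333
Per functional unit:
  kg CO2e per ha                 1954.84
  kg CO2e per LU                 3746.06
  kg CO2e per present_female      948.91
  kg CO2e per L_FPCM                1.37
N balance: 33.9 kg N/ha surplus, efficiency 29.1%
```

The per-liter value is the milk share (AF) of the total footprint divided
by the FPCM liters; literature values for small-ruminant dairy span
roughly 2–6 kg CO₂e/L FPCM, and the synthetic baseline farms land at the
low end of that range because their allocation ratio is meat-heavy.
`examples/02_empirical_models.py` evaluates each sub-model on reference
inputs (fecal N at the trial-mean intake of 20.9 g/d is 6.3 g/d),
`examples/03_scenarios.py` prints the scenario comparison table, and
`examples/04_model_validation.py` refits the urine-volume model from
synthetic trials and scores it with r², Willmott's d, RMSE, MBE and
Nash–Sutcliffe EF.

## Layout

- `src/flockcarbon/farm.py` — farm-year domain types, livestock units
- `src/flockcarbon/empirical.py` — regression sub-models, Gompertz, stepwise fitting
- `src/flockcarbon/nutrition.py` — rations, potential production, NUE/PUE
- `src/flockcarbon/manure.py` — manure pools, farm-gate and soil nutrient balances
- `src/flockcarbon/emissions.py` — CH₄/NH₃/N₂O/CO₂ pathways, sequestration
- `src/flockcarbon/assessment.py` — FPCM, allocation, footprints, land use
- `src/flockcarbon/scenarios.py` — mitigation-scenario engine
- `src/flockcarbon/validation.py` — model-evaluation indices, VIF/DW
- `src/flockcarbon/synth.py` — seeded synthetic farms, trials, climate
- `src/flockcarbon/simulate.py` — the whole-farm pipeline
- `src/flockcarbon/cli.py` — `flockcarbon simulate|scenarios|synth|validate|factors`

See `docs/methods.md` for model assumptions, parameter defaults and
limitations.
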