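"""Evaluate the empirical sub-models on reference inputs.

Each sub-model is a published regression: herd flows from the breeding
census, excreta from diet composition, winter-cereal forage yield from
agronomic predictors, live weight from a Gompertz curve, and milk per
lactation from the flock genetic index.
"""

from flockcarbon import (
    demography, excreta_predict, forage_yield, gdd, gompertz_weight,
    milk_from_genetic_value,
)
from flockcarbon.empirical import GOMPERTZ_GOAT, GOMPERTZ_SHEEP

print("Herd flows for a 1267-ewe census (head/year):")
d = demography(1267)
print(f"  replacements reared {d.replacement_females:7.0f}")
print(f"  offspring born      {d.born_offspring:7.0f}")
print(f"  offspring culled    {d.culled_offspring:7.0f}")
print(f"  adult losses        {d.adult_losses:7.0f}")
print(f"  offspring deaths    {d.offspring_deaths:7.0f}")

print("\nExcreta at the metabolic-trial mean diet "
      "(OMD 0.633, 791.5 g DM, 20.9 g N/day):")
ex = excreta_predict(omd=0.633, dmi_g=791.5, gp_g=143.8, ndf_g=386.7,
                     n_intake_g=20.9)
print(f"  feces   {ex['feces_g_dm']:7.1f} g DM/day")
print(f"  urine   {ex['urine_ml']:7.0f} mL/day")
print(f"  fecal N {ex['n_feces_g']:7.1f} g/day   urinary N "
      f"{ex['n_urine_g']:.1f} g/day")

print("\nForage yield (kg DM/ha):")
print(f"  triticale (82.4 cm, 154 days to ear, 23.8 kg N): "
      f"{forage_yield('triticale', 82.4, 154.2, 23.8):,.0f}")
print(f"  oats (70.5 cm): {forage_yield('oats', 70.5):,.0f}")

print("\nGompertz live weight (kg):")
for label, p in [("sheep", GOMPERTZ_SHEEP), ("goat", GOMPERTZ_GOAT)]:
    print(f"  {label}: birth {gompertz_weight(p, 0):5.1f}, "
          f"35 d {gompertz_weight(p, 35):5.1f}, "
          f"240 d {gompertz_weight(p, 240):5.1f}, "
          f"mature {p.beta1:5.1f}")

print("\nHeat units for a 20/10 degree day (base 4 C): "
      f"{gdd(20, 10):.0f} degree-days")
print("Milk per lactation at genetic index 0 / 10: "
      f"{milk_from_genetic_value(0):.1f} / {milk_from_genetic_value(10):.1f} L")
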