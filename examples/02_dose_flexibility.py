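"""Inspect the dose evidence behind a dose-flexibility score.

For the paracetamol oral liquid (120 mg/5 mL and 125 mg/5 mL) the engine
computes, at each evaluation age, the required 10-15 mg/kg dose window from
the median weight-for-age and the smallest syringe-measurable volume that
delivers a conforming dose.  Volumes above 10 mL are flagged: that is what
caps acceptability for older children at yellow.
"""

from pqtpp import assess_dose, default_growth_reference, load_fixture
from pqtpp.scoring import score_dose_flexibility

growth = default_growth_reference()
liquid = load_fixture("paracetamol_oral_liquid")
assessments = assess_dose(liquid, growth=growth)

print("age (mo)  weight (kg)  required dose (mg)  chosen volume (mL)  >10 mL")
for a in assessments:
    weight = growth.median_weight(a.age_months)
    print(f"{a.age_months:>7}  {weight:>10.1f}  "
          f"{a.required_dose_low_mg:>7.0f}-{a.required_dose_high_mg:<9.0f} "
          f"{a.volume_ml:>17.1f}  {'yes' if a.high_volume_flag else 'no'}")

score = score_dose_flexibility(assessments)
print(f"\nDose-flexibility score: {score.score} ({score.colour}) - {score.rationale}")
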