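# Clofazimine soft-gel capsules, 50 mg and 100 mg, antileprosy multidrug
# therapy.  Children 10-14 years: 150 mg once a month plus 50 mg on
# alternate days; children below 10 years (or below 40 kg): 100 mg once a
# month plus 50 mg twice weekly.  Soft-gel capsules cannot be opened and
# dispersed because the drug is extremely hydrophobic; the capsules are
# round, about 7 mm.  Supplied in blister packs inside humidity-resistant
# containers; long shelf life but storage below 25 degC and moisture
# protection required.  No stringent regulatory authority has approved the
# capsules for leprosy or TB.  Encoded from public EMLc listings and
# product-label narratives.
medicine_name: clofazimine
product_label: Clofazimine capsules (50 mg, 100 mg)
indication: leprosy (multidrug therapy)
chronic_use: true
dosage_form:
  category: capsule_softgel
  largest_dimension_mm: 7
strengths:
  - amount_mg: 50
  - amount_mg: 100
posology:
  - age_window: {min_months: 120, max_months: 144}
    dose_mode: fixed_mg
    dose_low: 150
    dose_high: 150
    frequency_per_day: 1/30
  - age_window: {min_months: 120, max_months: 144}
    dose_mode: fixed_mg
    dose_low: 50
    dose_high: 50
    frequency_per_day: 1/2
  - age_window: {min_months: 0, max_months: 119}
    weight_window_kg: [0, 40]
    dose_mode: fixed_mg
    dose_low: 100
    dose_high: 100
    frequency_per_day: 1/30
  - age_window: {min_months: 0, max_months: 119}
    weight_window_kg: [0, 40]
    dose_mode: fixed_mg
    dose_low: 50
    dose_high: 50
    frequency_per_day: 2/7
excipients:
  - {name: propylene glycol, function: cosolvent}
  - {name: methyl parahydroxybenzoate, function: preservative}
  - {name: gelatin, function: other}
  - {name: beeswax, function: other}
stability:
  shelf_life_months: 60
  storage: below_25C
  moisture_protection_required: true
packaging:
  pack_type: blister in humidity-resistant container
  bulk_class: light_low_bulk
  complexity: simple
regulatory:
  - authority: USFDA
    is_SRA: true
    approved: false
    approval_anticipated: false
administration:
  manipulation: none
  setting: both
assertions:
  notes: encoded from public EMLc listings and product-label narratives;
    soft-gel capsules cannot be opened and dispersed in water
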