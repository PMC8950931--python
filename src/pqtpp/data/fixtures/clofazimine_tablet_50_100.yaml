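# Clofazimine tablets, 50 mg and 100 mg.  Better stability profile than the
# soft-gel capsules (not moisture sensitive) but not dispersible and, like
# the capsules, not approved by any stringent regulatory authority for
# leprosy or TB.  Tablet excipient composition is not publicly detailed.
# Encoded from public EMLc listings and product-label narratives.
medicine_name: clofazimine
product_label: Clofazimine tablets (50 mg, 100 mg)
indication: leprosy (multidrug therapy)
chronic_use: true
dosage_form:
  category: conventional_tablet
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
stability:
  shelf_life_months: 36
  storage: room_temperature
packaging:
  pack_type: blister
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
  excipient_profile_summary: unknown
  notes: encoded from public EMLc listings and product-label narratives;
    tablets are not dispersible
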