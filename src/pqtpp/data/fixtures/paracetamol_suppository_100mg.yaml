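# Paracetamol suppository, single 100 mg strength, licensed from about
# 3 months of age.  Encoded from public EMLc listings and product-label
# narratives.
medicine_name: paracetamol
product_label: Paracetamol suppository
indication: mild-to-moderate pain and fever
dosage_form:
  category: suppository
strengths:
  - amount_mg: 100
posology:
  - age_window: {min_months: 3, max_months: 144}
    dose_mode: per_kg_mg
    dose_low: 10
    dose_high: 15
    frequency_per_day: 4
    max_daily_mg_per_kg: 60
excipients:
  - {name: hard fat, function: other}
stability:
  shelf_life_months: 36
  storage: room_temperature
packaging:
  pack_type: strip
  bulk_class: light_low_bulk
  complexity: simple
regulatory:
  - authority: EMA
    is_SRA: true
    approved: true
    approved_age_range: {min_months: 3, max_months: 144}
administration:
  manipulation: none
  insertion_or_injection_burden: moderate
  setting: both
assertions:
  notes: encoded from public EMLc listings and product-label narratives;
    cultural barriers to rectal administration may apply
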