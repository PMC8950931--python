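# Paracetamol conventional tablets, 100-500 mg (EMLc listing "Tablet; 100 mg
# to 500 mg"; the exact strength set is not published, so 100/300/500 mg is
# used and documented).  Encoded from public EMLc listings and product-label
# narratives.
medicine_name: paracetamol
product_label: Paracetamol tablet
indication: mild-to-moderate pain and fever
dosage_form:
  category: conventional_tablet
strengths:
  - amount_mg: 100
  - amount_mg: 300
  - amount_mg: 500
posology:
  - age_window: {min_months: 0, max_months: 144}
    dose_mode: per_kg_mg
    dose_low: 10
    dose_high: 15
    frequency_per_day: 4
    max_daily_mg_per_kg: 60
excipients:
  - {name: maize starch, function: filler_binder}
  - {name: povidone, function: filler_binder}
  - {name: stearic acid, function: other}
stability:
  shelf_life_months: 36
  storage: room_temperature
packaging:
  pack_type: blister
  bulk_class: light_low_bulk
  complexity: simple
regulatory:
  - authority: EMA
    is_SRA: true
    approved: true
    approved_age_range: {min_months: 0, max_months: 144}
administration:
  manipulation: none
  setting: both
assertions:
  notes: encoded from public EMLc listings and product-label narratives
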