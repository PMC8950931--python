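# Paracetamol oral liquid, 120 mg/5 mL (24 mg/mL) and 125 mg/5 mL (25 mg/mL).
# Liquids in this class generally contain preservatives, sweeteners and
# flavouring; some variants contain sucrose and/or colour - the excipient
# list below encodes representative members of those categories.  Encoded
# from public EMLc listings and product-label narratives.
medicine_name: paracetamol
product_label: Paracetamol oral liquid
indication: mild-to-moderate pain and fever
dosage_form:
  category: oral_liquid
strengths:
  - concentration_mg_per_ml: 24    # 120 mg/5 mL
  - concentration_mg_per_ml: 25    # 125 mg/5 mL
posology:
  - age_window: {min_months: 0, max_months: 144}
    dose_mode: per_kg_mg
    dose_low: 10
    dose_high: 15
    frequency_per_day: 4
    max_daily_mg_per_kg: 60
excipients:
  - {name: sodium benzoate, function: preservative}
  - {name: sorbitol, function: sweetener_polyol}
  - {name: sucrose, function: sugar}
  - {name: sunset yellow, function: colourant}
  - {name: strawberry flavour, function: flavour}
stability:
  shelf_life_months: 36
  storage: room_temperature
packaging:
  pack_type: bottle
  bulk_class: bulky_heavy
  complexity: simple
regulatory:
  - authority: MHRA
    is_SRA: true
    approved: true
    approved_age_range: {min_months: 0, max_months: 144}
administration:
  manipulation: dose_measurement
  device_required: oral syringe or measuring spoon
  device_readily_available: true
  setting: both
assertions:
  notes: encoded from public EMLc listings and product-label narratives
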