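# Formulation record schema

Input records are YAML (1.2 subset) or JSON documents validated against
the `FormulationProduct` model. The machine-readable JSON Schema is
generated from the model:

```sh
python -c "import json, pqtpp; print(json.dumps(pqtpp.formulation_json_schema(), indent=2))"
```

No canonical machine format exists for the label dossiers this schema
encodes; the layout here is this package's own invention, designed to hold
exactly the fields the scoring rubric consumes. Unknown fields are
rejected with path-qualified messages; all ages are integer months within
0–144.

## Top level

| field | type | notes |
|-------|------|-------|
| `medicine_name` | str | required |
| `product_label` | str | display name for report columns |
| `indication` | str | free text |
| `condition_min_age_months` | int, default 0 | youngest age the indication is relevant/diagnosable |
| `chronic_use` | bool, default false | enables the frequent-dosing acceptability penalty |
| `indicated_age_range` | AgeRange | overrides licence/posology-derived population coverage |
| `dosage_form` | `{category, largest_dimension_mm?}` | category from the enumeration below |
| `strengths` | list, ≥ 1 | each exactly one of `amount_mg` (solids) / `concentration_mg_per_ml` (liquids) |
| `posology` | list, ≥ 1 | see below |
| `excipients` | list | `{name, function, quantity_mg_per_unit?, concentration_class?}` |
| `stability` | section | `shelf_life_months?`, `storage?`, `constituted_requires_refrigeration`, `moisture_protection_required` |
| `packaging` | section | `pack_type?`, `bulk_class?` (`light_low_bulk`/`bulky_heavy`), `complexity?` (`simple`/`complex`) |
| `regulatory` | list | see below |
| `administration` | section | `manipulation?`, `device_required?`, `device_readily_available?`, `insertion_or_injection_burden?`, `setting` |
| `assertions` | section | narrative overrides; see below |

## Enumerations

* `dosage_form.category`: `conventional_tablet`, `dispersible_tablet`,
  `orodispersible_tablet`, `scored_tablet`, `capsule_hard`,
  `capsule_softgel`, `oral_liquid`, `powder_for_oral_liquid`,
  `granules_minitablets`, `suppository`, `injection`,
  `topical_semisolid`, `unknown`
* `excipients[].function`: `preservative`, `sweetener_polyol`, `sugar`,
  `colourant`, `flavour`, `cosolvent`, `surfactant`, `filler_binder`,
  `other`; `concentration_class`: `trace_in_flavour`, `functional`
* `stability.storage`: `room_temperature` (20–25 °C), `below_25C`,
  `refrigerated_2_8C`, `freezer`
* `administration.manipulation`: `none`, `dose_measurement`,
  `food_mixing`, `reconstitution_fixed_volume`, `multiple_dilution`;
  `setting`: `domiciliary`, `healthcare_facility`, `both`

## Posology rules

```yaml
posology:
  - age_window: {min_months: 0, max_months: 119}
    weight_window_kg: [0, 40]        # optional extra applicability filter
    dose_mode: per_kg_mg             # or fixed_mg
    dose_low: 10                     # mg/kg (per_kg_mg) or mg (fixed_mg)
    dose_high: 15
    frequency_per_day: 2/7           # exact rational; 4, 1/2, 1/30 ...
    max_daily_mg_per_kg: 60          # optional daily cap
```

Invariants: `dose_low ≤ dose_high`, `frequency_per_day > 0`, age windows
ordered and within 0–144. A regimen with several components (e.g. a
monthly dose plus an alternate-day dose) is written as several rules with
identical windows; an age is dosable only if every applicable component is
achievable.

## Regulatory records

```yaml
regulatory:
  - authority: EMA
    is_SRA: true                     # stringent regulatory authority
    maturity_level: 3                # 1-4, for non-SRA authorities
    approved: true
    approval_anticipated: false
    approved_age_range: {min_months: 3, max_months: 144}
    supports_tablet_splitting: false
    supports_dispersion_administration: false
```

## Assertions

Narrative overrides for facts the label states but structured fields
cannot carry; every score they influence is marked "assertion-sourced":

```yaml
assertions:
  palatability: concerns             # acceptable | concerns | strongly_aversive
  excipient_profile_summary: unknown # acceptable | some_concern | several_concerns | unknown
  registration_unknown: false        # true -> registration scores grey
  notes: free text, copied into the profile comments
```
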