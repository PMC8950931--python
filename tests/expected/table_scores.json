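{
  "paracetamol_tablet": {
    "target_population": 2,
    "dose_flexibility": 2,
    "acceptability_0_5": 1,
    "acceptability_6_12": 3,
    "excipient_safety": 3,
    "administration": 3,
    "stability_storage_packaging": 3,
    "registration_status": 3
  },
  "paracetamol_oral_liquid": {
    "target_population": 3,
    "dose_flexibility": 3,
    "acceptability_0_5": 3,
    "acceptability_6_12": 2,
    "excipient_safety": 1,
    "administration": 2,
    "stability_storage_packaging": 2,
    "registration_status": 3
  },
  "paracetamol_suppository_100mg": {
    "target_population": 3,
    "dose_flexibility": 2,
    "acceptability_0_5": 3,
    "acceptability_6_12": 2,
    "excipient_safety": 3,
    "administration": 2,
    "stability_storage_packaging": 3,
    "registration_status": 3
  },
  "clofazimine_capsule_50_100": {
    "target_population": 2,
    "dose_flexibility": 2,
    "acceptability_0_5": 1,
    "acceptability_6_12": 3,
    "excipient_safety": 2,
    "administration": 3,
    "stability_storage_packaging": 2,
    "registration_status": 1
  },
  "clofazimine_tablet_50_100": {
    "registration_status": 1
  }
}
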