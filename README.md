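# pqtpp — paediatric age-appropriateness scoring of drug formulations

Most essential medicines exist in dosage forms designed for adults. Whether
a given marketed formulation is actually usable in children — from neonates
to 12-year-olds, including in low- and middle-income settings with hot,
humid climates and fragile supply chains — is a multi-dimensional question:
can the required mg/kg doses be delivered with the marketed strengths, will
a four-year-old swallow it, are the excipients safe for neonates, does it
survive without a cold chain?

`pqtpp` implements the paediatric Quality Target Product Profile (pQTPP)
rubric as a deterministic, testable assessment engine. A structured
formulation record (YAML/JSON, encoding what the product label/SmPC states)
is scored on **eight attributes**, each on a traffic-light scale:

| score | colour | meaning |
|-------|--------|---------|
| 3 | green | meets the target |
| 2 | yellow | partially meets the target |
| 1 | red | does not meet the target |
| 0 | grey | insufficient information |

The attributes, in fixed heat-map order: target population (age coverage of
the 0–144-month window), dose and dose flexibility, patient acceptability
split into 0–5 and 6–12 year bands, excipient safety, administration
considerations, stability/storage/packaging, and registration status.
There is deliberately no weighted composite score: the per-attribute heat
map is the result.

Behind the scorers sit two evidence engines:

* a **dose engine** that converts mg/kg posology into required dose windows
  via a packaged median weight-for-age table (`w(a)`, linearly interpolated),
  enumerates achievable doses (unit combinations of the marketed strengths,
  half-units under a splitting licence, or syringe-grid volumes for
  liquids), and flags volumes `< 0.1 mL` (unmeasurable) and `> 10 mL`
  (burdensome for a single oral dose);
* an **excipient engine** that matches listed excipients against an
  editable concern registry (benzoates with a neonatal restriction, ethanol,
  propylene glycol, parabens, polyols, sucrose, azo colourants, saccharin)
  and, when quantities are known, compares the worst-case daily intake
  `quantity × doses/day ÷ w(a)` against acceptable daily intakes (ADIs).

Bundled fixture records encode the published worked evaluations —
paracetamol tablet / oral liquid / 100 mg suppository and clofazimine
soft-gel capsules — and the engine reproduces their printed score vectors
cell for cell.

## Worked example

```sh
python examples/01_score_a_formulation.py
```

prints, for the clofazimine 50/100 mg soft-gel capsules:

```
Clofazimine capsules (50 mg, 100 mg)

  Target population                  2 (yellow) suitable for most of the target population (coverage 50% via posology windows)
  Dose and dose flexibility          2 (yellow) limited dose flexibility (16/16 evaluated ages dosable)
  Patient acceptability (0-5 years)  1 (red   ) unacceptable for this age range (dosage form unsuitable)
  Patient acceptability (6-12 years) 3 (green ) acceptable for this age range
  Excipient safety                   2 (yellow) 2 excipient(s) of potential concern (propylene glycol, methyl parahydroxybenzoate)
  Administration considerations      3 (green ) no manipulation or measurement required
  Stability, storage and packaging   2 (yellow) partially meets storage/packaging targets
  Registration status                1 (red   ) not approved by any regulatory authority and no approvals anticipated

Score vector: (2, 2, 1, 3, 2, 3, 2, 1)
```

Reading the vector: capsules only serve children old enough to swallow them
(half the 0–12-year window, hence 2), the 50 mg floor forces an
alternate-day/twice-weekly regimen rather than fine dose titration (2),
under-sixes cannot take them at all (1) while the small 7 mm capsule is
fine from six up (3), two excipients of potential concern (2), no
manipulation needed (3), moisture-sensitive soft-gels needing below-25 °C
storage (2), and no stringent-regulatory-authority approval (1) — together
flagging the formulation gap for young children.

The other example scripts show the dose-evidence table behind a flexibility
score, the excipient screen, multi-product CSV/HTML heat maps, and batch
assessment of a synthetic cohort. The same functionality is available from
the shell:

```sh
pqtpp validate myrecord.yaml
pqtpp assess myrecord.yaml --report html --out report.html
pqtpp rules
pqtpp fixtures --write-dir fixtures/
```

## Layout

```
src/pqtpp/        model, io, growth, dose, excipients, scoring, report, cli
src/pqtpp/data/   growth reference, excipient registry, acceptability base
                  table, fixture records (all plain text, all overridable)
examples/         one narrative script per capability
docs/             methods note and input-schema reference
tests/            unit, property (hypothesis) and acceptance suites
```
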