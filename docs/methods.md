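# Methods

## The assessment model

`pqtpp` treats paediatric age-appropriateness as a rubric evaluation: a
formulation record is compared attribute by attribute against targets, and
each comparison yields a score in {3, 2, 1, 0} with a fixed colour map
(3 green / 2 yellow / 1 red / 0 grey). Grey always means *insufficient
information*, never risk. Attributes are independent; no composite or
weighted total is computed, because any weighting would be indication- and
context-specific. Multi-criterion attributes resolve by *most severe
triggered criterion*: the engine collects every criterion an input
triggers and the worst severity wins.

The assessment is fully deterministic: a fixed record plus a fixed
configuration always produces the identical profile (and byte-identical
JSON/CSV reports).

### Target population

The target window is `[condition_min_age_months, 144]` months. The window
a product actually covers comes from, in order of preference: an explicit
indicated age range, the union of approved licence age ranges, or the
union of posology windows (closed month intervals; abutting windows such
as 0–119 and 120–144 merge). Forms that must be swallowed whole
(conventional/scored tablets, hard and soft-gel capsules) have their
covered window floored at the tablet-swallowing age. Coverage fraction
≥ 0.95 scores 3, ≥ 0.5 scores 2, below that 1; an unknown dosage form
scores 0 because swallowability cannot be judged. The 0.95 "full
coverage" threshold is deliberate: a licence floor of two or three months
is a neonatal technicality that practitioners still read as "suitable for
the whole population", and a strict 1.0 rule would misgrade rectal and
liquid paracetamol products whose licences start at a few months of age.

### Dose engine

Required doses: for a mg/kg rule, the per-dose window is
`[dose_low·w(a), dose_high·w(a)]` with `w(a)` the median weight-for-age;
a stated daily mg/kg cap limits the per-dose high once the dosing
frequency is applied. Fixed-dose rules pass through unchanged.
Frequencies are exact rationals (monthly = 1/30, alternate days = 1/2,
twice weekly = 2/7) so sub-daily regimens share the doses-per-day axis
without rounding.

Achievable doses: solids are enumerated as all unit combinations across
the marketed strengths up to a per-dose unit budget (default 4 units;
3 for suppositories), plus half-units when any licence supports tablet
splitting. Liquids can deliver any volume on the measuring-device grid
(default graduation 0.1 mL) up to a maximum administrable volume
(default 25 mL). An age is *dosable* when some achievable dose lies inside
the required window for every rule applicable at that age.

The suppository unit budget of 3 departs from an initial inclination to
allow only 2: published practice for the single-strength 100 mg
suppository explicitly contemplates giving several suppositories to older
children, and a budget of 2 would grade that product as mostly
un-dosable, which contradicts its published evaluation. The value is
configuration, not code.

Two liquid thresholds are hard usability rules: a dose measurable only
below one 0.1 mL graduation is unacceptable (it cannot be drawn up
accurately), and a dose above 10 mL is flagged as burdensome — the flag
feeds the 6–12-year acceptability modifier, not the dose score itself.

Dose-flexibility scoring over the age grid: 3 when every evaluable age is
dosable with fine increments (a liquid on the device grid, or at least
three distinct achievable doses inside the required window); 2 when at
least half the ages are dosable (coarse increments tolerated); 1 below
half; 0 when no rule applies anywhere. Ages outside every posology window
are excluded from the denominator — they belong to populations the
product does not claim.

### Acceptability

A shipped base lookup (dosage form × age band) encodes form
suitability: swallow-whole forms score 1 for 0–5 years and 3 for
6–12 years; liquids, dispersible/orodispersible forms, granules and
suppositories start at 3 in both bands; injections at 2. Modifiers then
apply: strongly aversive palatability forces 1; palatability concerns,
frequent dosing (> 3/day) on a *chronic* regimen, per-dose volumes above
10 mL (6–12, liquids), needing ≥ 2 suppositories per dose (6–12), or a
solid unit larger than the swallowable dimension (default 10 mm, 6–12)
each cap the score at 2. Frequent dosing is not penalised for short-term
treatments, which is why a 4×/day antipyretic liquid stays green; the
`chronic_use` flag on the record carries that distinction.

### Excipient safety

Findings come from the registry match (see `data/excipient_registry.csv`);
0 findings → 3; 1–2 → 2; ≥ 3 ("several"), any exceeded ADI, or any
known-severity concern whose population restriction overlaps the target
population → 1; a record with no excipient information → 0, unless a
label-level summary assertion supplies a judgement (marked
assertion-sourced in the rationale). The registry is data, not code: it
is a documented superset of the excipient classes named in the worked
evaluations, and both route filters (e.g. polyols only matter orally) and
neonatal age restrictions are expressed per row. The benzoate pattern
deliberately excludes parahydroxybenzoates — parabens are a separate row
with their own severity. When no quantities are public, findings are
presence-based and say so; ADI comparisons use the worst case (highest
intake per kg) over the evaluated age grid.

### Administration, stability, registration

Administration maps manipulation class × setting (no manipulation → 3;
dose measurement or food mixing → 2, measurement by trained staff → 3;
fixed-volume reconstitution → 2 in trained hands, 1 domiciliary; multiple
dilutions or an unavailable required device → 1), then caps for
insertion/injection burden (moderate → 2, high → 1) and for sub-0.1 mL
doses (→ 2).

Stability/storage/packaging runs the severity ladder: cold-chain storage
or shelf life < 18 months are red; constituted-product refrigeration,
moisture-protection requirements, shelf life < 24 months, and
bulky/complex packaging are yellow; otherwise green (storage "below
25 °C" is treated as room-temperature-compatible). Packaging bulk is
nominally a red-column criterion, but a product can be otherwise fully
conforming and still come in a heavy bottle; the published evaluations
grade exactly that case yellow, so bulk/complexity is implemented at
yellow severity. Both stability and administration are verified against
independent brute-force oracles over the exhaustively enumerated input
space.

Registration: any approved stringent-regulatory-authority (SRA) record →
3; approval by a maturity-level ≥ 3 authority, or an anticipated SRA
approval → 2; otherwise 1 — including an empty record list, since absence
of approvals is itself the red criterion. A record can opt out via an
explicit `registration_unknown` assertion (→ 0).

### Multi-licence overviews

When several licences of the same medicine/dosage form are assessed,
the overview score per attribute is the modal score with ties resolved
to the worse score; greys are excluded from the mode whenever any
informative score exists; the min–max range is kept in the rationale.

## Configuration

| key | default | meaning |
|-----|---------|---------|
| `device_resolution_ml` | 0.1 | oral-syringe graduation, mL |
| `max_volume_ml` | 25 | largest administrable liquid dose, mL |
| `max_units_per_dose` | 4 | solid units per dose |
| `max_units_suppository` | 3 | suppositories per dose |
| `age_grid_months` | 0,1,3,6,12,…,144 | evaluation ages |
| `several_excipients_min` | 3 | red band for excipient counts |
| `population_coverage_half` / `_full` | 0.5 / 0.95 | coverage thresholds |
| `tablet_swallow_age_months` | 72 | swallow-whole floor |
| `swallowable_max_mm` | 10 | largest swallowable solid unit, mm |
| `high_volume_threshold_ml` | 10 | burdensome liquid dose, mL |
| `frequent_doses_per_day` | 3 | chronic-dosing penalty threshold |

The age grid (yearly 0–12 years plus 1, 3 and 6 months) anchors
dose-flexibility judgements at the ages where paediatric dosing actually
changes, without false monthly precision; it is a declared convention,
as is the 50 % month-coverage reading of "most of the population".

The packaged growth reference is a sex-averaged approximation of public
WHO 50th-centile weight-for-age values at 19 knot ages from birth to
144 months, linearly interpolated between knots; it ships as CSV and can
be replaced via `growth_reference_path` (e.g. with sex-specific or
population-specific medians).

## Synthetic data

`generate_synthetic(seed, n)` emits schema-valid random records spanning
every dosage-form category, 0–3 concern excipients, shelf lives 6–60
months, all storage classes and 0–2 regulatory records. It emulates the
*structural* variety of label data — it does not emulate correlations in
real products (e.g. liquids co-occurring with preservatives), so property
tests built on it demonstrate schema validity, determinism, score-domain
closure and monotonicity, not epidemiology of real formulations. The
worked-example fixtures, not the generator, carry the fidelity claim: the
engine reproduces their published score vectors exactly, and that
reproduction is asserted in the acceptance suite.

Fixture records are encoded from public essential-medicines listings and
product-label narratives at the level of detail those sources state;
where a source reports a category rather than a brand-specific fact, the
fixture encodes a representative member (e.g. "sodium benzoate" for "a
preservative") and the file header says so. The tablet strength set
{100, 300, 500} mg instantiates a published "100 mg to 500 mg" range
whose exact membership is not stated.

## Numerical choices and degenerate inputs

Dose-window membership uses a 1e-9 absolute tolerance so grid arithmetic
(0.1 mL × 24 mg/mL) does not lose boundary doses to floating-point noise.
Achievable-dose enumeration deduplicates by dose, keeping the option with
the fewest units. A product whose posology applies at no grid age scores
0 for dose flexibility rather than erroring; `assemble_profile` never
aborts on missing information — every not-evaluable state propagates as a
grey cell.

## Known limitations

* No pharmacokinetics: arguments from long elimination half-lives (which
  can make coarse dosing clinically acceptable) are not modelled; they can
  only enter as record assertions.
* Acceptability rests on a form-level base table plus flags; it does not
  model taste, texture or cultural factors beyond the palatability and
  narrative assertions.
* The excipient registry is presence-oriented; without quantities the
  engine cannot distinguish a trace from a bulk cosolvent unless the
  record's `concentration_class` says so.
* The growth reference is a median: dose checks are for the typical child
  of each age, not for outlying weights.
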