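"""Traffic-light scoring of the eight paediatric-appropriateness attributes.

Each attribute is scored on a fixed rubric: 3 (green, meets target),
2 (yellow, partially meets target), 1 (red, does not meet target) and
0 (grey, insufficient information).  Multi-criterion attributes follow a
most-severe-triggered-criterion precedence, with one documented exception:
bulky or complex packaging on its own demotes stability to yellow rather
than red, because a product can be otherwise unproblematic and still come
in a heavy bottle.

There is deliberately no composite or weighted total: the heat map of
per-attribute scores *is* the result, and trading attributes off against
each other is left to human reviewers case by case.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .config import DEFAULT_CONFIG, ToolConfig
from .dose import DoseAssessment, assess_dose
from .excipients import ExcipientFinding, evaluate_excipients, default_registry
from .growth import GrowthReference, default_growth_reference
from .model import (
    MAX_AGE_MONTHS,
    SWALLOW_WHOLE_CATEGORIES,
    AdministrationProfile,
    AgeRange,
    Burden,
    DosageFormCategory,
    ExcipientSummary,
    FormulationProduct,
    Manipulation,
    PackagingProfile,
    PackComplexity,
    Palatability,
    QualitativeAssertions,
    RegulatoryRecord,
    Setting,
    StabilityProfile,
    StorageClass,
    BulkClass,
)

__all__ = [
    "Attribute",
    "ATTRIBUTE_ORDER",
    "ATTRIBUTE_LABELS",
    "SCORE_COLOURS",
    "AttributeScore",
    "PQTPPProfile",
    "score_target_population",
    "score_dose_flexibility",
    "score_acceptability",
    "score_excipient_safety",
    "score_administration",
    "score_stability",
    "score_registration",
    "assemble_profile",
    "aggregate_profiles",
]


class Attribute(str, Enum):
    target_population = "target_population"
    dose_flexibility = "dose_flexibility"
    acceptability_0_5 = "acceptability_0_5"
    acceptability_6_12 = "acceptability_6_12"
    excipient_safety = "excipient_safety"
    administration = "administration"
    stability_storage_packaging = "stability_storage_packaging"
    registration_status = "registration_status"


ATTRIBUTE_ORDER: tuple[Attribute, ...] = tuple(Attribute)

ATTRIBUTE_LABELS = {
    Attribute.target_population: "Target population",
    Attribute.dose_flexibility: "Dose and dose flexibility",
    Attribute.acceptability_0_5: "Patient acceptability (0-5 years)",
    Attribute.acceptability_6_12: "Patient acceptability (6-12 years)",
    Attribute.excipient_safety: "Excipient safety",
    Attribute.administration: "Administration considerations",
    Attribute.stability_storage_packaging: "Stability, storage and packaging",
    Attribute.registration_status: "Registration status",
}

#: bijective score <-> colour map of the traffic-light system
SCORE_COLOURS = {3: "green", 2: "yellow", 1: "red", 0: "grey"}

_BAND_WINDOWS = {"0_5": (0, 71), "6_12": (72, MAX_AGE_MONTHS)}


@dataclass(frozen=True)
class AttributeScore:
    attribute: Attribute
    score: int
    triggered_criteria: tuple[str, ...] = ()
    rationale: str = ""

    def __post_init__(self):
        if self.score not in SCORE_COLOURS:
            raise ValueError(f"score must be in {{0,1,2,3}}, got {self.score}")

    @property
    def colour(self) -> str:
        return SCORE_COLOURS[self.score]

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute.value,
            "score": self.score,
            "colour": self.colour,
            "triggered_criteria": list(self.triggered_criteria),
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class PQTPPProfile:
    """The eight-attribute score vector for one product (or an overview)."""

    product_label: str
    medicine_name: str
    scores: tuple[AttributeScore, ...]
    comments: str = ""

    def __post_init__(self):
        if tuple(s.attribute for s in self.scores) != ATTRIBUTE_ORDER:
            raise ValueError("profile must hold the eight attributes in fixed order")

    def vector(self) -> tuple[int, ...]:
        return tuple(s.score for s in self.scores)

    def score_for(self, attribute: Attribute) -> AttributeScore:
        return self.scores[ATTRIBUTE_ORDER.index(attribute)]

    def to_dict(self) -> dict:
        return {
            "product": self.product_label,
            "medicine": self.medicine_name,
            "scores": [s.to_dict() for s in self.scores],
            "comments": self.comments,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# attribute scorers


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    # age windows are closed month intervals, so [0,119] and [120,144] abut
    merged: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def score_target_population(
    product: FormulationProduct, config: Optional[ToolConfig] = None
) -> AttributeScore:
    """Fraction of the 0-12-year target window the product can actually serve.

    The covered window comes from an explicit indicated range, else from
    approved licence ranges, else from the posology windows.  Forms that must
    be swallowed whole cannot serve children below the tablet-swallowing age,
    so their covered window is floored accordingly.
    """
    config = config or DEFAULT_CONFIG
    attr = Attribute.target_population
    category = product.dosage_form.category
    if category is DosageFormCategory.unknown:
        return AttributeScore(attr, 0, ("target_population.form_unknown",),
                              "dosage form unknown; suitability cannot be judged")

    target_lo = product.condition_min_age_months
    target_span = MAX_AGE_MONTHS - target_lo
    if target_span <= 0:
        return AttributeScore(attr, 0, ("target_population.empty_target",),
                              "target window is empty")

    if product.indicated_age_range is not None:
        windows = [(product.indicated_age_range.min_months,
                    product.indicated_age_range.max_months)]
        source = "indicated age range"
    else:
        approved = [
            r.approved_age_range
            for r in product.regulatory
            if r.approved and r.approved_age_range is not None
        ]
        if approved:
            windows = [(a.min_months, a.max_months) for a in approved]
            source = "approved licence ranges"
        else:
            windows = [
                (r.age_window.min_months, r.age_window.max_months)
                for r in product.posology
            ]
            source = "posology windows"

    floor = (
        config.scoring.tablet_swallow_age_months
        if category in SWALLOW_WHOLE_CATEGORIES
        else target_lo
    )
    clipped = [
        (max(lo, target_lo, floor), min(hi, MAX_AGE_MONTHS))
        for lo, hi in windows
    ]
    covered = sum(hi - lo for lo, hi in _merge_intervals(
        [(lo, hi) for lo, hi in clipped if hi > lo]
    ))
    coverage = covered / target_span

    criteria = [f"target_population.coverage_from_{source.split()[0]}"]
    if category in SWALLOW_WHOLE_CATEGORIES:
        criteria.append("target_population.swallow_whole_floor")
    if coverage >= config.scoring.population_coverage_full:
        return AttributeScore(attr, 3, tuple(criteria),
                              f"suitable for the whole target population "
                              f"(coverage {coverage:.0%} via {source})")
    if coverage >= config.scoring.population_coverage_half:
        return AttributeScore(attr, 2, tuple(criteria),
                              f"suitable for most of the target population "
                              f"(coverage {coverage:.0%} via {source})")
    return AttributeScore(attr, 1, tuple(criteria),
                          f"not suitable for the majority of the target population "
                          f"(coverage {coverage:.0%} via {source})")


def _by_age(assessments: Sequence[DoseAssessment]) -> dict[int, list[DoseAssessment]]:
    grouped: dict[int, list[DoseAssessment]] = {}
    for a in assessments:
        grouped.setdefault(a.age_months, []).append(a)
    return grouped


def score_dose_flexibility(
    assessments: Sequence[DoseAssessment], config: Optional[ToolConfig] = None
) -> AttributeScore:
    """Dose flexibility from per-age achievability evidence.

    3: every age dosable with fine increments (liquid on a device grid, or at
    least three distinct achievable doses within the required window);
    2: most ages dosable (coarse increments tolerated); 1: most ages
    unreachable; 0: no assessable posology.
    """
    config = config or DEFAULT_CONFIG
    attr = Attribute.dose_flexibility
    if not assessments:
        raise ValueError("need at least one dose assessment")
    evaluable = {
        age: group
        for age, group in _by_age(assessments).items()
        if any(a.evaluable for a in group)
    }
    if not evaluable:
        return AttributeScore(attr, 0, ("dose.no_assessable_posology",),
                              "no assessable posology")
    dosable_ages = [
        age for age, group in evaluable.items()
        if all(a.dosable for a in group if a.evaluable)
    ]
    frac = len(dosable_ages) / len(evaluable)
    fine = frac == 1.0 and all(
        a.fine_grid or a.n_options_in_range >= 3
        for group in evaluable.values()
        for a in group
        if a.evaluable
    )
    detail = f"{len(dosable_ages)}/{len(evaluable)} evaluated ages dosable"
    if fine:
        return AttributeScore(attr, 3, ("dose.fine_increments",),
                              f"high dose flexibility ({detail})")
    if frac >= 0.5:
        return AttributeScore(attr, 2, ("dose.coarse_or_partial",),
                              f"limited dose flexibility ({detail})")
    return AttributeScore(attr, 1, ("dose.mostly_unreachable",),
                          f"poor dose flexibility ({detail})")


def load_acceptability_table(path: Union[str, Path, None] = None) -> dict:
    """Base acceptability score by dosage-form category and age band."""
    if path is None:
        source = resources.files("pqtpp.data").joinpath("acceptability_base.csv")
        with resources.as_file(source) as p:
            return load_acceptability_table(p)
    table: dict[DosageFormCategory, dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table[DosageFormCategory(row["category"])] = {
                "0_5": int(row["band_0_5"]),
                "6_12": int(row["band_6_12"]),
            }
    return table


def score_acceptability(
    product: FormulationProduct,
    band: str,
    assessments: Sequence[DoseAssessment] = (),
    config: Optional[ToolConfig] = None,
    table: Optional[dict] = None,
) -> AttributeScore:
    """Patient acceptability for one age band (``"0_5"`` or ``"6_12"``).

    Starts from a data-shipped base lookup (dosage form x band), then applies
    modifiers: strongly aversive palatability forces red; palatability
    concerns, frequent chronic dosing, high liquid volumes (6-12), multiple
    suppositories per dose (6-12) and oversized solid forms (6-12) each cap
    the score at yellow.
    """
    config = config or DEFAULT_CONFIG
    if band not in _BAND_WINDOWS:
        raise ValueError(f"band must be one of {sorted(_BAND_WINDOWS)}, got {band!r}")
    attr = Attribute.acceptability_0_5 if band == "0_5" else Attribute.acceptability_6_12
    category = product.dosage_form.category
    if category is DosageFormCategory.unknown:
        return AttributeScore(attr, 0, ("acceptability.form_unknown",),
                              "dosage form unknown")
    band_lo, band_hi = _BAND_WINDOWS[band]
    if product.condition_min_age_months > band_hi:
        return AttributeScore(attr, 0, ("acceptability.band_not_applicable",),
                              "target population does not include this age band")

    table = table or load_acceptability_table()
    base = table[category][band]
    criteria = [f"acceptability.base:{category.value}/{band}"]
    notes = []
    score = base

    palatability = product.assertions.palatability
    if palatability is Palatability.strongly_aversive:
        return AttributeScore(attr, 1,
                              tuple(criteria + ["acceptability.strongly_aversive"]),
                              "strongly aversive palatability (assertion-sourced)")
    if palatability is Palatability.concerns:
        score = min(score, 2)
        criteria.append("acceptability.palatability_concerns")
        notes.append("palatability concerns (assertion-sourced)")

    if product.chronic_use and any(
        float(r.frequency_per_day) > config.scoring.frequent_doses_per_day
        for r in product.posology
    ):
        score = min(score, 2)
        criteria.append("acceptability.frequent_chronic_dosing")
        notes.append("frequent dosing on a chronic regimen")

    in_band = [
        a for a in assessments
        if a.evaluable and band_lo <= a.age_months <= band_hi
    ]
    if band == "6_12":
        if any(a.high_volume_flag for a in in_band):
            score = min(score, 2)
            criteria.append("acceptability.high_volume")
            notes.append(
                f"doses above {config.scoring.high_volume_threshold_ml:g} mL "
                "for older children"
            )
        if category is DosageFormCategory.suppository and any(
            (a.units_per_dose or 0) >= 2 for a in in_band
        ):
            score = min(score, 2)
            criteria.append("acceptability.multiple_suppositories")
            notes.append("multiple suppositories needed per dose")
        size = product.dosage_form.largest_dimension_mm
        if (
            category in SWALLOW_WHOLE_CATEGORIES
            and size is not None
            and size > config.scoring.swallowable_max_mm
        ):
            score = min(score, 2)
            criteria.append("acceptability.large_unit_size")
            notes.append(f"unit size {size:g} mm above swallowable limit")

    rationale = "; ".join(notes) if notes else {
        3: "acceptable for this age range",
        2: "some acceptability concerns in this age range",
        1: "unacceptable for this age range (dosage form unsuitable)",
        0: "insufficient information",
    }[score]
    return AttributeScore(attr, score, tuple(criteria), rationale)


def score_excipient_safety(
    findings: Sequence[ExcipientFinding],
    product: Optional[FormulationProduct] = None,
    config: Optional[ToolConfig] = None,
) -> AttributeScore:
    """Excipient safety from registry findings (possibly presence-based).

    0 concerns -> green; 1-2 -> yellow; "several" (>= 3), an exceeded ADI or
    a known concern applying to the target population -> red.  A wholly
    unknown composition scores grey unless a label-level assertion summarises
    it.
    """
    config = config or DEFAULT_CONFIG
    attr = Attribute.excipient_safety
    if product is not None:
        summary = product.assertions.excipient_profile_summary
        if summary is not None and not product.excipients:
            mapping = {
                ExcipientSummary.acceptable: 3,
                ExcipientSummary.some_concern: 2,
                ExcipientSummary.several_concerns: 1,
                ExcipientSummary.unknown: 0,
            }
            return AttributeScore(attr, mapping[summary],
                                  ("excipients.assertion_summary",),
                                  f"label summary '{summary.value}' (assertion-sourced)")
        if not product.excipients:
            return AttributeScore(attr, 0, ("excipients.unknown_composition",),
                                  "excipient composition unknown")

    n = len(findings)
    names = ", ".join(f.excipient for f in findings)
    if any(f.concern_level == "adi_exceeded" for f in findings):
        return AttributeScore(attr, 1, ("excipients.adi_exceeded",),
                              f"estimated intake exceeds an ADI ({names})")
    if any(f.concern_level == "known" for f in findings):
        return AttributeScore(attr, 1, ("excipients.known_concern_in_population",),
                              f"known concern for the target population ({names})")
    if n >= config.scoring.several_excipients_min:
        return AttributeScore(attr, 1, ("excipients.several_concerns",),
                              f"several excipients of concern ({names})")
    if n >= 1:
        return AttributeScore(attr, 2, ("excipients.one_or_two_concerns",),
                              f"{n} excipient(s) of potential concern ({names})")
    return AttributeScore(attr, 3, ("excipients.acceptable_profile",),
                          "excipients have an acceptable safety profile")


def score_administration(
    profile: AdministrationProfile,
    assessments: Sequence[DoseAssessment] = (),
    config: Optional[ToolConfig] = None,
) -> AttributeScore:
    """Administration burden for the required dose.

    No manipulation -> green; dose measurement or food mixing (and fixed-
    volume reconstitution in trained hands) -> yellow; multiple dilutions,
    fixed-volume reconstitution by caregivers, or an unavailable device ->
    red.  Insertion/injection burden and sub-0.1 mL doses cap the score.
    """
    attr = Attribute.administration
    if profile.manipulation is None:
        return AttributeScore(attr, 0, ("administration.unknown",),
                              "administration requirements unknown")
    criteria = []
    notes = []
    manip = profile.manipulation
    setting = profile.setting
    if manip is Manipulation.none:
        score = 3
        criteria.append("administration.no_manipulation")
        notes.append("no manipulation or measurement required")
    elif manip is Manipulation.dose_measurement:
        if setting is Setting.healthcare_facility:
            score = 3
            criteria.append("administration.measurement_hcp")
            notes.append("dose measurement by trained staff")
        else:
            score = 2
            criteria.append("administration.measurement_required")
            notes.append("doses must be measured with a device")
    elif manip is Manipulation.food_mixing:
        score = 2
        criteria.append("administration.food_mixing")
        notes.append("requires mixing with food")
    elif manip is Manipulation.reconstitution_fixed_volume:
        if setting is Setting.healthcare_facility:
            score = 2
            criteria.append("administration.reconstitution_hcp")
            notes.append("fixed-volume reconstitution by trained staff")
        else:
            score = 1
            criteria.append("administration.reconstitution_domiciliary")
            notes.append("fixed-volume reconstitution by caregivers")
    else:  # multiple_dilution
        score = 1
        criteria.append("administration.multiple_dilution")
        notes.append("multiple dilutions required")

    if profile.device_required and profile.device_readily_available is False:
        score = 1
        criteria.append("administration.device_not_available")
        notes.append(f"required device not readily available ({profile.device_required})")

    burden = profile.insertion_or_injection_burden
    if burden is Burden.high:
        score = min(score, 1)
        criteria.append("administration.insertion_burden_high")
        notes.append("high insertion/injection burden")
    elif burden is Burden.moderate:
        score = min(score, 2)
        criteria.append("administration.insertion_burden_moderate")
        notes.append("some patients/caregivers may struggle with administration")

    if any(a.min_volume_flag for a in assessments):
        score = min(score, 2)
        criteria.append("administration.sub_measurable_volume")
        notes.append("some required doses fall below the 0.1 mL measurable volume")

    return AttributeScore(attr, score, tuple(criteria), "; ".join(notes))


def score_stability(
    stability: StabilityProfile,
    packaging: Optional[PackagingProfile] = None,
    config: Optional[ToolConfig] = None,
) -> AttributeScore:
    """Stability/storage/packaging on a severity ladder (most severe wins).

    Red: cold-chain storage or shelf life under 18 months.  Yellow:
    constituted product needs refrigeration, moisture protection required,
    shelf life under 2 years, or bulky/complex packaging.  Green otherwise
    (room-temperature storable, >= 2-year shelf life, light simple pack).
    """
    attr = Attribute.stability_storage_packaging
    packaging = packaging or PackagingProfile()
    if stability.shelf_life_months is None and stability.storage is None:
        return AttributeScore(attr, 0, ("stability.unknown",),
                              "no shelf-life or storage information")
    red, yellow = [], []
    if stability.storage in (StorageClass.refrigerated_2_8C, StorageClass.freezer):
        red.append("stability.cold_chain_storage")
    shelf = stability.shelf_life_months
    if shelf is not None:
        if shelf < 18:
            red.append("stability.shelf_under_18_months")
        elif shelf < 24:
            yellow.append("stability.shelf_under_24_months")
    if stability.constituted_requires_refrigeration:
        yellow.append("stability.constituted_needs_refrigeration")
    if stability.moisture_protection_required:
        yellow.append("stability.moisture_protection_required")
    if packaging.bulk_class is BulkClass.bulky_heavy or (
        packaging.complexity is PackComplexity.complex
    ):
        # demoted from the red column: bulk alone does not make a product
        # unusable when everything else meets the target
        yellow.append("stability.bulky_or_complex_packaging")

    if red:
        return AttributeScore(attr, 1, tuple(red + yellow),
                              "does not meet storage/shelf-life targets")
    if yellow:
        return AttributeScore(attr, 2, tuple(yellow),
                              "partially meets storage/packaging targets")
    return AttributeScore(attr, 3, ("stability.meets_targets",),
                          "room-temperature storable with adequate shelf life "
                          "and simple, light packaging")


def score_registration(
    records: Sequence[RegulatoryRecord],
    assertions: Optional[QualitativeAssertions] = None,
) -> AttributeScore:
    """Regulatory standing: SRA approval -> green; approval by a maturity
    level >= 3 authority or an anticipated SRA approval -> yellow; nothing
    approved or anticipated -> red."""
    attr = Attribute.registration_status
    if assertions is not None and assertions.registration_unknown:
        return AttributeScore(attr, 0, ("registration.unknown",),
                              "regulatory status unknown (assertion-sourced)")
    if any(r.approved and r.is_SRA for r in records):
        names = ", ".join(r.authority for r in records if r.approved and r.is_SRA)
        return AttributeScore(attr, 3, ("registration.sra_approved",),
                              f"approved by stringent regulatory authority ({names})")
    if any(
        r.approved and r.maturity_level is not None and r.maturity_level >= 3
        for r in records
    ):
        return AttributeScore(attr, 2, ("registration.ml3_approved",),
                              "approved by a maturity level >= 3 authority")
    if any(r.approval_anticipated and r.is_SRA for r in records):
        return AttributeScore(attr, 2, ("registration.sra_anticipated",),
                              "stringent regulatory authority approval anticipated")
    return AttributeScore(attr, 1, ("registration.none",),
                          "not approved by any regulatory authority and "
                          "no approvals anticipated")


# --------------------------------------------------------------------------
# assembly and aggregation


def assemble_profile(
    product: FormulationProduct,
    config: Optional[ToolConfig] = None,
    growth: Optional[GrowthReference] = None,
    registry=None,
) -> PQTPPProfile:
    """Run the dose and excipient engines, then all eight scorers.

    Deterministic for a fixed product and config; not-evaluable states
    propagate as score 0 rather than aborting the assessment.
    """
    config = config or DEFAULT_CONFIG
    if growth is None:
        growth = (
            GrowthReference.from_csv(config.growth_reference_path)
            if config.growth_reference_path
            else default_growth_reference()
        )
    if registry is None and config.registry_path:
        from .excipients import load_registry

        registry = load_registry(config.registry_path)
    table = (
        load_acceptability_table(config.acceptability_table_path)
        if config.acceptability_table_path
        else None
    )

    assessments = assess_dose(product, config=config, growth=growth)
    findings = evaluate_excipients(
        product, registry=registry, growth=growth, config=config
    )
    scores = (
        score_target_population(product, config),
        score_dose_flexibility(assessments, config),
        score_acceptability(product, "0_5", assessments, config, table=table),
        score_acceptability(product, "6_12", assessments, config, table=table),
        score_excipient_safety(findings, product, config),
        score_administration(product.administration, assessments, config),
        score_stability(product.stability, product.packaging, config),
        score_registration(product.regulatory, product.assertions),
    )
    return PQTPPProfile(
        product_label=product.label,
        medicine_name=product.medicine_name,
        scores=scores,
        comments=product.assertions.notes or "",
    )


def aggregate_profiles(profiles: Sequence[PQTPPProfile]) -> PQTPPProfile:
    """Overview across several licences of the same medicine/dosage form.

    Per attribute the overview score is the modal score (ties resolved to
    the lower, i.e. worse, score); grey zeros are ignored whenever any
    informative score exists, since they encode missing information rather
    than risk.  The min-max range is kept in the rationale.
    """
    if not profiles:
        raise ValueError("need at least one profile to aggregate")
    medicines = {p.medicine_name for p in profiles}
    if len(medicines) > 1:
        raise ValueError(f"cannot aggregate across medicines: {sorted(medicines)}")
    scores = []
    for idx, attribute in enumerate(ATTRIBUTE_ORDER):
        values = [p.scores[idx].score for p in profiles]
        informative = [v for v in values if v != 0]
        pool = informative or values
        counts = Counter(pool)
        top = max(counts.values())
        overview = min(v for v, c in counts.items() if c == top)
        rationale = f"overview of {len(profiles)} licence(s); scores ranged " \
                    f"{min(pool)}-{max(pool)}"
        scores.append(AttributeScore(attribute, overview,
                                     ("aggregate.modal_score",), rationale))
    return PQTPPProfile(
        product_label=f"{profiles[0].medicine_name} (overview of {len(profiles)})",
        medicine_name=profiles[0].medicine_name,
        scores=tuple(scores),
        comments="; ".join(filter(None, (p.comments for p in profiles))),
    )
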