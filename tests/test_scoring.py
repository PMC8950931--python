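"""Attribute scorers, severity-ladder semantics and aggregation."""

import itertools

import pytest

from pqtpp import (
    ATTRIBUTE_ORDER,
    SCORE_COLOURS,
    Attribute,
    aggregate_profiles,
    assemble_profile,
    assess_dose,
    evaluate_excipients,
    score_acceptability,
    score_administration,
    score_dose_flexibility,
    score_excipient_safety,
    score_registration,
    score_stability,
    score_target_population,
)
from pqtpp.model import (
    AdministrationProfile,
    AgeRange,
    BulkClass,
    Burden,
    DosageForm,
    DoseMode,
    ExcipientEntry,
    FormulationProduct,
    Manipulation,
    PackagingProfile,
    PackComplexity,
    PosologyRule,
    QualitativeAssertions,
    RegulatoryRecord,
    Setting,
    StabilityProfile,
    StorageClass,
    Strength,
)

from conftest import make_unknown_product

UNKNOWN_PRODUCT = make_unknown_product()


# ---------------------------------------------------------------- target population


def test_product_indicated_only_from_eleven_years_scores_red(products):
    late = products["paracetamol_oral_liquid"].model_copy(
        update={"indicated_age_range": AgeRange(min_months=132, max_months=144)}
    )
    assert score_target_population(late).score == 1


def test_swallow_only_form_covers_half_the_population(products):
    assert score_target_population(products["paracetamol_tablet"]).score == 2
    assert score_target_population(products["clofazimine_capsule_50_100"]).score == 2


def test_liquid_and_suppository_cover_whole_population(products):
    assert score_target_population(products["paracetamol_oral_liquid"]).score == 3
    # a licence floor of a few months still counts as whole-population coverage
    assert score_target_population(products["paracetamol_suppository_100mg"]).score == 3


# ---------------------------------------------------------------- dose flexibility


def test_single_strength_tablet_mostly_unreachable_scores_red(growth):
    product = FormulationProduct(
        medicine_name="x",
        dosage_form=DosageForm(category="conventional_tablet"),
        strengths=[Strength(amount_mg=500)],
        posology=[
            PosologyRule(
                age_window=AgeRange(min_months=0, max_months=144),
                dose_mode=DoseMode.per_kg_mg,
                dose_low=10,
                dose_high=15,
                frequency_per_day=4,
            )
        ],
    )
    assessments = assess_dose(product, growth=growth)
    score = score_dose_flexibility(assessments)
    assert score.score == 1


def test_no_assessable_posology_scores_grey(growth):
    assessments = assess_dose(UNKNOWN_PRODUCT, growth=growth)
    assert score_dose_flexibility(assessments).score == 0


def test_dose_flexibility_requires_assessments():
    with pytest.raises(ValueError):
        score_dose_flexibility([])


# ---------------------------------------------------------------- acceptability


def test_tablet_unacceptable_under_six_but_fine_over_six(products, growth):
    tablet = products["paracetamol_tablet"]
    assessments = assess_dose(tablet, growth=growth)
    assert score_acceptability(tablet, "0_5", assessments).score == 1
    assert score_acceptability(tablet, "6_12", assessments).score == 3


def test_small_capsule_acceptable_but_large_one_capped(products, growth):
    capsule = products["clofazimine_capsule_50_100"]
    assessments = assess_dose(capsule, growth=growth)
    assert score_acceptability(capsule, "6_12", assessments).score == 3
    big = capsule.model_copy(
        update={"dosage_form": DosageForm(category="capsule_softgel",
                                          largest_dimension_mm=18)}
    )
    assert score_acceptability(big, "6_12", assessments).score == 2


def test_high_liquid_volumes_cap_older_band_only(products, growth):
    liquid = products["paracetamol_oral_liquid"]
    assessments = assess_dose(liquid, growth=growth)
    assert score_acceptability(liquid, "0_5", assessments).score == 3
    score = score_acceptability(liquid, "6_12", assessments)
    assert score.score == 2
    assert "acceptability.high_volume" in score.triggered_criteria


def test_multiple_suppositories_cap_older_band(products, growth):
    supp = products["paracetamol_suppository_100mg"]
    assessments = assess_dose(supp, growth=growth)
    assert score_acceptability(supp, "0_5", assessments).score == 3
    score = score_acceptability(supp, "6_12", assessments)
    assert score.score == 2
    assert "acceptability.multiple_suppositories" in score.triggered_criteria


def test_strongly_aversive_palatability_forces_red(products):
    bitter = products["paracetamol_oral_liquid"].model_copy(
        update={"assertions": QualitativeAssertions(palatability="strongly_aversive")}
    )
    score = score_acceptability(bitter, "0_5")
    assert score.score == 1
    assert "assertion-sourced" in score.rationale


def test_frequent_dosing_penalised_only_for_chronic_use(products, growth):
    liquid = products["paracetamol_oral_liquid"]  # 4x/day but short-term
    assessments = assess_dose(liquid, growth=growth)
    assert score_acceptability(liquid, "0_5", assessments).score == 3
    chronic = liquid.model_copy(update={"chronic_use": True})
    assert score_acceptability(chronic, "0_5", assessments).score == 2


def test_unknown_band_rejected(products):
    with pytest.raises(ValueError):
        score_acceptability(products["paracetamol_tablet"], "0_99")


# ---------------------------------------------------------------- excipient safety


def test_excipient_score_bands(products):
    liquid = products["paracetamol_oral_liquid"]
    assert score_excipient_safety(evaluate_excipients(liquid), liquid).score == 1
    capsule = products["clofazimine_capsule_50_100"]
    assert score_excipient_safety(evaluate_excipients(capsule), capsule).score == 2
    tablet = products["paracetamol_tablet"]
    assert score_excipient_safety(evaluate_excipients(tablet), tablet).score == 3


def test_unknown_composition_scores_grey(products):
    bare = products["paracetamol_tablet"].model_copy(update={"excipients": []})
    assert score_excipient_safety([], bare).score == 0


def test_assertion_summary_substitutes_for_structured_data(products):
    asserted = products["paracetamol_tablet"].model_copy(
        update={
            "excipients": [],
            "assertions": QualitativeAssertions(excipient_profile_summary="some_concern"),
        }
    )
    score = score_excipient_safety([], asserted)
    assert score.score == 2
    assert "assertion-sourced" in score.rationale


# ---------------------------------------------------------------- administration


def test_administration_examples(products, growth):
    tablet = products["paracetamol_tablet"]
    assert score_administration(tablet.administration).score == 3
    liquid = products["paracetamol_oral_liquid"]
    assert score_administration(liquid.administration).score == 2
    supp = products["paracetamol_suppository_100mg"]
    score = score_administration(supp.administration)
    assert score.score == 2
    assert "administration.insertion_burden_moderate" in score.triggered_criteria


def _admin_oracle(profile):
    """Independent most-severe-criterion reading of the administration rubric."""
    if profile.manipulation is None:
        return 0
    severities = []
    hcp = profile.setting is Setting.healthcare_facility
    base = {
        Manipulation.none: 3,
        Manipulation.dose_measurement: 3 if hcp else 2,
        Manipulation.food_mixing: 2,
        Manipulation.reconstitution_fixed_volume: 2 if hcp else 1,
        Manipulation.multiple_dilution: 1,
    }[profile.manipulation]
    severities.append(base)
    if profile.device_required and profile.device_readily_available is False:
        severities.append(1)
    if profile.insertion_or_injection_burden is Burden.high:
        severities.append(1)
    elif profile.insertion_or_injection_burden is Burden.moderate:
        severities.append(2)
    return min(severities)


def test_administration_matches_most_severe_criterion_oracle():
    manipulations = (None,) + tuple(Manipulation)
    burdens = (None,) + tuple(Burden)
    devices = ((None, None), ("syringe", True), ("syringe", False))
    for manip, setting, burden, (device, available) in itertools.product(
        manipulations, Setting, burdens, devices
    ):
        profile = AdministrationProfile(
            manipulation=manip,
            setting=setting,
            insertion_or_injection_burden=burden,
            device_required=device,
            device_readily_available=available,
        )
        assert score_administration(profile).score == _admin_oracle(profile), profile


# ---------------------------------------------------------------- stability


def test_stability_examples(products):
    capsule = products["clofazimine_capsule_50_100"]
    score = score_stability(capsule.stability, capsule.packaging)
    assert score.score == 2
    assert "stability.moisture_protection_required" in score.triggered_criteria
    tablet = products["paracetamol_tablet"]
    assert score_stability(tablet.stability, tablet.packaging).score == 3
    syrup = StabilityProfile(shelf_life_months=12, storage="refrigerated_2_8C")
    score = score_stability(syrup)
    assert score.score == 1
    assert len(score.triggered_criteria) == 2  # two red criteria fire together


def test_bulky_bottle_alone_demotes_to_yellow_not_red(products):
    liquid = products["paracetamol_oral_liquid"]
    score = score_stability(liquid.stability, liquid.packaging)
    assert score.score == 2
    assert score.triggered_criteria == ("stability.bulky_or_complex_packaging",)


def _stability_oracle(stability, packaging):
    """Independent severity-ladder reading of the stability rubric."""
    if stability.shelf_life_months is None and stability.storage is None:
        return 0
    severities = [3]
    if stability.storage in (StorageClass.refrigerated_2_8C, StorageClass.freezer):
        severities.append(1)
    if stability.shelf_life_months is not None:
        if stability.shelf_life_months < 18:
            severities.append(1)
        elif stability.shelf_life_months < 24:
            severities.append(2)
    if stability.constituted_requires_refrigeration:
        severities.append(2)
    if stability.moisture_protection_required:
        severities.append(2)
    if packaging.bulk_class is BulkClass.bulky_heavy or (
        packaging.complexity is PackComplexity.complex
    ):
        severities.append(2)
    return min(severities)


def test_stability_matches_severity_ladder_oracle():
    storages = (None,) + tuple(StorageClass)
    shelves = (None, 6, 12, 17, 18, 20, 23, 24, 36, 60)
    for storage, shelf, constituted, moisture, bulk, complexity in itertools.product(
        storages, shelves, (False, True), (False, True), BulkClass, PackComplexity
    ):
        stability = StabilityProfile(
            shelf_life_months=shelf,
            storage=storage,
            constituted_requires_refrigeration=constituted,
            moisture_protection_required=moisture,
        )
        packaging = PackagingProfile(bulk_class=bulk, complexity=complexity)
        assert score_stability(stability, packaging).score == _stability_oracle(
            stability, packaging
        ), (stability, packaging)


# ---------------------------------------------------------------- registration


def test_registration_ladder():
    sra = RegulatoryRecord(authority="EMA", is_SRA=True, approved=True)
    ml3 = RegulatoryRecord(authority="NRA-X", maturity_level=3, approved=True)
    anticipated = RegulatoryRecord(authority="USFDA", is_SRA=True,
                                   approval_anticipated=True)
    nothing = RegulatoryRecord(authority="NRA-Y")
    assert score_registration([sra, nothing]).score == 3
    assert score_registration([ml3]).score == 2
    assert score_registration([anticipated]).score == 2
    assert score_registration([nothing]).score == 1
    assert score_registration([]).score == 1  # absence of approvals is red


# ---------------------------------------------------------------- assembly


def test_colour_score_bijection_on_profiles(products):
    assert SCORE_COLOURS == {3: "green", 2: "yellow", 1: "red", 0: "grey"}
    for product in products.values():
        for score in assemble_profile(product).scores:
            assert score.score in SCORE_COLOURS
            assert score.colour == SCORE_COLOURS[score.score]


def test_profile_is_deterministic_and_hash_stable(products):
    first = assemble_profile(products["clofazimine_capsule_50_100"])
    second = assemble_profile(products["clofazimine_capsule_50_100"])
    assert first.to_json() == second.to_json()


def test_all_unknown_product_yields_all_zero_profile():
    profile = assemble_profile(UNKNOWN_PRODUCT)
    assert profile.vector() == (0,) * 8


def test_monotonicity_under_single_dimension_worsening(products):
    capsule = products["clofazimine_capsule_50_100"]
    base = assemble_profile(capsule)

    shorter_shelf = capsule.model_copy(
        update={"stability": capsule.stability.model_copy(
            update={"shelf_life_months": 12})}
    )
    assert (
        assemble_profile(shorter_shelf)
        .score_for(Attribute.stability_storage_packaging).score
        <= base.score_for(Attribute.stability_storage_packaging).score
    )

    extra_excipient = capsule.model_copy(
        update={"excipients": list(capsule.excipients)
                + [ExcipientEntry(name="sorbitol", function="sweetener_polyol")]}
    )
    assert (
        assemble_profile(extra_excipient).score_for(Attribute.excipient_safety).score
        <= base.score_for(Attribute.excipient_safety).score
    )

    liquid = products["paracetamol_oral_liquid"]
    base_liquid = assemble_profile(liquid)
    unapproved = liquid.model_copy(
        update={"regulatory": [r.model_copy(update={"approved": False})
                               for r in liquid.regulatory]}
    )
    assert (
        assemble_profile(unapproved).score_for(Attribute.registration_status).score
        <= base_liquid.score_for(Attribute.registration_status).score
    )

    tablet = products["paracetamol_tablet"]
    base_tablet = assemble_profile(tablet)
    fewer = tablet.model_copy(update={"strengths": tablet.strengths[:1]})
    assert (
        assemble_profile(fewer).score_for(Attribute.dose_flexibility).score
        <= base_tablet.score_for(Attribute.dose_flexibility).score
    )


# ---------------------------------------------------------------- aggregation


def test_aggregate_single_profile_is_identity(products):
    profile = assemble_profile(products["paracetamol_tablet"])
    assert aggregate_profiles([profile]).vector() == profile.vector()


def _profile_with_vector(products, attribute, score):
    base = assemble_profile(products["paracetamol_tablet"])
    idx = ATTRIBUTE_ORDER.index(attribute)
    scores = list(base.scores)
    scores[idx] = scores[idx].__class__(attribute, score)
    return base.__class__(base.product_label, base.medicine_name, tuple(scores))


def test_aggregate_mode_and_tie_rules(products):
    attr = Attribute.stability_storage_packaging
    trio = [_profile_with_vector(products, attr, s) for s in (3, 3, 2)]
    agg = aggregate_profiles(trio)
    assert agg.score_for(attr).score == 3
    assert "2-3" in agg.score_for(attr).rationale
    duo = [_profile_with_vector(products, attr, s) for s in (3, 2)]
    assert aggregate_profiles(duo).score_for(attr).score == 2  # tie -> worse


def test_aggregate_ignores_grey_when_informative_scores_exist(products):
    attr = Attribute.excipient_safety
    mixed = [_profile_with_vector(products, attr, s) for s in (0, 3, 0)]
    assert aggregate_profiles(mixed).score_for(attr).score == 3


def test_aggregate_rejects_empty_and_mixed_medicines(products):
    with pytest.raises(ValueError):
        aggregate_profiles([])
    with pytest.raises(ValueError):
        aggregate_profiles([
            assemble_profile(products["paracetamol_tablet"]),
            assemble_profile(products["clofazimine_capsule_50_100"]),
        ])
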