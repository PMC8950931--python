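"""Domain model for structured formulation records.

A :class:`FormulationProduct` captures what a product label or SmPC states
about one marketed presentation of a medicine: dosage form, strengths or
concentrations, posology rules, excipients, stability/storage, primary
packaging, regulatory approvals and administration burden.  The model is the
single schema against which YAML/JSON records are validated; unknown fields
are rejected so that typos in input documents surface as errors rather than
silently dropped data.

Ages are stored in months (integers).  The assessment covers children from
birth up to and including 12 years, so 144 months is the hard ceiling.
Dosing frequencies are stored as exact rationals (doses per day), which lets
weekly (``2/7``), alternate-day (``1/2``) and monthly (``1/30``) regimens
round-trip without floating-point drift and share one comparison axis with
daily regimens.
"""

from __future__ import annotations

from enum import Enum
from fractions import Fraction
from typing import Annotated, Optional

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    PlainSerializer,
    PlainValidator,
    model_validator,
)

MAX_AGE_MONTHS = 144


# --------------------------------------------------------------------------
# exact-rational dosing frequency


def _parse_frequency(value: object) -> Fraction:
    if isinstance(value, Fraction):
        frac = value
    elif isinstance(value, bool):
        raise ValueError("frequency_per_day must be a number or 'a/b' string")
    elif isinstance(value, int):
        frac = Fraction(value)
    elif isinstance(value, float):
        frac = Fraction(value).limit_denominator(100_000)
    elif isinstance(value, str):
        frac = Fraction(value.strip())
    else:
        raise ValueError("frequency_per_day must be a number or 'a/b' string")
    if frac <= 0:
        raise ValueError("frequency_per_day must be > 0")
    return frac


def _dump_frequency(frac: Fraction):
    if frac.denominator == 1:
        return frac.numerator
    return f"{frac.numerator}/{frac.denominator}"


FrequencyPerDay = Annotated[
    Fraction, PlainValidator(_parse_frequency), PlainSerializer(_dump_frequency)
]


# --------------------------------------------------------------------------
# enumerations


class DosageFormCategory(str, Enum):
    conventional_tablet = "conventional_tablet"
    dispersible_tablet = "dispersible_tablet"
    orodispersible_tablet = "orodispersible_tablet"
    scored_tablet = "scored_tablet"
    capsule_hard = "capsule_hard"
    capsule_softgel = "capsule_softgel"
    oral_liquid = "oral_liquid"
    powder_for_oral_liquid = "powder_for_oral_liquid"
    granules_minitablets = "granules_minitablets"
    suppository = "suppository"
    injection = "injection"
    topical_semisolid = "topical_semisolid"
    #: records where the label does not identify the presentation; scores
    #: that depend on the dosage form fall back to 0 (insufficient information)
    unknown = "unknown"


#: forms that must be swallowed whole, hence unsuitable before the age at
#: which children can reliably swallow tablets (~6 years)
SWALLOW_WHOLE_CATEGORIES = frozenset(
    {
        DosageFormCategory.conventional_tablet,
        DosageFormCategory.scored_tablet,
        DosageFormCategory.capsule_hard,
        DosageFormCategory.capsule_softgel,
    }
)

LIQUID_CATEGORIES = frozenset(
    {DosageFormCategory.oral_liquid, DosageFormCategory.powder_for_oral_liquid}
)


class ExcipientFunction(str, Enum):
    preservative = "preservative"
    sweetener_polyol = "sweetener_polyol"
    sugar = "sugar"
    colourant = "colourant"
    flavour = "flavour"
    cosolvent = "cosolvent"
    surfactant = "surfactant"
    filler_binder = "filler_binder"
    other = "other"


class ConcentrationClass(str, Enum):
    trace_in_flavour = "trace_in_flavour"
    functional = "functional"


class StorageClass(str, Enum):
    room_temperature = "room_temperature"  # 20-25 degC
    below_25C = "below_25C"
    refrigerated_2_8C = "refrigerated_2_8C"
    freezer = "freezer"


class BulkClass(str, Enum):
    light_low_bulk = "light_low_bulk"
    bulky_heavy = "bulky_heavy"


class PackComplexity(str, Enum):
    simple = "simple"
    complex = "complex"


class Manipulation(str, Enum):
    none = "none"
    dose_measurement = "dose_measurement"
    food_mixing = "food_mixing"
    reconstitution_fixed_volume = "reconstitution_fixed_volume"
    multiple_dilution = "multiple_dilution"


class Setting(str, Enum):
    domiciliary = "domiciliary"
    healthcare_facility = "healthcare_facility"
    both = "both"


class Burden(str, Enum):
    none = "none"
    moderate = "moderate"
    high = "high"


class Palatability(str, Enum):
    acceptable = "acceptable"
    concerns = "concerns"
    strongly_aversive = "strongly_aversive"


class ExcipientSummary(str, Enum):
    acceptable = "acceptable"
    some_concern = "some_concern"
    several_concerns = "several_concerns"
    unknown = "unknown"


class DoseMode(str, Enum):
    fixed_mg = "fixed_mg"
    per_kg_mg = "per_kg_mg"


# --------------------------------------------------------------------------
# record components


class StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class AgeRange(StrictModel):
    """Closed age window in months, within the 0-144 month assessment span."""

    min_months: int = Field(ge=0, le=MAX_AGE_MONTHS)
    max_months: int = Field(ge=0, le=MAX_AGE_MONTHS)

    @model_validator(mode="after")
    def _ordered(self) -> "AgeRange":
        if self.min_months > self.max_months:
            raise ValueError("min_months must be <= max_months")
        return self

    def contains(self, age_months: float) -> bool:
        return self.min_months <= age_months <= self.max_months

    def overlaps(self, other: "AgeRange") -> bool:
        return self.min_months <= other.max_months and other.min_months <= self.max_months

    @property
    def span_months(self) -> int:
        return self.max_months - self.min_months


class DosageForm(StrictModel):
    category: DosageFormCategory
    largest_dimension_mm: Optional[float] = Field(default=None, gt=0)


class Strength(StrictModel):
    """One marketed strength: mg per unit (solids) or mg/mL (liquids)."""

    amount_mg: Optional[float] = Field(default=None, gt=0)
    concentration_mg_per_ml: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _exactly_one(self) -> "Strength":
        if (self.amount_mg is None) == (self.concentration_mg_per_ml is None):
            raise ValueError(
                "exactly one of amount_mg / concentration_mg_per_ml must be set"
            )
        return self


class PosologyRule(StrictModel):
    """One dosing instruction: age (and optionally weight) window to dose.

    ``dose_low``/``dose_high`` are mg per dose (``fixed_mg``) or mg/kg per
    dose (``per_kg_mg``).  ``frequency_per_day`` is an exact rational so that
    sub-daily regimens keep their meaning (``1/30`` = monthly).
    """

    age_window: AgeRange
    weight_window_kg: Optional[tuple[float, float]] = None
    dose_mode: DoseMode
    dose_low: float = Field(gt=0)
    dose_high: float = Field(gt=0)
    frequency_per_day: FrequencyPerDay
    max_daily_mg_per_kg: Optional[float] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "PosologyRule":
        if self.dose_low > self.dose_high:
            raise ValueError("dose_low must be <= dose_high")
        if self.weight_window_kg is not None:
            lo, hi = self.weight_window_kg
            if lo < 0 or lo > hi:
                raise ValueError("weight_window_kg must be an ordered non-negative pair")
        return self


class ExcipientEntry(StrictModel):
    name: str
    function: ExcipientFunction = ExcipientFunction.other
    quantity_mg_per_unit: Optional[float] = Field(default=None, gt=0)
    concentration_class: Optional[ConcentrationClass] = None


class StabilityProfile(StrictModel):
    shelf_life_months: Optional[int] = Field(default=None, gt=0)
    storage: Optional[StorageClass] = None
    constituted_requires_refrigeration: bool = False
    moisture_protection_required: bool = False


class PackagingProfile(StrictModel):
    pack_type: Optional[str] = None
    bulk_class: Optional[BulkClass] = None
    complexity: Optional[PackComplexity] = None


class RegulatoryRecord(StrictModel):
    authority: str
    is_SRA: bool = False
    maturity_level: Optional[int] = Field(default=None, ge=1, le=4)
    approved: bool = False
    approval_anticipated: bool = False
    approved_age_range: Optional[AgeRange] = None
    supports_tablet_splitting: Optional[bool] = None
    supports_dispersion_administration: Optional[bool] = None


class AdministrationProfile(StrictModel):
    manipulation: Optional[Manipulation] = None
    device_required: Optional[str] = None
    device_readily_available: Optional[bool] = None
    insertion_or_injection_burden: Optional[Burden] = None
    setting: Setting = Setting.both


class QualitativeAssertions(StrictModel):
    """Label-narrative overrides used when structured data are unavailable.

    Every score influenced by one of these carries an "assertion-sourced"
    note in its rationale, so overview reports can show which cells rest on
    narrative rather than structured evidence.
    """

    palatability: Optional[Palatability] = None
    excipient_profile_summary: Optional[ExcipientSummary] = None
    registration_unknown: bool = False
    notes: Optional[str] = None


class FormulationProduct(StrictModel):
    medicine_name: str
    product_label: Optional[str] = None
    indication: Optional[str] = None
    #: youngest age at which the indication itself is relevant/diagnosable
    condition_min_age_months: int = Field(default=0, ge=0, le=MAX_AGE_MONTHS)
    #: chronic regimens are penalised for frequent dosing; short-term use is not
    chronic_use: bool = False
    indicated_age_range: Optional[AgeRange] = None
    dosage_form: DosageForm
    strengths: list[Strength] = Field(min_length=1)
    posology: list[PosologyRule] = Field(min_length=1)
    excipients: list[ExcipientEntry] = Field(default_factory=list)
    stability: StabilityProfile = Field(default_factory=StabilityProfile)
    packaging: PackagingProfile = Field(default_factory=PackagingProfile)
    regulatory: list[RegulatoryRecord] = Field(default_factory=list)
    administration: AdministrationProfile = Field(default_factory=AdministrationProfile)
    assertions: QualitativeAssertions = Field(default_factory=QualitativeAssertions)

    @model_validator(mode="after")
    def _strengths_match_form(self) -> "FormulationProduct":
        category = self.dosage_form.category
        for i, strength in enumerate(self.strengths):
            if category in LIQUID_CATEGORIES:
                if strength.concentration_mg_per_ml is None:
                    raise ValueError(
                        f"strengths[{i}]: liquid forms need concentration_mg_per_ml"
                    )
            elif category in (
                DosageFormCategory.injection,
                DosageFormCategory.topical_semisolid,
                DosageFormCategory.unknown,
            ):
                pass  # either representation is meaningful
            elif strength.amount_mg is None:
                raise ValueError(f"strengths[{i}]: solid forms need amount_mg")
        return self

    @property
    def label(self) -> str:
        if self.product_label:
            return self.product_label
        return f"{self.medicine_name} {self.dosage_form.category.value}"

    def splitting_supported(self) -> bool:
        return any(r.supports_tablet_splitting for r in self.regulatory)


def formulation_json_schema() -> dict:
    """JSON Schema (draft 2020-12, as emitted by pydantic) for input records."""
    return FormulationProduct.model_json_schema()
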