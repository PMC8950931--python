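"""Bundled worked-example records and a synthetic formulation generator.

The named fixtures encode the published paracetamol (tablet, oral liquid,
100 mg suppository) and clofazimine (soft-gel capsule, tablet) evaluations
as machine-readable records; they are the package's primary regression
oracle.  :func:`generate_synthetic` produces random schema-valid products
for property tests, spanning every dosage-form category, concern-excipient
counts 0-3, shelf lives 6-60 months, all storage classes and 0-2 regulatory
records.
"""

from __future__ import annotations

import random
from fractions import Fraction
from importlib import resources

from .io import reads_formulation
from .model import (
    AdministrationProfile,
    AgeRange,
    BulkClass,
    Burden,
    DosageForm,
    DosageFormCategory,
    DoseMode,
    ExcipientEntry,
    ExcipientFunction,
    FormulationProduct,
    LIQUID_CATEGORIES,
    Manipulation,
    PackagingProfile,
    PackComplexity,
    PosologyRule,
    RegulatoryRecord,
    Setting,
    StabilityProfile,
    StorageClass,
    Strength,
)

__all__ = ["FIXTURE_NAMES", "load_fixture", "generate_synthetic"]

FIXTURE_NAMES = (
    "paracetamol_tablet",
    "paracetamol_oral_liquid",
    "paracetamol_suppository_100mg",
    "clofazimine_capsule_50_100",
    "clofazimine_tablet_50_100",
)


def load_fixture(name: str) -> FormulationProduct:
    """Load and validate one of the bundled worked-example records."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    text = (
        resources.files("pqtpp.data")
        .joinpath("fixtures").joinpath(f"{name}.yaml")
        .read_text(encoding="utf-8")
    )
    return reads_formulation(text)


def fixture_text(name: str) -> str:
    """Raw YAML of a bundled fixture (for export via the CLI)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}")
    return (
        resources.files("pqtpp.data")
        .joinpath("fixtures").joinpath(f"{name}.yaml")
        .read_text(encoding="utf-8")
    )


_CONCERN_POOL = (
    ("sodium benzoate", ExcipientFunction.preservative),
    ("ethanol", ExcipientFunction.cosolvent),
    ("propylene glycol", ExcipientFunction.cosolvent),
    ("methylparaben", ExcipientFunction.preservative),
    ("sorbitol", ExcipientFunction.sweetener_polyol),
    ("sucrose", ExcipientFunction.sugar),
    ("tartrazine", ExcipientFunction.colourant),
    ("saccharin sodium", ExcipientFunction.sweetener_polyol),
)
_BENIGN_POOL = (
    ("microcrystalline cellulose", ExcipientFunction.filler_binder),
    ("purified water", ExcipientFunction.other),
    ("magnesium stearate", ExcipientFunction.other),
)
_FREQUENCIES = (Fraction(1, 30), Fraction(2, 7), Fraction(1, 2), Fraction(1),
                Fraction(2), Fraction(3), Fraction(4))


def _synthetic_product(rng: random.Random, index: int) -> FormulationProduct:
    category = rng.choice(list(DosageFormCategory))
    if category in LIQUID_CATEGORIES:
        strengths = [
            Strength(concentration_mg_per_ml=rng.choice((1, 2, 5, 10, 20, 24, 25, 50)))
            for _ in range(rng.randint(1, 2))
        ]
    else:
        amounts = rng.sample((25, 50, 100, 200, 250, 300, 400, 500), rng.randint(1, 3))
        strengths = [Strength(amount_mg=a) for a in amounts]

    window_lo = rng.choice((0, 0, 3, 24))
    window_hi = rng.choice((119, 144, 144))
    if rng.random() < 0.5:
        rule = PosologyRule(
            age_window=AgeRange(min_months=window_lo, max_months=window_hi),
            dose_mode=DoseMode.per_kg_mg,
            dose_low=rng.choice((2, 5, 10)),
            dose_high=rng.choice((15, 20, 25)),
            frequency_per_day=rng.choice(_FREQUENCIES),
            max_daily_mg_per_kg=rng.choice((None, 60, 100)),
        )
    else:
        low = rng.choice((25, 50, 100, 150))
        rule = PosologyRule(
            age_window=AgeRange(min_months=window_lo, max_months=window_hi),
            dose_mode=DoseMode.fixed_mg,
            dose_low=low,
            dose_high=low + rng.choice((0, 50, 100)),
            frequency_per_day=rng.choice(_FREQUENCIES),
        )

    n_concern = rng.randint(0, 3)
    excipients = [
        ExcipientEntry(name=name, function=fn)
        for name, fn in rng.sample(_CONCERN_POOL, n_concern)
    ]
    for name, fn in rng.sample(_BENIGN_POOL, rng.randint(0, 2)):
        excipients.append(ExcipientEntry(name=name, function=fn))

    storage = rng.choice((None,) + tuple(StorageClass))
    shelf = rng.choice((None, 6, 12, 18, 20, 24, 36, 60))
    stability = StabilityProfile(
        shelf_life_months=shelf,
        storage=storage,
        constituted_requires_refrigeration=rng.random() < 0.2,
        moisture_protection_required=rng.random() < 0.3,
    )
    packaging = PackagingProfile(
        pack_type=rng.choice(("blister", "bottle", "sachet")),
        bulk_class=rng.choice(tuple(BulkClass)),
        complexity=rng.choice(tuple(PackComplexity)),
    )
    regulatory = [
        RegulatoryRecord(
            authority=rng.choice(("EMA", "USFDA", "MHRA", "TGA", "NRA-X")),
            is_SRA=rng.random() < 0.5,
            maturity_level=rng.choice((None, 2, 3, 4)),
            approved=rng.random() < 0.6,
            approval_anticipated=rng.random() < 0.3,
            approved_age_range=rng.choice(
                (None, AgeRange(min_months=0, max_months=144),
                 AgeRange(min_months=24, max_months=144))
            ),
            supports_tablet_splitting=rng.choice((None, True, False)),
        )
        for _ in range(rng.randint(0, 2))
    ]
    administration = AdministrationProfile(
        manipulation=rng.choice((None,) + tuple(Manipulation)),
        device_required=rng.choice((None, "oral syringe")),
        device_readily_available=rng.choice((None, True, False)),
        insertion_or_injection_burden=rng.choice((None,) + tuple(Burden)),
        setting=rng.choice(tuple(Setting)),
    )
    return FormulationProduct(
        medicine_name=f"synthetic-{index}",
        product_label=f"Synthetic product {index}",
        indication="synthetic test record",
        condition_min_age_months=rng.choice((0, 0, 3, 36)),
        chronic_use=rng.random() < 0.5,
        dosage_form=DosageForm(
            category=category,
            largest_dimension_mm=rng.choice((None, 5.0, 7.0, 12.0)),
        ),
        strengths=strengths,
        posology=[rule],
        excipients=excipients,
        stability=stability,
        packaging=packaging,
        regulatory=regulatory,
        administration=administration,
    )


def generate_synthetic(seed: int, n: int) -> list[FormulationProduct]:
    """Deterministically generate ``n`` random valid formulation records."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    return [_synthetic_product(rng, i) for i in range(n)]
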