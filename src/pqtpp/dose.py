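"""Dose evidence: required doses by age, achievable doses, volumes and flags.

For each age on the evaluation grid the engine derives the required dose
window from the applicable posology rules (multiplying mg/kg rules by the
median weight-for-age), enumerates the doses the marketed strengths can
actually deliver, and records whether the requirement is achievable plus the
volume/unit-count evidence that the acceptability and administration scorers
consume.

Two hard usability thresholds apply to oral liquids: volumes below 0.1 mL
cannot be measured reliably and are treated as unachievable, and volumes
above 10 mL per dose are flagged as burdensome for older children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import DEFAULT_CONFIG, ToolConfig
from .growth import GrowthReference, default_growth_reference
from .model import (
    LIQUID_CATEGORIES,
    DosageFormCategory,
    DoseMode,
    FormulationProduct,
    PosologyRule,
)

__all__ = [
    "AchievableDose",
    "DoseAssessment",
    "required_dose",
    "achievable_doses",
    "assess_dose",
    "rule_applies",
]

_EPS = 1e-9


@dataclass(frozen=True)
class AchievableDose:
    """One deliverable dose option."""

    dose_mg: float
    units_used: int
    split_used: bool = False
    volume_ml: Optional[float] = None


@dataclass(frozen=True)
class DoseAssessment:
    """Evidence for one (age, posology rule) pair.

    ``evaluable`` is False when no posology rule applies at the age (or the
    dosage form is unknown); such entries feed the score-0 path and never
    claim dosability.
    """

    age_months: int
    rule_index: Optional[int]
    evaluable: bool
    required_dose_low_mg: Optional[float] = None
    required_dose_high_mg: Optional[float] = None
    options_in_range: tuple[AchievableDose, ...] = ()
    dosable: bool = False
    units_per_dose: Optional[int] = None
    volume_ml: Optional[float] = None
    min_volume_flag: bool = False
    high_volume_flag: bool = False
    #: liquids measured on a syringe grid offer continuous dose increments
    fine_grid: bool = False

    @property
    def n_options_in_range(self) -> int:
        return len({opt.dose_mg for opt in self.options_in_range})


def rule_applies(
    rule: PosologyRule, age_months: float, weight_kg: Optional[float] = None
) -> bool:
    if not rule.age_window.contains(age_months):
        return False
    if rule.weight_window_kg is not None and weight_kg is not None:
        lo, hi = rule.weight_window_kg
        if not lo <= weight_kg <= hi:
            return False
    return True


def required_dose(
    rule: PosologyRule,
    age_months: float,
    growth: Optional[GrowthReference] = None,
) -> tuple[float, float]:
    """Required per-dose window (mg) for ``rule`` at ``age_months``.

    mg/kg rules are scaled by the median weight-for-age; a daily mg/kg cap,
    when stated, limits the per-dose high once the frequency is applied.
    """
    if not rule.age_window.contains(age_months):
        raise ValueError(
            f"age {age_months} months outside rule window "
            f"[{rule.age_window.min_months}, {rule.age_window.max_months}]"
        )
    growth = growth or default_growth_reference()
    weight = growth.median_weight(age_months)
    if rule.dose_mode is DoseMode.per_kg_mg:
        low, high = rule.dose_low * weight, rule.dose_high * weight
    else:
        low, high = rule.dose_low, rule.dose_high
    if rule.max_daily_mg_per_kg is not None:
        cap = rule.max_daily_mg_per_kg * weight / float(rule.frequency_per_day)
        high = min(high, cap)
        low = min(low, high)
    return low, high


def _max_units(product: FormulationProduct, config: ToolConfig) -> int:
    if product.dosage_form.category is DosageFormCategory.suppository:
        return config.dose.max_units_suppository
    return config.dose.max_units_per_dose


def achievable_doses(
    product: FormulationProduct,
    config: Optional[ToolConfig] = None,
) -> list[AchievableDose]:
    """Enumerate deliverable dose options for a product.

    Solids: every combination of whole units across the marketed strengths up
    to the per-dose unit budget, plus half units when a product licence
    supports tablet splitting.  Liquids: every volume on the measuring-device
    grid up to the maximum administrable volume, for each concentration.
    An unknown dosage form yields no options.
    """
    config = config or DEFAULT_CONFIG
    category = product.dosage_form.category
    if category is DosageFormCategory.unknown:
        return []

    options: dict[float, AchievableDose] = {}

    def offer(option: AchievableDose) -> None:
        key = round(option.dose_mg, 9)
        held = options.get(key)
        if held is None or option.units_used < held.units_used:
            options[key] = option

    if category in LIQUID_CATEGORIES:
        step_ml = config.dose.device_resolution_ml
        n_steps = int(math.floor(config.dose.max_volume_ml / step_ml + _EPS))
        for strength in product.strengths:
            conc = strength.concentration_mg_per_ml
            if conc is None:
                continue
            for k in range(1, n_steps + 1):
                volume = round(k * step_ml, 9)
                offer(
                    AchievableDose(
                        dose_mg=round(volume * conc, 9),
                        units_used=1,
                        volume_ml=volume,
                    )
                )
    else:
        unit_menu: list[tuple[float, bool]] = []
        for strength in product.strengths:
            if strength.amount_mg is None:
                continue
            unit_menu.append((strength.amount_mg, False))
            if product.splitting_supported():
                unit_menu.append((strength.amount_mg / 2.0, True))
        max_units = _max_units(product, config)

        def expand(start: int, units_left: int, dose: float, used: int, split: bool):
            if used:
                offer(AchievableDose(round(dose, 9), used, split))
            if units_left == 0:
                return
            for idx in range(start, len(unit_menu)):
                amount, is_half = unit_menu[idx]
                expand(idx, units_left - 1, dose + amount, used + 1, split or is_half)

        expand(0, max_units, 0.0, 0, False)

    return sorted(options.values(), key=lambda o: (o.dose_mg, o.units_used))


def _liquid_flags(
    product: FormulationProduct,
    low: float,
    high: float,
    in_range: list[AchievableDose],
    config: ToolConfig,
) -> tuple[bool, bool]:
    """(min_volume_flag, high_volume_flag) for oral-liquid assessments."""
    if product.dosage_form.category not in LIQUID_CATEGORIES:
        return False, False
    min_flag = False
    if not in_range:
        # unachievable because every conforming volume is below one graduation
        min_flag = all(
            high / s.concentration_mg_per_ml < config.dose.device_resolution_ml - _EPS
            for s in product.strengths
            if s.concentration_mg_per_ml is not None
        )
    chosen = min(
        (o.volume_ml for o in in_range if o.volume_ml is not None), default=None
    )
    high_flag = chosen is not None and chosen > config.scoring.high_volume_threshold_ml + _EPS
    return min_flag, high_flag


def assess_dose(
    product: FormulationProduct,
    ages: Optional[Sequence[int]] = None,
    config: Optional[ToolConfig] = None,
    growth: Optional[GrowthReference] = None,
) -> list[DoseAssessment]:
    """Evaluate the product at each grid age against every applicable rule.

    Returns one assessment per (age, rule) pair; ages with no applicable rule
    produce a single non-evaluable entry.
    """
    config = config or DEFAULT_CONFIG
    growth = growth or default_growth_reference()
    if ages is None:
        ages = [
            a
            for a in config.dose.age_grid_months
            if product.condition_min_age_months <= a
        ]
    options = achievable_doses(product, config)
    is_liquid = product.dosage_form.category in LIQUID_CATEGORIES

    out: list[DoseAssessment] = []
    for age in ages:
        weight = growth.median_weight(age)
        applicable = [
            (idx, rule)
            for idx, rule in enumerate(product.posology)
            if rule_applies(rule, age, weight)
        ]
        if not applicable or product.dosage_form.category is DosageFormCategory.unknown:
            out.append(DoseAssessment(age_months=age, rule_index=None, evaluable=False))
            continue
        for idx, rule in applicable:
            low, high = required_dose(rule, age, growth)
            in_range = [
                o for o in options if low - _EPS <= o.dose_mg <= high + _EPS
            ]
            min_flag, high_flag = _liquid_flags(product, low, high, in_range, config)
            chosen = min(
                in_range, key=lambda o: (o.units_used, o.volume_ml or 0.0, o.dose_mg)
            ) if in_range else None
            out.append(
                DoseAssessment(
                    age_months=age,
                    rule_index=idx,
                    evaluable=True,
                    required_dose_low_mg=low,
                    required_dose_high_mg=high,
                    options_in_range=tuple(in_range),
                    dosable=bool(in_range),
                    units_per_dose=chosen.units_used if chosen else None,
                    volume_ml=chosen.volume_ml if chosen else None,
                    min_volume_flag=min_flag,
                    high_volume_flag=high_flag,
                    fine_grid=is_liquid,
                )
            )
    return out
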