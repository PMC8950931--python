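"""Excipient risk screening for the paediatric population.

Excipients can behave very differently in children than in adults:
benzoates accumulate in neonates, polyol sweeteners have osmotic laxative
effects, ethanol and propylene glycol are higher-risk as bulk cosolvents
than as traces in a flavour.  Because full quantitative compositions are
rarely public, the engine works at two levels:

* presence-based: each listed excipient is matched against a concern
  registry (shipped as editable CSV data) filtered by administration route
  and by the target population's age window;
* exposure-based: when a quantity per unit is known and the registry carries
  an acceptable daily intake (ADI), the worst-case daily intake per kg over
  the evaluated age grid is compared against the ADI.

A finding can only escalate to ``adi_exceeded`` when both a quantity and an
ADI are known - presence alone never implies an exceeded intake.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .config import DEFAULT_CONFIG, ToolConfig
from .growth import GrowthReference, default_growth_reference
from .model import (
    AgeRange,
    ConcentrationClass,
    DosageFormCategory,
    ExcipientEntry,
    FormulationProduct,
    MAX_AGE_MONTHS,
)

__all__ = [
    "ConcernRule",
    "ExcipientFinding",
    "load_registry",
    "default_registry",
    "daily_intake",
    "evaluate_excipients",
]

_LEVEL_ORDER = {"potential": 1, "known": 2, "adi_exceeded": 3}


@dataclass(frozen=True)
class ConcernRule:
    """One registry row: which excipient names raise which level of concern."""

    name_pattern: str
    route: str = "any"  # any | oral | rectal | parenteral | topical
    population_restriction: Optional[AgeRange] = None
    adi_mg_per_kg_day: Optional[float] = None
    severity: str = "potential"  # potential | known
    #: trace-in-flavour presence is discounted one level for this rule
    function_discount: bool = False

    def matches_name(self, name: str) -> bool:
        return re.search(self.name_pattern, name, flags=re.IGNORECASE) is not None


@dataclass(frozen=True)
class ExcipientFinding:
    excipient: str
    concern_level: str  # potential | known | adi_exceeded
    estimated_intake_mg_per_kg_day: Optional[float] = None
    adi_mg_per_kg_day: Optional[float] = None
    presence_based: bool = True
    rationale: str = ""


_ROUTE_BY_FORM = {
    DosageFormCategory.suppository: "rectal",
    DosageFormCategory.injection: "parenteral",
    DosageFormCategory.topical_semisolid: "topical",
}


def product_route(product: FormulationProduct) -> str:
    return _ROUTE_BY_FORM.get(product.dosage_form.category, "oral")


def load_registry(path: Union[str, Path]) -> list[ConcernRule]:
    """Load a concern registry CSV.

    Columns: ``name_pattern,route,min_age_months,max_age_months,
    adi_mg_per_kg_day,severity,function_discount`` (age and ADI cells may be
    empty).
    """
    rules: list[ConcernRule] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            restriction = None
            if row["min_age_months"].strip() or row["max_age_months"].strip():
                restriction = AgeRange(
                    min_months=int(row["min_age_months"] or 0),
                    max_months=int(row["max_age_months"] or MAX_AGE_MONTHS),
                )
            adi = float(row["adi_mg_per_kg_day"]) if row["adi_mg_per_kg_day"].strip() else None
            if adi is not None and adi <= 0:
                raise ValueError(f"{row['name_pattern']}: ADI must be > 0")
            rules.append(
                ConcernRule(
                    name_pattern=row["name_pattern"],
                    route=row["route"].strip() or "any",
                    population_restriction=restriction,
                    adi_mg_per_kg_day=adi,
                    severity=row["severity"].strip() or "potential",
                    function_discount=row["function_discount"].strip().lower()
                    in ("true", "1", "yes"),
                )
            )
    if not rules:
        raise ValueError("registry is empty")
    return rules


def default_registry() -> list[ConcernRule]:
    """The packaged registry of excipients of potential/known concern."""
    source = resources.files("pqtpp.data").joinpath("excipient_registry.csv")
    with resources.as_file(source) as path:
        return load_registry(path)


def daily_intake(
    entry: ExcipientEntry, doses_per_day: Union[float, Fraction], weight_kg: float
) -> float:
    """Total daily excipient intake in mg per kg body weight."""
    if entry.quantity_mg_per_unit is None:
        raise ValueError(f"{entry.name}: quantity_mg_per_unit unknown, not evaluable")
    if doses_per_day <= 0:
        raise ValueError("doses_per_day must be > 0")
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    return entry.quantity_mg_per_unit * float(doses_per_day) / weight_kg


def _worst_case_intake(
    product: FormulationProduct,
    entry: ExcipientEntry,
    population: AgeRange,
    growth: GrowthReference,
    config: ToolConfig,
) -> Optional[float]:
    """Highest daily intake per kg across the evaluated age grid."""
    worst = None
    for age in config.dose.age_grid_months:
        if not population.contains(age):
            continue
        weight = growth.median_weight(age)
        freq = sum(
            (float(r.frequency_per_day) for r in product.posology
             if r.age_window.contains(age)),
            0.0,
        )
        if freq <= 0:
            continue
        intake = daily_intake(entry, freq, weight)
        worst = intake if worst is None else max(worst, intake)
    return worst


def evaluate_excipients(
    product: FormulationProduct,
    registry: Optional[Sequence[ConcernRule]] = None,
    population: Optional[AgeRange] = None,
    growth: Optional[GrowthReference] = None,
    config: Optional[ToolConfig] = None,
) -> list[ExcipientFinding]:
    """Match each excipient against the concern registry.

    Returns one finding per excipient of concern; excipients that match no
    registry row (or whose rule's population restriction does not overlap
    the target population) produce no finding.
    """
    registry = list(registry) if registry is not None else default_registry()
    if not registry:
        raise ValueError("registry must be non-empty")
    config = config or DEFAULT_CONFIG
    growth = growth or default_growth_reference()
    population = population or AgeRange(
        min_months=product.condition_min_age_months, max_months=MAX_AGE_MONTHS
    )
    route = product_route(product)

    findings: list[ExcipientFinding] = []
    for entry in product.excipients:
        best: Optional[tuple[int, str, ConcernRule, Optional[float]]] = None
        for rule in registry:
            if not rule.matches_name(entry.name):
                continue
            if rule.route not in ("any", route):
                continue
            if rule.population_restriction is not None and not population.overlaps(
                rule.population_restriction
            ):
                continue
            level = rule.severity
            if (
                rule.function_discount
                and entry.concentration_class is ConcentrationClass.trace_in_flavour
                and level == "known"
            ):
                level = "potential"
            intake = None
            if entry.quantity_mg_per_unit is not None and rule.adi_mg_per_kg_day is not None:
                intake = _worst_case_intake(product, entry, population, growth, config)
                if intake is not None and intake > rule.adi_mg_per_kg_day:
                    level = "adi_exceeded"
            candidate = (_LEVEL_ORDER[level], level, rule, intake)
            if best is None or candidate[0] > best[0]:
                best = candidate
        if best is None:
            continue
        _, level, rule, intake = best
        notes = []
        if rule.population_restriction is not None:
            lo, hi = rule.population_restriction.min_months, rule.population_restriction.max_months
            notes.append(f"restricted for ages {lo}-{hi} months within the target population")
        if intake is not None:
            notes.append(
                f"worst-case intake {intake:.2f} mg/kg/day vs ADI "
                f"{rule.adi_mg_per_kg_day:g} mg/kg/day"
            )
        else:
            notes.append("presence-based (no quantitative composition)")
        findings.append(
            ExcipientFinding(
                excipient=entry.name,
                concern_level=level,
                estimated_intake_mg_per_kg_day=intake,
                adi_mg_per_kg_day=rule.adi_mg_per_kg_day,
                presence_based=intake is None,
                rationale="; ".join(notes),
            )
        )
    return findings
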