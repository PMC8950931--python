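"""Tool configuration: dose-evaluation grid, devices, and scoring thresholds.

All thresholds that quantify a qualitative rubric term ("several", "most of
the population", swallowable tablet size) live here so they are visible and
overridable, with defaults chosen to reproduce the published worked
evaluations.  Configs are frozen dataclasses; load overrides from YAML with
:meth:`ToolConfig.from_yaml`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import yaml

#: yearly ages 0-12 years plus 1, 3 and 6 months for neonatal/infant detail
DEFAULT_AGE_GRID = (0, 1, 3, 6, 12, 24, 36, 48, 60, 72, 84, 96, 108, 120, 132, 144)


@dataclass(frozen=True)
class DoseConfig:
    #: smallest oral-syringe graduation assumed available, mL
    device_resolution_ml: float = 0.1
    #: largest single oral-liquid dose considered administrable, mL
    max_volume_ml: float = 25.0
    #: tablets/capsules a patient can be asked to take per dose
    max_units_per_dose: int = 4
    #: suppositories per dose (multiple insertions are tolerated but limited)
    max_units_suppository: int = 3
    age_grid_months: tuple[int, ...] = DEFAULT_AGE_GRID


@dataclass(frozen=True)
class ScoringConfig:
    #: "several excipients of concern" lower bound (red band starts here)
    several_excipients_min: int = 3
    #: month-coverage fraction counting as "most of" the target population
    population_coverage_half: float = 0.5
    #: month-coverage fraction counting as full coverage (a licence floor of
    #: a few months still reads as "suitable for the whole population")
    population_coverage_full: float = 0.95
    #: age from which children are assumed able to swallow tablets, months
    tablet_swallow_age_months: int = 72
    #: largest solid-form dimension swallowable by 6-12 year olds, mm
    swallowable_max_mm: float = 10.0
    #: oral-liquid volume per dose above which acceptability suffers, mL
    high_volume_threshold_ml: float = 10.0
    #: doses/day above which chronic regimens are penalised for acceptability
    frequent_doses_per_day: float = 3.0


@dataclass(frozen=True)
class ToolConfig:
    dose: DoseConfig = DoseConfig()
    scoring: ScoringConfig = ScoringConfig()
    #: CSV (age_months,median_weight_kg) overriding the packaged growth table
    growth_reference_path: Optional[str] = None
    #: CSV overriding the packaged excipient-concern registry
    registry_path: Optional[str] = None
    #: CSV overriding the packaged acceptability base lookup
    acceptability_table_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ToolConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file root must be a mapping")
        dose = DoseConfig(**{**_as_dict(raw.get("dose", {})), })
        scoring = ScoringConfig(**_as_dict(raw.get("scoring", {})))
        top = {
            k: raw[k]
            for k in ("growth_reference_path", "registry_path", "acceptability_table_path")
            if k in raw
        }
        return cls(dose=dose, scoring=scoring, **top)

    def replace(self, **kwargs) -> "ToolConfig":
        return dataclasses.replace(self, **kwargs)


def _as_dict(section: object) -> dict:
    if not isinstance(section, dict):
        raise ValueError("config sections must be mappings")
    if "age_grid_months" in section:
        section = dict(section)
        section["age_grid_months"] = tuple(section["age_grid_months"])
    return section


DEFAULT_CONFIG = ToolConfig()
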