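"""Median weight-for-age reference used to turn mg/kg posology into doses.

The packaged table holds sex-averaged 50th-centile weights at knot ages from
birth to 144 months, approximating the public WHO weight-for-age charts.
Between knots the weight is linearly interpolated; the tool must run offline
so the table ships as versioned CSV package data and can be overridden via
``ToolConfig.growth_reference_path``.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

from .model import MAX_AGE_MONTHS

__all__ = ["GrowthReference", "default_growth_reference"]


class GrowthReference:
    """Ordered (age_months, median_weight_kg) pairs spanning 0-144 months."""

    def __init__(self, ages: Sequence[float], weights: Sequence[float]):
        if len(ages) != len(weights) or len(ages) < 2:
            raise ValueError("need >= 2 (age, weight) pairs of equal length")
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if any(w <= 0 for w in weights):
            raise ValueError("weights must be strictly positive")
        if any(b < a for a, b in zip(weights, weights[1:])):
            raise ValueError("median weights must be non-decreasing with age")
        self.ages = tuple(float(a) for a in ages)
        self.weights = tuple(float(w) for w in weights)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GrowthReference":
        ages, weights = [], []
        with open(path, newline="", encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                ages.append(float(row["age_months"]))
                weights.append(float(row["median_weight_kg"]))
        return cls(ages, weights)

    def median_weight(self, age_months: float) -> float:
        """Median weight in kg at ``age_months``; linear between table rows."""
        if not self.ages[0] <= age_months <= self.ages[-1]:
            raise ValueError(
                f"age {age_months} months outside reference range "
                f"[{self.ages[0]:g}, {self.ages[-1]:g}]"
            )
        idx = bisect_right(self.ages, age_months)
        if idx == len(self.ages):
            return self.weights[-1]
        if self.ages[idx - 1] == age_months:
            return self.weights[idx - 1]
        a0, a1 = self.ages[idx - 1], self.ages[idx]
        w0, w1 = self.weights[idx - 1], self.weights[idx]
        return w0 + (w1 - w0) * (age_months - a0) / (a1 - a0)


def default_growth_reference() -> GrowthReference:
    """The packaged sex-averaged median weight-for-age table (0-144 months)."""
    source = resources.files("pqtpp.data").joinpath("growth_reference.csv")
    with resources.as_file(source) as path:
        ref = GrowthReference.from_csv(path)
    if ref.ages[0] != 0 or ref.ages[-1] != MAX_AGE_MONTHS:
        raise RuntimeError("packaged growth reference must span 0-144 months")
    return ref
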