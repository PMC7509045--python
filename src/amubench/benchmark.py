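"""Percentile benchmarking: flag the top-usage farms within an age category.

Farms are ranked descending on one normalized indicator; the top
``round_half_up(fraction × n)`` farms are classified as high usage.  Ties
straddling the cut are all included and flagged, so the classification never
depends on input order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ddd_catalog import AgeCategory
from .errors import DomainError
from .indicators import NORMALIZED_INDICATORS, IndicatorTable


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero (for x >= 0).

    Float noise within 1e-9 of an integer is snapped first, so e.g.
    ``0.05 * 360`` lands on 18 rather than drifting across the half."""
    nearest = round(x)
    if abs(x - nearest) < 1e-9:
        return int(nearest)
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class BenchmarkClassification:
    """High/low usage labels for every farm of one category at one cut."""

    age_category: AgeCategory
    fraction: float
    indicator: str
    high_farms: frozenset[str]
    all_farms: frozenset[str]
    threshold_value: float | None
    tie_flag: bool = False

    @property
    def n_farms(self) -> int:
        return len(self.all_farms)

    def is_high(self, farm_id: str) -> bool:
        if farm_id not in self.all_farms:
            raise DomainError(f"farm {farm_id!r} not part of this classification")
        return farm_id in self.high_farms

    def labels(self) -> dict[str, bool]:
        return {farm: farm in self.high_farms for farm in sorted(self.all_farms)}


def classify_high_usage(
    table: IndicatorTable,
    category: AgeCategory,
    indicator: str,
    fraction: float,
) -> BenchmarkClassification:
    """Classify farms of one category as high usage at a percentile cut.

    ``indicator`` is ``"ati"`` or ``"nddd_per_animal_year"``; ``fraction`` is
    the benchmark share in (0, 1), e.g. 0.05, 0.10, 0.25.  All farms whose
    value ties the farm at the cut are included, with ``tie_flag`` set when
    that inflates the high group beyond the target count.
    """
    if indicator not in NORMALIZED_INDICATORS:
        raise DomainError(
            f"unknown indicator {indicator!r}; expected one of {NORMALIZED_INDICATORS}"
        )
    if not 0 < fraction < 1:
        raise DomainError(f"fraction must be in (0, 1), got {fraction}")

    values = table.category_values(category, indicator)
    n = len(values)
    if n < 2:
        raise DomainError(
            f"need at least 2 farms in category {category.value}, got {n}"
        )

    target = round_half_up(fraction * n)
    all_farms = frozenset(values.index)
    if target == 0:
        return BenchmarkClassification(
            age_category=category,
            fraction=fraction,
            indicator=indicator,
            high_farms=frozenset(),
            all_farms=all_farms,
            threshold_value=None,
            tie_flag=False,
        )

    ordered = values.sort_values(ascending=False, kind="mergesort")
    threshold = float(ordered.iloc[target - 1])
    high = frozenset(values.index[values >= threshold])
    return BenchmarkClassification(
        age_category=category,
        fraction=fraction,
        indicator=indicator,
        high_farms=high,
        all_farms=all_farms,
        threshold_value=threshold,
        tie_flag=len(high) > target,
    )
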