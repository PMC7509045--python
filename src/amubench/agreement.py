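"""Concordance between the two usage indicators.

Percent agreement and Cohen's Kappa compare the high/low classifications the
two indicators produce at a percentile cut; Spearman's Rho compares the
continuous per-farm values; Bland–Altman analysis summarizes per-farm
differences (ATI − nDDD/animal/year) against their means, with outliers
outside mean ± 1.96 × SD of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import BenchmarkClassification, classify_high_usage
from .ddd_catalog import AgeCategory
from .errors import DomainError
from .indicators import IndicatorTable


class KappaResult(NamedTuple):
    """Cohen's Kappa plus a flag for the degenerate constant-rater case."""

    value: float
    degenerate: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


def _check_comparable(c1: BenchmarkClassification, c2: BenchmarkClassification) -> list[str]:
    if c1.all_farms != c2.all_farms:
        raise DomainError("classifications cover different farm sets")
    if c1.age_category is not c2.age_category or c1.fraction != c2.fraction:
        raise DomainError("classifications differ in category or fraction")
    return sorted(c1.all_farms)


def percent_agreement(c1: BenchmarkClassification, c2: BenchmarkClassification) -> float:
    """Share of farms (in percent) given the same high/low label by both."""
    farms = _check_comparable(c1, c2)
    matching = sum((f in c1.high_farms) == (f in c2.high_farms) for f in farms)
    return 100.0 * matching / len(farms)


def kappa_from_table(n11: int, n10: int, n01: int, n00: int) -> KappaResult:
    """Cohen's Kappa from 2×2 counts (both-high, 1-only, 2-only, both-low).

    When both raters are constant the chance-agreement term makes the formula
    0/0; by convention this returns 1 for perfect agreement and 0 otherwise,
    flagged as degenerate.
    """
    n = n11 + n10 + n01 + n00
    if n == 0:
        raise DomainError("empty 2x2 table")
    po = (n11 + n00) / n
    p1 = (n11 + n10) / n
    p2 = (n11 + n01) / n
    pe = p1 * p2 + (1 - p1) * (1 - p2)
    if pe == 1.0:
        return KappaResult(1.0 if po == 1.0 else 0.0, True)
    return KappaResult((po - pe) / (1 - pe), False)


def cohen_kappa(c1: BenchmarkClassification, c2: BenchmarkClassification) -> KappaResult:
    """Chance-corrected agreement between two high-usage classifications."""
    farms = _check_comparable(c1, c2)
    n11 = n10 = n01 = n00 = 0
    for f in farms:
        h1, h2 = f in c1.high_farms, f in c2.high_farms
        if h1 and h2:
            n11 += 1
        elif h1:
            n10 += 1
        elif h2:
            n01 += 1
        else:
            n00 += 1
    return kappa_from_table(n11, n10, n01, n00)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN (the flagged missing value) when either vector is constant,
    for which the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be paired 1-d vectors")
    if len(x) < 3:
        raise DomainError(f"need at least 3 pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Per-farm means/differences of two paired measurements plus the
    mean ± 1.96·SD limits of agreement and the farms outside them."""

    farm_ids: tuple[str, ...]
    means: np.ndarray
    diffs: np.ndarray
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    outliers: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.farm_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "farm_id": self.farm_ids,
                "mean": self.means,
                "diff": self.diffs,
                "is_outlier": [f in self.outliers for f in self.farm_ids],
            }
        )


def bland_altman(
    x: Sequence[float],
    y: Sequence[float],
    farm_ids: Sequence[str] | None = None,
) -> BlandAltmanResult:
    """Bland–Altman analysis of paired values; differences are ``x − y``.

    ``sd_diff`` is the sample standard deviation (n−1 denominator); limits
    are ``mean_diff ± 1.96 × sd_diff``; outliers are the farms whose
    difference falls strictly outside the limits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 3:
        raise DomainError(f"need at least 3 pairs, got {n}")
    if farm_ids is None:
        farm_ids = tuple(str(i) for i in range(n))
    else:
        farm_ids = tuple(str(f) for f in farm_ids)
        if len(farm_ids) != n:
            raise DomainError("farm_ids length mismatch")

    diffs = x - y
    means = (x + y) / 2.0
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))
    lower = mean_diff - 1.96 * sd_diff
    upper = mean_diff + 1.96 * sd_diff
    outside = (diffs < lower) | (diffs > upper)
    return BlandAltmanResult(
        farm_ids=farm_ids,
        means=means,
        diffs=diffs,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        lower_limit=lower,
        upper_limit=upper,
        outliers=frozenset(f for f, o in zip(farm_ids, outside) if o),
    )


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between the indicators for one category at one cut."""

    age_category: AgeCategory
    fraction: float
    n_farms: int
    percent_agreement: float
    kappa: float
    degenerate: bool
    rho: float


def normality_gate(values: Sequence[float]) -> tuple[float, bool]:
    """Advisory Shapiro–Wilk check: (p-value, looks_normal at alpha 0.05).

    The pipeline reports rank-based statistics regardless of the outcome;
    this only annotates the run log."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3 or np.ptp(values) == 0:
        return float("nan"), False
    stat = stats.shapiro(values)
    return float(stat.pvalue), bool(stat.pvalue > 0.05)


def agreement_suite(
    table: IndicatorTable,
    fractions: Sequence[float] = (0.05, 0.10, 0.25),
) -> tuple[list[AgreementReport], dict[AgeCategory, BlandAltmanResult]]:
    """Full indicator-concordance analysis per age category.

    For every category present in the table: classify high-usage farms under
    ATI and nDDD/animal/year at each fraction, compute percent agreement and
    Kappa; once per category compute Spearman's Rho on the continuous values
    and the Bland–Altman summary of per-farm ATI − nDDD/animal/year
    differences.  Output order is deterministic: categories alphabetically,
    fractions as given.
    """
    reports: list[AgreementReport] = []
    bland: dict[AgeCategory, BlandAltmanResult] = {}
    for category in table.categories():
        ati = table.category_values(category, "ati")
        nddd = table.category_values(category, "nddd_per_animal_year")
        if len(ati) < 2:
            continue
        rho = spearman_rho(ati.values, nddd.values) if len(ati) >= 3 else float("nan")
        if len(ati) >= 3:
            bland[category] = bland_altman(ati.values, nddd.values, farm_ids=ati.index)
        for fraction in fractions:
            c_ati = classify_high_usage(table, category, "ati", fraction)
            c_nddd = classify_high_usage(table, category, "nddd_per_animal_year", fraction)
            kappa = cohen_kappa(c_ati, c_nddd)
            reports.append(
                AgreementReport(
                    age_category=category,
                    fraction=fraction,
                    n_farms=c_ati.n_farms,
                    percent_agreement=percent_agreement(c_ati, c_nddd),
                    kappa=kappa.value,
                    degenerate=kappa.degenerate,
                    rho=rho,
                )
            )
    return reports, bland


def agreement_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_category": [r.age_category.value for r in reports],
            "fraction": [r.fraction for r in reports],
            "n_farms": [r.n_farms for r in reports],
            "percent_agreement": [r.percent_agreement for r in reports],
            "kappa": [r.kappa for r in reports],
            "degenerate_flag": [r.degenerate for r in reports],
        }
    )


def correlation_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    seen: dict[str, tuple[int, float]] = {}
    for r in reports:
        seen.setdefault(r.age_category.value, (r.n_farms, r.rho))
    cats = sorted(seen)
    return pd.DataFrame(
        {
            "age_category": cats,
            "n_farms": [seen[c][0] for c in cats],
            "rho": [seen[c][1] for c in cats],
        }
    )
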