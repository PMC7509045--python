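"""Farm-level usage indicators: NT, ATI, nDDD, and nDDD/animal/year.

One treatment is one application to one animal on one day, counted once per
active agent, so a record contributes ``n_animals × n_days`` treatments per
substance.  The dose count for a substance is the administered mass divided
by ``ddd × standard weight``; both measures are normalized by the yearly
animal denominator from the census to yield ATI and nDDD/animal/year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ddd_catalog import AgeCategory, DDDCatalog, standard_weight
from .errors import DomainError, ValidationError
from .journal import FarmCensus, TreatmentRecord

#: Sentinel substance-class label for the per-(farm, category) sum row.
TOTAL = "TOTAL"

INDICATOR_COLUMNS = (
    "farm_id",
    "age_category",
    "substance_class",
    "nt",
    "ati",
    "nddd",
    "nddd_per_animal_year",
)

#: Labels accepted wherever a normalized indicator must be named.
NORMALIZED_INDICATORS = ("ati", "nddd_per_animal_year")


def count_treatments(
    rec: TreatmentRecord,
    catalog: DDDCatalog | None = None,
    *,
    use_long_acting: bool = False,
) -> float:
    """Number of treatments for one record: ``n_animals × n_days`` per agent.

    With ``use_long_acting=True`` (off by default) each substance's day count
    is scaled by its catalog long-acting factor, adjusting the effective
    treatment duration of depot products; a catalog is then required.
    """
    base = rec.n_animals * rec.n_days
    if not use_long_acting:
        return float(base * len(rec.substances))
    if catalog is None:
        raise DomainError("use_long_acting requires a catalog")
    return float(
        sum(base * catalog.get(substance).long_acting_factor for substance, _ in rec.substances)
    )


def count_nddd(rec: TreatmentRecord, catalog: DDDCatalog) -> dict[str, float]:
    """Defined daily doses per substance: ``amount_mg / (ddd × SW)``."""
    sw = standard_weight(rec.age_category)
    out: dict[str, float] = {}
    for substance, amount in rec.substances:
        ddd = catalog.ddd(substance)  # raises DomainError for unknown substances
        out[substance] = out.get(substance, 0.0) + amount / (ddd * sw)
    return out


@dataclass
class IndicatorTable:
    """Per (farm, age category, substance class) indicator values.

    ``frame`` has the columns of ``INDICATOR_COLUMNS``; every censused
    (farm, category) pair carries a TOTAL row (zero for farms without usage,
    so zero-usage farms enter percentile rankings), plus one row per
    substance class with non-zero usage.  Rows are sorted by farm, category,
    class, with TOTAL last within each group.
    """

    frame: pd.DataFrame

    def total_rows(self) -> pd.DataFrame:
        return self.frame[self.frame["substance_class"] == TOTAL]

    def class_rows(self) -> pd.DataFrame:
        return self.frame[self.frame["substance_class"] != TOTAL]

    def categories(self) -> list[AgeCategory]:
        return sorted(
            {AgeCategory(c) for c in self.frame["age_category"].unique()},
            key=lambda c: c.value,
        )

    def category_values(self, category: AgeCategory, indicator: str) -> pd.Series:
        """Per-farm TOTAL values of one indicator within one category,
        indexed by farm_id."""
        if indicator not in ("nt", "nddd", *NORMALIZED_INDICATORS):
            raise DomainError(f"unknown indicator {indicator!r}")
        rows = self.total_rows()
        rows = rows[rows["age_category"] == category.value]
        return rows.set_index("farm_id")[indicator].sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndicatorTable":
        frame = pd.read_csv(
            path, dtype={"farm_id": str, "age_category": str, "substance_class": str}
        )
        missing = set(INDICATOR_COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"indicator table {path}: missing columns {sorted(missing)}")
        return cls(frame)


def aggregate(
    records: Sequence[TreatmentRecord],
    census: FarmCensus,
    catalog: DDDCatalog,
    *,
    use_long_acting: bool = False,
    year_fraction: float = 1.0,
) -> IndicatorTable:
    """Aggregate validated records into the per-farm indicator table.

    Every (farm, category) in ``records`` must have a census denominator;
    otherwise a :class:`DomainError` lists the offending pairs.  For study
    windows shorter than a year, ``year_fraction`` scales the denominator
    proportionally (1.0 reproduces the yearly definition).
    """
    if not 0 < year_fraction <= 1:
        raise DomainError(f"year_fraction must be in (0, 1], got {year_fraction}")

    missing = sorted(
        {
            (r.farm_id, r.age_category.value)
            for r in records
            if (r.farm_id, r.age_category) not in census
        }
    )
    if missing:
        raise DomainError(
            "records reference (farm, category) pairs absent from census: "
            + ", ".join(f"{f}/{c}" for f, c in missing)
        )

    # (farm, category, class) -> [nt, nddd]
    sums: dict[tuple[str, AgeCategory, str], list[float]] = {}
    for rec in records:
        base_nt = rec.n_animals * rec.n_days
        doses = count_nddd(rec, catalog)
        for substance, _ in rec.substances:
            entry = catalog.get(substance)
            nt = base_nt * (entry.long_acting_factor if use_long_acting else 1.0)
            key = (rec.farm_id, rec.age_category, entry.substance_class)
            cell = sums.setdefault(key, [0.0, 0.0])
            cell[0] += nt
        for substance, nddd in doses.items():
            key = (rec.farm_id, rec.age_category, catalog.substance_class(substance))
            sums.setdefault(key, [0.0, 0.0])[1] += nddd

    rows: list[dict] = []
    for farm, cat in census.keys():
        denom = census.animals_per_year(farm, cat) * year_fraction
        class_keys = sorted(
            cls for (f, c, cls) in sums if f == farm and c is cat
        )
        total_nt = total_nddd = 0.0
        for cls in class_keys:
            nt, nddd = sums[(farm, cat, cls)]
            total_nt += nt
            total_nddd += nddd
            rows.append(_row(farm, cat, cls, nt, nddd, denom))
        rows.append(_row(farm, cat, TOTAL, total_nt, total_nddd, denom))

    frame = pd.DataFrame(rows, columns=list(INDICATOR_COLUMNS))
    return IndicatorTable(frame)


def _row(farm: str, cat: AgeCategory, cls: str, nt: float, nddd: float, denom: float) -> dict:
    return {
        "farm_id": farm,
        "age_category": cat.value,
        "substance_class": cls,
        "nt": nt,
        "ati": nt / denom,
        "nddd": nddd,
        "nddd_per_animal_year": nddd / denom,
    }
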