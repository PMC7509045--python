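"""Dose-standardization constants: DDD catalog, age categories, standard weights.

The catalog maps each active substance to its defined daily dose (mg per kg
body weight per day) and an antimicrobial-class label.  Age categories carry
the fixed standard weight used to convert administered mass into dose counts,
and the kind of yearly denominator (animals housed vs. produced) used to
normalize farm-level indicators.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import DomainError, SchemaError, ValidationError


class AgeCategory(enum.Enum):
    """The five production age categories."""

    SUCKLING_PIGLET = "suckling_piglet"
    WEANED_PIGLET = "weaned_piglet"
    FATTENING_PIG = "fattening_pig"
    LACTATING_SOW = "lactating_sow"
    GESTATING_SOW = "gestating_sow"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, name: str) -> "AgeCategory":
        try:
            return cls(name.strip().lower())
        except ValueError:
            valid = ", ".join(c.value for c in cls)
            raise DomainError(f"unknown age category {name!r}; expected one of: {valid}") from None

    @property
    def denominator_kind(self) -> str:
        """'housed' for sow categories, 'produced' for the growing categories."""
        if self in (AgeCategory.LACTATING_SOW, AgeCategory.GESTATING_SOW):
            return "housed"
        return "produced"


#: Fixed assumed body weight (kg) at treatment, per age category.
STANDARD_WEIGHTS_KG: Mapping[AgeCategory, float] = {
    AgeCategory.SUCKLING_PIGLET: 4.0,
    AgeCategory.WEANED_PIGLET: 12.0,
    AgeCategory.FATTENING_PIG: 50.0,
    AgeCategory.LACTATING_SOW: 220.0,
    AgeCategory.GESTATING_SOW: 220.0,
}

#: Default antimicrobial-class taxonomy for substance-class rollups.
DEFAULT_CLASSES = (
    "aminoglycosides",
    "cephalosporins",
    "fluoroquinolones",
    "macrolides",
    "penicillins",
    "pleuromutilins",
    "polypeptides",
    "sulfonamides",
    "tetracyclines",
    "trimethoprim",
)


def standard_weight(cat: AgeCategory) -> float:
    """Return the fixed standard weight (kg) for an age category."""
    if not isinstance(cat, AgeCategory):
        raise DomainError(f"not an age category: {cat!r}")
    return STANDARD_WEIGHTS_KG[cat]


def normalize_substance(name: str) -> str:
    """Canonical substance key: lower-cased, whitespace-trimmed."""
    return name.strip().lower()


@dataclass(frozen=True)
class DDDEntry:
    """Catalog row for one active substance."""

    ddd_mg_per_kg: float
    substance_class: str
    long_acting_factor: float = 1.0


@dataclass
class DDDCatalog:
    """Validated map from active substance to its DDD entry.

    Substance keys are normalized (see :func:`normalize_substance`); lookups
    normalize their argument, so journal and catalog spellings only need to
    match up to case and surrounding whitespace.
    """

    entries: dict[str, DDDEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        normalized: dict[str, DDDEntry] = {}
        for name, entry in self.entries.items():
            key = normalize_substance(name)
            if key in normalized:
                raise ValidationError(f"duplicate substance in catalog: {key!r}")
            if not entry.ddd_mg_per_kg > 0:
                raise ValidationError(
                    f"ddd must be > 0 for substance {key!r}, got {entry.ddd_mg_per_kg}"
                )
            if entry.long_acting_factor <= 0:
                raise ValidationError(
                    f"long_acting_factor must be > 0 for substance {key!r}"
                )
            normalized[key] = entry
        self.entries = normalized

    def __contains__(self, substance: str) -> bool:
        return normalize_substance(substance) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, substance: str) -> DDDEntry:
        key = normalize_substance(substance)
        try:
            return self.entries[key]
        except KeyError:
            raise DomainError(f"substance not in catalog: {key!r}") from None

    def ddd(self, substance: str) -> float:
        return self.get(substance).ddd_mg_per_kg

    def substance_class(self, substance: str) -> str:
        return self.get(substance).substance_class

    def substances(self) -> list[str]:
        return sorted(self.entries)

    def classes(self) -> list[str]:
        return sorted({e.substance_class for e in self.entries.values()})

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CATALOG_COLUMNS)
            for name in self.substances():
                e = self.entries[name]
                writer.writerow(
                    [name, repr(e.ddd_mg_per_kg), e.substance_class, repr(e.long_acting_factor)]
                )


CATALOG_COLUMNS = ("substance", "ddd_mg_per_kg", "substance_class", "long_acting_factor")


def load_catalog(path: str | Path) -> DDDCatalog:
    """Load and validate a DDD catalog CSV.

    Expected header: ``substance,ddd_mg_per_kg,substance_class,long_acting_factor``;
    the last column is optional and defaults to 1 when absent or blank.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        required = set(CATALOG_COLUMNS[:3])
        missing = required - set(header)
        if missing:
            raise SchemaError(
                f"catalog {path}: missing column(s) {sorted(missing)}; header was {header}"
            )
        entries: dict[str, DDDEntry] = {}
        for i, row in enumerate(reader):
            name = normalize_substance(row["substance"])
            if not name:
                raise ValidationError(f"catalog {path}: empty substance name at data row {i}")
            if name in entries:
                raise ValidationError(f"catalog {path}: duplicate substance {name!r}")
            try:
                ddd = float(row["ddd_mg_per_kg"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"catalog {path}: non-numeric ddd for {name!r}: {row['ddd_mg_per_kg']!r}"
                ) from None
            raw_factor = (row.get("long_acting_factor") or "").strip()
            factor = float(raw_factor) if raw_factor else 1.0
            entries[name] = DDDEntry(
                ddd_mg_per_kg=ddd,
                substance_class=row["substance_class"].strip(),
                long_acting_factor=factor,
            )
    return DDDCatalog(entries)


def make_catalog(rows: Iterable[tuple[str, float, str]]) -> DDDCatalog:
    """Build a catalog from ``(substance, ddd, substance_class)`` triples."""
    return DDDCatalog({name: DDDEntry(ddd, cls) for name, ddd, cls in rows})
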