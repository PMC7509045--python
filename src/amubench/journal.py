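"""Treatment-journal and census ingestion, validation, and inclusion filters.

A journal row describes one (event, substance) pair; rows sharing an
``event_id`` are merged into a single multi-substance treatment record so
that combination products can later be counted per agent.  Filters implement
the study inclusion rules: timely journal entry (default: within 7 days of
application), a study window, continuous recording, and plausibility caps
that catch records that are clearly data-entry errors.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .ddd_catalog import AgeCategory, DDDCatalog, standard_weight
from .errors import JournalParseError, SchemaError, ValidationError

JOURNAL_COLUMNS = (
    "event_id",
    "farm_id",
    "age_category",
    "substance",
    "amount_mg",
    "n_animals",
    "n_days",
    "application_date",
    "entry_date",
)

CENSUS_COLUMNS = ("farm_id", "age_category", "animals_per_year", "continuous_recording")


@dataclass(frozen=True)
class TreatmentRecord:
    """One treatment event: a group of animals treated with one product."""

    event_id: str
    farm_id: str
    age_category: AgeCategory
    substances: tuple[tuple[str, float], ...]  # (substance, total amount in mg)
    n_animals: int
    n_days: int
    application_date: dt.date
    entry_date: dt.date

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValidationError(f"event {self.event_id}: n_animals must be >= 1")
        if self.n_days < 1:
            raise ValidationError(f"event {self.event_id}: n_days must be >= 1")
        if not self.substances:
            raise ValidationError(f"event {self.event_id}: at least one substance required")
        for name, amount in self.substances:
            if not amount > 0:
                raise ValidationError(
                    f"event {self.event_id}: amount for {name!r} must be > 0, got {amount}"
                )
        if self.entry_date < self.application_date:
            raise ValidationError(
                f"event {self.event_id}: entry_date precedes application_date"
            )

    @property
    def entry_lag_days(self) -> int:
        return (self.entry_date - self.application_date).days


@dataclass
class FarmCensus:
    """Yearly animal denominators per (farm, age category).

    Counts are animals housed (sows) or produced (piglets, fatteners) per
    year.  ``continuous`` flags whether the farm recorded treatments for the
    whole study window in that category.
    """

    counts: dict[tuple[str, AgeCategory], int] = field(default_factory=dict)
    continuous: dict[tuple[str, AgeCategory], bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, n in self.counts.items():
            if n < 1:
                raise ValidationError(f"census count for {key} must be >= 1, got {n}")
            self.continuous.setdefault(key, True)

    def __contains__(self, key: tuple[str, AgeCategory]) -> bool:
        return key in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def animals_per_year(self, farm_id: str, category: AgeCategory) -> int:
        return self.counts[(farm_id, category)]

    def is_continuous(self, farm_id: str, category: AgeCategory) -> bool:
        return self.continuous.get((farm_id, category), False)

    def keys(self) -> list[tuple[str, AgeCategory]]:
        return sorted(self.counts, key=lambda k: (k[0], k[1].value))

    def farms(self, category: AgeCategory) -> list[str]:
        return sorted(f for f, c in self.counts if c is category)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CENSUS_COLUMNS)
            for farm, cat in self.keys():
                writer.writerow(
                    [
                        farm,
                        cat.value,
                        self.counts[(farm, cat)],
                        str(self.continuous[(farm, cat)]).lower(),
                    ]
                )


@dataclass
class ValidationReport:
    """Bookkeeping for one filter stage: input = kept + rejected."""

    n_input: int
    n_kept: int
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_input != self.n_kept + len(self.rejected):
            raise ValidationError(
                f"inconsistent report: {self.n_input} != {self.n_kept} + {len(self.rejected)}"
            )

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rejected:
            out[reason] = out.get(reason, 0) + 1
        return out


def _parse_date(text: str, what: str) -> dt.date:
    try:
        return dt.date.fromisoformat(text.strip())
    except ValueError:
        raise ValueError(f"malformed {what} {text!r} (expected ISO-8601)") from None


def _parse_positive_int(text: str, what: str) -> int:
    try:
        value = int(text)
    except (TypeError, ValueError):
        raise ValueError(f"non-integer {what}: {text!r}") from None
    if value < 1:
        raise ValueError(f"{what} must be >= 1, got {value}")
    return value


def load_journal(
    path: str | Path, *, collect_errors: bool = False
) -> list[TreatmentRecord] | tuple[list[TreatmentRecord], list[tuple[int, str]]]:
    """Parse a treatment-journal CSV into merged treatment records.

    Rows sharing an ``event_id`` are merged into one record carrying one
    substance entry per row; all non-substance fields of merged rows must
    agree.  Malformed rows are collected and reported together: by default a
    :class:`~amubench.errors.JournalParseError` listing every bad row is
    raised; with ``collect_errors=True`` the tuple ``(records, row_errors)``
    is returned instead and bad rows are excluded (never silently dropped —
    they are enumerated in the second element).
    """
    path = Path(path)
    row_errors: list[tuple[int, str]] = []
    # event_id -> (fields tuple, [(substance, amount), ...], first row index)
    events: dict[str, tuple[tuple, list[tuple[str, float]], int]] = {}
    order: list[str] = []

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = set(JOURNAL_COLUMNS) - set(header)
        if missing:
            raise SchemaError(
                f"journal {path}: missing column(s) {sorted(missing)}; header was {header}"
            )
        for i, row in enumerate(reader):
            try:
                event_id = row["event_id"].strip()
                if not event_id:
                    raise ValueError("empty event_id")
                fields = (
                    row["farm_id"].strip(),
                    AgeCategory.parse(row["age_category"]),
                    _parse_positive_int(row["n_animals"], "n_animals"),
                    _parse_positive_int(row["n_days"], "n_days"),
                    _parse_date(row["application_date"], "application_date"),
                    _parse_date(row["entry_date"], "entry_date"),
                )
                amount = float(row["amount_mg"])
                if not amount > 0:
                    raise ValueError(f"amount_mg must be > 0, got {amount}")
                substance = row["substance"].strip()
                if not substance:
                    raise ValueError("empty substance")
            except Exception as exc:
                row_errors.append((i, str(exc)))
                continue
            if event_id in events:
                known_fields, substances, first_row = events[event_id]
                if known_fields != fields:
                    row_errors.append(
                        (i, f"event {event_id}: fields differ from row {first_row}")
                    )
                    continue
                substances.append((substance, amount))
            else:
                events[event_id] = (fields, [(substance, amount)], i)
                order.append(event_id)

    records: list[TreatmentRecord] = []
    for event_id in order:
        (farm, cat, n_animals, n_days, app, entry), substances, first_row = events[event_id]
        try:
            records.append(
                TreatmentRecord(
                    event_id=event_id,
                    farm_id=farm,
                    age_category=cat,
                    substances=tuple(substances),
                    n_animals=n_animals,
                    n_days=n_days,
                    application_date=app,
                    entry_date=entry,
                )
            )
        except ValidationError as exc:
            row_errors.append((first_row, str(exc)))

    if collect_errors:
        return records, row_errors
    if row_errors:
        raise JournalParseError(row_errors)
    return records


def load_census(path: str | Path) -> FarmCensus:
    """Load and validate the farm-census CSV."""
    path = Path(path)
    counts: dict[tuple[str, AgeCategory], int] = {}
    continuous: dict[tuple[str, AgeCategory], bool] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = set(CENSUS_COLUMNS[:3]) - set(header)
        if missing:
            raise SchemaError(
                f"census {path}: missing column(s) {sorted(missing)}; header was {header}"
            )
        for i, row in enumerate(reader):
            farm = row["farm_id"].strip()
            cat = AgeCategory.parse(row["age_category"])
            key = (farm, cat)
            if key in counts:
                raise ValidationError(
                    f"census {path}: duplicate entry for farm {farm!r}, category {cat.value}"
                )
            try:
                n = int(row["animals_per_year"])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"census {path}: non-integer count at data row {i}"
                ) from None
            if n < 1:
                raise ValidationError(
                    f"census {path}: count must be >= 1 for farm {farm!r} "
                    f"({cat.value}), got {n}"
                )
            counts[key] = n
            raw_flag = (row.get("continuous_recording") or "true").strip().lower()
            continuous[key] = raw_flag in ("true", "1", "yes")
    return FarmCensus(counts=counts, continuous=continuous)


def _run_filter(records, predicate) -> tuple[list[TreatmentRecord], ValidationReport]:
    kept: list[TreatmentRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, rec in enumerate(records):
        reason = predicate(rec)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((i, reason))
    return kept, ValidationReport(n_input=len(records), n_kept=len(kept), rejected=rejected)


def apply_entry_lag_filter(
    records: Sequence[TreatmentRecord], max_lag_days: int = 7
) -> tuple[list[TreatmentRecord], ValidationReport]:
    """Reject records entered more than ``max_lag_days`` after application.

    A lag of exactly ``max_lag_days`` is still accepted (inclusion rule:
    entered no later than N days after application).
    """
    return _run_filter(
        records, lambda r: "entry_lag" if r.entry_lag_days > max_lag_days else None
    )


def apply_window_filter(
    records: Sequence[TreatmentRecord], start: dt.date, end: dt.date
) -> tuple[list[TreatmentRecord], ValidationReport]:
    """Reject records applied outside the study window [start, end]."""
    return _run_filter(
        records,
        lambda r: None if start <= r.application_date <= end else "out_of_window",
    )


def apply_continuity_filter(
    records: Sequence[TreatmentRecord], census: FarmCensus
) -> tuple[list[TreatmentRecord], ValidationReport]:
    """Keep only records whose (farm, category) is censused and flagged as
    continuously recording for the study window."""

    def predicate(rec: TreatmentRecord) -> str | None:
        key = (rec.farm_id, rec.age_category)
        if key not in census:
            return "not_censused"
        if not census.is_continuous(rec.farm_id, rec.age_category):
            return "not_continuous"
        return None

    return _run_filter(records, predicate)


@dataclass(frozen=True)
class PlausibilityRules:
    """Numeric caps that flag records clearly identified as entry errors.

    ``max_dose_multiple`` caps the implied per-animal-per-day dose at that
    multiple of ``ddd × standard weight``; it is only enforced when a catalog
    is supplied.  Defaults are deliberately loose: an order of magnitude
    beyond any plausible licensed dosing, so only gross errors are caught.
    """

    max_animals: int = 20_000
    max_days: int = 365
    max_dose_multiple: float = 10.0


def apply_plausibility_filter(
    records: Sequence[TreatmentRecord],
    rules: PlausibilityRules = PlausibilityRules(),
    catalog: DDDCatalog | None = None,
) -> tuple[list[TreatmentRecord], ValidationReport]:
    """Reject records violating any plausibility cap.

    Reasons: ``"animals"`` (group size cap), ``"duration"`` (treatment-day
    cap), ``"dose"`` (implied per-day dose above ``max_dose_multiple × ddd``),
    ``"unknown_substance"`` (dose rule active but substance not in catalog).
    """

    def predicate(rec: TreatmentRecord) -> str | None:
        if rec.n_animals > rules.max_animals:
            return "animals"
        if rec.n_days > rules.max_days:
            return "duration"
        if catalog is not None:
            sw = standard_weight(rec.age_category)
            for substance, amount in rec.substances:
                if substance not in catalog:
                    return "unknown_substance"
                implied = amount / (rec.n_animals * rec.n_days * sw)
                if implied > rules.max_dose_multiple * catalog.ddd(substance):
                    return "dose"
        return None

    return _run_filter(records, predicate)


def combine_reports(reports: Iterable[ValidationReport]) -> ValidationReport:
    """Chain per-stage reports into one: input of the first stage, kept of the
    last, rejections pooled (indices refer to each stage's own input)."""
    reports = list(reports)
    if not reports:
        return ValidationReport(0, 0, [])
    rejected = [pair for rep in reports for pair in rep.rejected]
    return ValidationReport(
        n_input=reports[0].n_input, n_kept=reports[-1].n_kept, rejected=rejected
    )
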