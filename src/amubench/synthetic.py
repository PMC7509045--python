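"""Synthetic farms, censuses, and treatment journals.

The generator emulates the structure the analysis assumes: four farm types
(fattening, breeding, farrow-to-finish, sow-pool) housing subsets of the five
age categories, log-normal herd sizes centered on realistic medians,
negative-binomial therapy-event counts per farm-year, and per-event amounts of

    amount = ddd × bias × dose_deviation × SW × weight_deviation × animals × days

so that dose deviations change the dose count (nDDD) but never the treatment
count (NT) — the mechanism that makes the two indicators diverge.  A
configurable fraction of records is corrupted (amount × 100 or a late journal
entry) to exercise the validation filters.  All randomness derives from one
seed via per-farm counter-based streams, so adding farms never perturbs the
draws of existing farms.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ddd_catalog import AgeCategory, DDDCatalog, DDDEntry, standard_weight
from .errors import ValidationError
from .indicators import IndicatorTable
from .journal import JOURNAL_COLUMNS, FarmCensus, TreatmentRecord

#: Plausible per-substance defaults spanning the shipped class taxonomy.
#: These are user-replaceable inputs, not authoritative dose standards.
DEFAULT_CATALOG_ROWS: tuple[tuple[str, float, str], ...] = (
    ("amoxicillin", 20.0, "penicillins"),
    ("benzylpenicillin", 10.0, "penicillins"),
    ("ceftiofur", 3.0, "cephalosporins"),
    ("chlortetracycline", 20.0, "tetracyclines"),
    ("colistin", 5.0, "polypeptides"),
    ("doxycycline", 10.0, "tetracyclines"),
    ("enrofloxacin", 5.0, "fluoroquinolones"),
    ("gentamicin", 4.0, "aminoglycosides"),
    ("sulfadimidine", 25.0, "sulfonamides"),
    ("tiamulin", 10.0, "pleuromutilins"),
    ("trimethoprim", 5.0, "trimethoprim"),
    ("tylosin", 10.0, "macrolides"),
)


def default_catalog() -> DDDCatalog:
    return DDDCatalog(
        {name: DDDEntry(ddd, cls) for name, ddd, cls in DEFAULT_CATALOG_ROWS}
    )


_SUCK = AgeCategory.SUCKLING_PIGLET
_WEAN = AgeCategory.WEANED_PIGLET
_FAT = AgeCategory.FATTENING_PIG
_LACT = AgeCategory.LACTATING_SOW
_GEST = AgeCategory.GESTATING_SOW

DEFAULT_HERD_MEDIANS: Mapping[AgeCategory, float] = {
    _SUCK: 2200.0,
    _WEAN: 2000.0,
    _FAT: 1050.0,
    _LACT: 22.0,
    _GEST: 75.0,
}

DEFAULT_EVENT_RATES: Mapping[AgeCategory, float] = {
    _SUCK: 5.0,
    _WEAN: 8.0,
    _FAT: 4.0,
    _LACT: 3.0,
    _GEST: 2.0,
}

DEFAULT_SUBSTANCE_WEIGHTS: Mapping[AgeCategory, Mapping[str, float]] = {
    _SUCK: {"gentamicin": 3, "amoxicillin": 3, "ceftiofur": 1, "sulfadimidine": 2},
    _WEAN: {"amoxicillin": 4, "colistin": 3, "doxycycline": 2, "sulfadimidine": 2,
            "trimethoprim": 1, "chlortetracycline": 1},
    _FAT: {"tylosin": 2, "tiamulin": 2, "doxycycline": 2, "amoxicillin": 3},
    _LACT: {"amoxicillin": 3, "benzylpenicillin": 2, "sulfadimidine": 2, "enrofloxacin": 1},
    _GEST: {"amoxicillin": 3, "benzylpenicillin": 2, "tylosin": 1, "enrofloxacin": 1},
}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the generator; every rate/sigma must be non-negative."""

    n_fattening: int = 60
    n_breeding: int = 45
    n_farrow_finish: int = 30
    n_sow_pool: int = 15
    herd_medians: Mapping[AgeCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_HERD_MEDIANS)
    )
    herd_sigma: float = 0.5
    event_rates: Mapping[AgeCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_RATES)
    )
    event_dispersion: float = 2.0
    substance_weights: Mapping[AgeCategory, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(w) for c, w in DEFAULT_SUBSTANCE_WEIGHTS.items()}
    )
    combo_rate: float = 0.10
    dose_deviation_sigma: float = 0.3
    weight_deviation_sigma: float = 0.15
    substance_bias: Mapping[str, float] = field(default_factory=dict)
    error_rate: float = 0.0
    entry_lag_mean: float = 2.0
    window_start: dt.date = dt.date(2018, 10, 1)
    window_end: dt.date = dt.date(2019, 9, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_fattening", "n_breeding", "n_farrow_finish", "n_sow_pool"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in (
            "herd_sigma",
            "event_dispersion",
            "dose_deviation_sigma",
            "weight_deviation_sigma",
            "entry_lag_mean",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.error_rate < 1:
            raise ValidationError("error_rate must be in [0, 1)")
        if not 0 <= self.combo_rate < 1:
            raise ValidationError("combo_rate must be in [0, 1)")
        if self.window_end < self.window_start:
            raise ValidationError("window_end precedes window_start")
        for cat, median in self.herd_medians.items():
            if median < 1:
                raise ValidationError(f"herd median for {cat.value} must be >= 1")
        for cat, weights in self.substance_weights.items():
            if weights and sum(weights.values()) <= 0:
                raise ValidationError(f"substance weights for {cat.value} must sum > 0")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimConfig":
        kwargs = dict(data)
        for key in ("window_start", "window_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        for key in ("herd_medians", "event_rates"):
            if key in kwargs:
                kwargs[key] = {
                    AgeCategory.parse(c): float(v) for c, v in kwargs[key].items()
                }
        if "substance_weights" in kwargs:
            kwargs["substance_weights"] = {
                AgeCategory.parse(c): dict(w)
                for c, w in kwargs["substance_weights"].items()
            }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


_FARM_TYPE_CATEGORIES: dict[str, tuple[AgeCategory, ...]] = {
    "fattening": (_FAT,),
    "breeding": (_LACT, _GEST, _SUCK, _WEAN),
    "farrow_finish": (_LACT, _GEST, _SUCK, _WEAN, _FAT),
    # sow-pool farms: resolved per farm to one of two subsets below
    "sow_pool_nursing": (_LACT, _SUCK, _WEAN),
    "sow_pool_gestation": (_GEST,),
}


@dataclass
class SimResult:
    """Generated inputs plus ground truth for recovery checks."""

    config: SimConfig
    records: list[TreatmentRecord]
    census: FarmCensus
    catalog: DDDCatalog
    truth_records: pd.DataFrame  # per-event contributions, as written to the journal
    farm_types: dict[str, str]

    def farm_truth(self, kept_event_ids: set[str] | None = None) -> pd.DataFrame:
        """Per (farm, category) true NT/nDDD totals and normalized values.

        With ``kept_event_ids`` the sums are restricted to those events
        (use after filtering); otherwise corrupted events are excluded,
        giving the clean ground truth.
        """
        tr = self.truth_records
        if kept_event_ids is None:
            tr = tr[~tr["corrupted"]]
        else:
            tr = tr[tr["event_id"].isin(kept_event_ids)]
        rows = []
        grouped = tr.groupby(["farm_id", "age_category"])[["nt", "nddd"]].sum()
        for farm, cat in self.census.keys():
            denom = float(self.census.animals_per_year(farm, cat))
            key = (farm, cat.value)
            nt, nddd = (
                grouped.loc[key] if key in grouped.index else (0.0, 0.0)
            )
            rows.append(
                {
                    "farm_id": farm,
                    "age_category": cat.value,
                    "nt": float(nt),
                    "nddd": float(nddd),
                    "ati": float(nt) / denom,
                    "nddd_per_animal_year": float(nddd) / denom,
                }
            )
        return pd.DataFrame(rows)

    def write_csvs(self, out_dir: str | Path) -> dict[str, Path]:
        """Write journal/census/catalog/truth CSVs; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "journal": out_dir / "journal.csv",
            "census": out_dir / "census.csv",
            "catalog": out_dir / "catalog.csv",
            "truth": out_dir / "truth.csv",
        }
        with open(paths["journal"], "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(JOURNAL_COLUMNS)
            for rec in self.records:
                for substance, amount in rec.substances:
                    writer.writerow(
                        [
                            rec.event_id,
                            rec.farm_id,
                            rec.age_category.value,
                            substance,
                            repr(amount),
                            rec.n_animals,
                            rec.n_days,
                            rec.application_date.isoformat(),
                            rec.entry_date.isoformat(),
                        ]
                    )
        self.census.write_csv(paths["census"])
        self.catalog.write_csv(paths["catalog"])
        self.truth_records.to_csv(paths["truth"], index=False)
        return paths


def _build_roster(config: SimConfig) -> list[tuple[str, str, int]]:
    """(farm_id, farm_type, stream_index) for every farm, in a fixed order."""
    roster = []
    idx = 0
    for farm_type, count, prefix in (
        ("fattening", config.n_fattening, "FT"),
        ("breeding", config.n_breeding, "BR"),
        ("farrow_finish", config.n_farrow_finish, "FF"),
        ("sow_pool", config.n_sow_pool, "SP"),
    ):
        for k in range(count):
            roster.append((f"{prefix}{k + 1:04d}", farm_type, idx))
            idx += 1
    return roster


def generate(config: SimConfig) -> SimResult:
    """Generate a deterministic synthetic dataset from the config seed."""
    catalog = default_catalog()
    window_days = (config.window_end - config.window_start).days + 1

    records: list[TreatmentRecord] = []
    truth_rows: list[dict] = []
    counts: dict[tuple[str, AgeCategory], int] = {}
    farm_types: dict[str, str] = {}

    for farm_id, farm_type, stream_idx in _build_roster(config):
        rng = np.random.default_rng([config.seed, stream_idx])
        farm_types[farm_id] = farm_type
        if farm_type == "sow_pool":
            variant = "sow_pool_nursing" if rng.random() < 0.5 else "sow_pool_gestation"
            categories = _FARM_TYPE_CATEGORIES[variant]
        else:
            categories = _FARM_TYPE_CATEGORIES[farm_type]

        for cat in categories:
            median = config.herd_medians[cat]
            herd = max(1, int(round(median * np.exp(config.herd_sigma * rng.standard_normal()))))
            counts[(farm_id, cat)] = herd

            mean_events = config.event_rates.get(cat, 0.0)
            if mean_events <= 0:
                continue
            k = config.event_dispersion
            n_events = int(rng.negative_binomial(k, k / (k + mean_events)))
            weights = config.substance_weights.get(cat, {})
            if not weights or n_events == 0:
                continue
            names = sorted(weights)
            probs = np.array([weights[n] for n in names], dtype=float)
            probs /= probs.sum()
            sw = standard_weight(cat)

            for j in range(n_events):
                day_offset = int(rng.integers(0, window_days))
                app_date = config.window_start + dt.timedelta(days=day_offset)
                group = int(rng.integers(1, herd + 1))
                days = int(rng.integers(1, 15))
                chosen = [names[int(rng.choice(len(names), p=probs))]]
                if len(names) > 1 and rng.random() < config.combo_rate:
                    second = names[int(rng.choice(len(names), p=probs))]
                    if second != chosen[0]:
                        chosen.append(second)
                weight_dev = float(np.exp(config.weight_deviation_sigma * rng.standard_normal()))
                substances = []
                nddd_true = 0.0
                for substance in chosen:
                    dose_dev = float(
                        np.exp(config.dose_deviation_sigma * rng.standard_normal())
                    )
                    bias = float(config.substance_bias.get(substance, 1.0))
                    ddd = catalog.ddd(substance)
                    amount = ddd * bias * dose_dev * sw * weight_dev * group * days
                    substances.append((substance, amount))
                    nddd_true += amount / (ddd * sw)
                lag = min(7, int(rng.poisson(config.entry_lag_mean)))

                corrupted = False
                corruption = ""
                if config.error_rate > 0 and rng.random() < config.error_rate:
                    corrupted = True
                    if rng.random() < 0.5:
                        corruption = "amount_x100"
                        name0, amount0 = substances[0]
                        substances[0] = (name0, amount0 * 100.0)
                        nddd_true = sum(
                            a / (catalog.ddd(s) * sw) for s, a in substances
                        )
                    else:
                        corruption = "late_entry"
                        lag = 8 + int(rng.integers(0, 30))

                event_id = f"{farm_id}-{cat.value}-{j + 1:05d}"
                entry_date = app_date + dt.timedelta(days=lag)
                records.append(
                    TreatmentRecord(
                        event_id=event_id,
                        farm_id=farm_id,
                        age_category=cat,
                        substances=tuple(substances),
                        n_animals=group,
                        n_days=days,
                        application_date=app_date,
                        entry_date=entry_date,
                    )
                )
                truth_rows.append(
                    {
                        "event_id": event_id,
                        "farm_id": farm_id,
                        "age_category": cat.value,
                        "nt": float(group * days * len(substances)),
                        "nddd": nddd_true,
                        "corrupted": corrupted,
                        "corruption": corruption,
                    }
                )

    census = FarmCensus(counts=counts, continuous={k: True for k in counts})
    truth = pd.DataFrame(
        truth_rows,
        columns=["event_id", "farm_id", "age_category", "nt", "nddd", "corrupted", "corruption"],
    )
    return SimResult(
        config=config,
        records=records,
        census=census,
        catalog=catalog,
        truth_records=truth,
        farm_types=farm_types,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of comparing pipeline indicator totals against ground truth."""

    n_rows: int
    max_rel_error_nt: float
    max_rel_error_nddd: float
    ok: bool


def truth_check(
    table: IndicatorTable,
    truth_farm: pd.DataFrame,
    rel_tol: float = 1e-9,
) -> RecoveryReport:
    """Verify pipeline NT/nDDD totals equal the generator's ground truth."""
    totals = table.total_rows().set_index(["farm_id", "age_category"])
    truth = truth_farm.set_index(["farm_id", "age_category"])
    if set(totals.index) != set(truth.index):
        raise ValidationError("pipeline and truth cover different (farm, category) sets")
    truth = truth.loc[totals.index]

    def max_rel(a: np.ndarray, b: np.ndarray) -> float:
        scale = np.maximum(np.abs(b), 1.0)
        return float(np.max(np.abs(a - b) / scale)) if len(a) else 0.0

    err_nt = max_rel(totals["nt"].to_numpy(), truth["nt"].to_numpy())
    err_nddd = max_rel(totals["nddd"].to_numpy(), truth["nddd"].to_numpy())
    return RecoveryReport(
        n_rows=len(totals),
        max_rel_error_nt=err_nt,
        max_rel_error_nddd=err_nddd,
        ok=err_nt <= rel_tol and err_nddd <= rel_tol,
    )


def scaled_config(base: SimConfig, **overrides) -> SimConfig:
    """Convenience for tests: replace fields on a frozen config."""
    return replace(base, **overrides)
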