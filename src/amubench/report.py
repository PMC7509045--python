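"""Summary tables and end-to-end pipeline orchestration.

``summarize`` reproduces the per-class distribution layout (total, min,
percentiles 10/25/50/75/90, max, SD per indicator); ``run_pipeline`` chains
loading/simulation, the inclusion filters, indicator aggregation,
benchmarking, and the agreement analysis, writing CSV outputs plus a JSON
run manifest.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import agreement_frame, agreement_suite, correlation_frame, normality_gate
from .benchmark import classify_high_usage
from .ddd_catalog import AgeCategory, DDDCatalog, load_catalog
from .errors import DomainError, ValidationError
from .indicators import NORMALIZED_INDICATORS, TOTAL, IndicatorTable, aggregate
from .journal import (
    FarmCensus,
    PlausibilityRules,
    ValidationReport,
    apply_continuity_filter,
    apply_entry_lag_filter,
    apply_plausibility_filter,
    apply_window_filter,
    load_census,
    load_journal,
)
from .synthetic import SimConfig, SimResult, generate

logger = logging.getLogger("amubench")

_INDICATOR_LABELS = ("nt", "ati", "nddd", "nddd_per_animal_year")

SUMMARY_COLUMNS = (
    "age_category",
    "substance_class",
    "indicator",
    "total",
    "min",
    "p10",
    "p25",
    "median",
    "p75",
    "p90",
    "max",
    "sd",
)


def _percentile(values: np.ndarray, q: float, method: str) -> float:
    np_method = {"linear": "linear", "nearest_rank": "inverted_cdf"}[method]
    return float(np.percentile(values, q, method=np_method))


def summarize(table: IndicatorTable, percentile_method: str = "linear") -> pd.DataFrame:
    """Distribution summary per (age category, substance class, indicator).

    For each class the per-farm vector covers every censused farm of the
    category, with zeros for farms that did not use the class, so totals are
    population sums and percentiles reflect the full farm distribution.
    ``percentile_method`` is ``"linear"`` (interpolating) or
    ``"nearest_rank"``.  SD uses the n−1 denominator; for a single farm it is
    reported as 0.
    """
    if percentile_method not in ("linear", "nearest_rank"):
        raise DomainError(f"unknown percentile method {percentile_method!r}")
    frame = table.frame
    if frame.empty:
        raise DomainError("cannot summarize an empty indicator table")

    rows: list[dict] = []
    for category in table.categories():
        cat_rows = frame[frame["age_category"] == category.value]
        farms = sorted(cat_rows.loc[cat_rows["substance_class"] == TOTAL, "farm_id"])
        if not farms:
            logger.warning("category %s has no farms; omitted from summary", category.value)
            continue
        classes = sorted(set(cat_rows["substance_class"]) - {TOTAL}) + [TOTAL]
        for cls in classes:
            cls_rows = cat_rows[cat_rows["substance_class"] == cls]
            for indicator in _INDICATOR_LABELS:
                by_farm = cls_rows.set_index("farm_id")[indicator]
                values = np.array([float(by_farm.get(f, 0.0)) for f in farms])
                sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
                rows.append(
                    {
                        "age_category": category.value,
                        "substance_class": cls,
                        "indicator": indicator,
                        "total": float(values.sum()),
                        "min": float(values.min()),
                        "p10": _percentile(values, 10, percentile_method),
                        "p25": _percentile(values, 25, percentile_method),
                        "median": _percentile(values, 50, percentile_method),
                        "p75": _percentile(values, 75, percentile_method),
                        "p90": _percentile(values, 90, percentile_method),
                        "max": float(values.max()),
                        "sd": sd,
                    }
                )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; paths may be None when simulating."""

    journal: Path | None = None
    census: Path | None = None
    catalog: Path | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: Path = Path("amubench_out")
    fractions: tuple[float, ...] = (0.05, 0.10, 0.25)
    max_lag_days: int = 7
    plausibility: PlausibilityRules = field(default_factory=PlausibilityRules)
    window_start: dt.date = dt.date(2018, 10, 1)
    window_end: dt.date = dt.date(2019, 9, 30)
    percentile_method: str = "linear"
    use_long_acting: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        kwargs = dict(data)
        for key in ("journal", "census", "catalog", "out_dir"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        for key in ("window_start", "window_end"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        if "fractions" in kwargs:
            kwargs["fractions"] = tuple(float(f) for f in kwargs["fractions"])
        if "sim" in kwargs:
            kwargs["sim"] = SimConfig.from_dict(kwargs["sim"])
        if "plausibility" in kwargs:
            kwargs["plausibility"] = PlausibilityRules(**kwargs["plausibility"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant config; output location excluded."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {
                    k: encode(v)
                    for k, v in dataclasses.asdict(obj).items()
                    if k != "out_dir"
                }
            if isinstance(obj, (dt.date, Path)):
                return str(obj)
            if isinstance(obj, dict):
                return {str(k): encode(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [encode(v) for v in obj]
            if isinstance(obj, AgeCategory):
                return obj.value
            return obj

        blob = json.dumps(encode(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: PipelineConfig
    stages: dict[str, ValidationReport]
    table: IndicatorTable
    summary: pd.DataFrame
    classifications: pd.DataFrame
    agreement: pd.DataFrame
    correlation: pd.DataFrame
    bland_altman: pd.DataFrame
    bland_altman_limits: pd.DataFrame
    manifest: dict
    sim_result: SimResult | None = None


def apply_filters(
    records,
    census: FarmCensus,
    catalog: DDDCatalog,
    config: PipelineConfig,
) -> tuple[list, dict[str, ValidationReport]]:
    """Run the inclusion filters in order; returns kept records and the
    per-stage reports (window, entry_lag, continuity, plausibility)."""
    stages: dict[str, ValidationReport] = {}
    kept, stages["window"] = apply_window_filter(
        records, config.window_start, config.window_end
    )
    kept, stages["entry_lag"] = apply_entry_lag_filter(kept, config.max_lag_days)
    kept, stages["continuity"] = apply_continuity_filter(kept, census)
    kept, stages["plausibility"] = apply_plausibility_filter(
        kept, config.plausibility, catalog
    )
    return kept, stages


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write all outputs under ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sim_result: SimResult | None = None
    if config.simulate:
        sim_result = generate(config.sim)
        inputs_dir = out_dir / "inputs"
        sim_result.write_csvs(inputs_dir)
        records, census, catalog = sim_result.records, sim_result.census, sim_result.catalog
        logger.info("simulated %d records on %d (farm, category) pairs",
                    len(records), len(census))
    else:
        if not (config.journal and config.census and config.catalog):
            raise DomainError("journal, census, and catalog paths are required unless simulating")
        catalog = load_catalog(config.catalog)
        census = load_census(config.census)
        records = load_journal(config.journal)

    kept, stages = apply_filters(records, census, catalog, config)
    for name, rep in stages.items():
        logger.info("filter %-12s input=%d kept=%d rejected=%d",
                    name, rep.n_input, rep.n_kept, rep.n_rejected)

    table = aggregate(kept, census, catalog, use_long_acting=config.use_long_acting)
    summary = summarize(table, config.percentile_method)

    cls_rows = []
    for category in table.categories():
        if len(table.category_values(category, "ati")) < 2:
            logger.warning("category %s has < 2 farms; benchmarking skipped",
                           category.value)
            continue
        for fraction in config.fractions:
            for indicator in NORMALIZED_INDICATORS:
                c = classify_high_usage(table, category, indicator, fraction)
                for farm in sorted(c.all_farms):
                    cls_rows.append(
                        {
                            "age_category": category.value,
                            "fraction": fraction,
                            "indicator": indicator,
                            "farm_id": farm,
                            "is_high": farm in c.high_farms,
                            "tie_flag": c.tie_flag,
                        }
                    )
    classifications = pd.DataFrame(
        cls_rows,
        columns=["age_category", "fraction", "indicator", "farm_id", "is_high", "tie_flag"],
    )

    reports, bland = agreement_suite(table, config.fractions)
    agreement = agreement_frame(reports)
    correlation = correlation_frame(reports)

    ba_rows, limit_rows = [], []
    for category in sorted(bland, key=lambda c: c.value):
        result = bland[category]
        per_farm = result.to_frame()
        per_farm.insert(0, "age_category", category.value)
        ba_rows.append(per_farm)
        limit_rows.append(
            {
                "age_category": category.value,
                "n_farms": result.n,
                "mean_diff": result.mean_diff,
                "sd_diff": result.sd_diff,
                "lower_limit": result.lower_limit,
                "upper_limit": result.upper_limit,
                "n_outliers": len(result.outliers),
            }
        )
    bland_frame = (
        pd.concat(ba_rows, ignore_index=True)
        if ba_rows
        else pd.DataFrame(columns=["age_category", "farm_id", "mean", "diff", "is_outlier"])
    )
    limits_frame = pd.DataFrame(
        limit_rows,
        columns=["age_category", "n_farms", "mean_diff", "sd_diff",
                 "lower_limit", "upper_limit", "n_outliers"],
    )

    normality = {}
    for category in table.categories():
        for indicator in NORMALIZED_INDICATORS:
            values = table.category_values(category, indicator).values
            pvalue, looks_normal = normality_gate(values)
            normality[f"{category.value}:{indicator}"] = {
                "shapiro_p": None if np.isnan(pvalue) else pvalue,
                "looks_normal": looks_normal,
            }

    manifest = {
        "amubench_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.sim.seed if config.simulate else None,
        "simulated": config.simulate,
        "n_records_input": len(records),
        "n_records_kept": len(kept),
        "filter_stages": {
            name: {"input": r.n_input, "kept": r.n_kept, "rejected": r.n_rejected,
                   "reasons": r.reasons()}
            for name, r in stages.items()
        },
        "n_farm_category_pairs": len(census),
        "fractions": list(config.fractions),
        "normality_gate_advisory": normality,
    }

    table.to_csv(out_dir / "indicators.csv")
    summary.to_csv(out_dir / "summary.csv", index=False)
    classifications.to_csv(out_dir / "classifications.csv", index=False)
    agreement.to_csv(out_dir / "agreement.csv", index=False)
    correlation.to_csv(out_dir / "correlation.csv", index=False)
    bland_frame.to_csv(out_dir / "bland_altman.csv", index=False)
    limits_frame.to_csv(out_dir / "bland_altman_limits.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        config=config,
        stages=stages,
        table=table,
        summary=summary,
        classifications=classifications,
        agreement=agreement,
        correlation=correlation,
        bland_altman=bland_frame,
        bland_altman_limits=limits_frame,
        manifest=manifest,
        sim_result=sim_result,
    )
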