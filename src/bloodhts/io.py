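"""File I/O, run configuration and the end-to-end pipeline.

Series travel as long-format CSV with columns ``period,node,value`` and
ISO ``YYYY-MM`` periods; hierarchies as a YAML/JSON file with a
``children`` mapping. ``run_pipeline`` wires the stages together:
evaluate the (base model x reconciliation method) grid on a holdout,
select by average MAPE, refit on the full history and write the forecast,
accuracy and log artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, GapError, LabelError
from .evaluation import METHOD_ORDER, MODEL_ORDER
from .hierarchy import (
    HierarchicalSeries,
    HierarchySpec,
    build_summing_matrix,
    check_coherence,
    gender_abo_hierarchy,
)
from .model import HierarchicalForecastModel
from .synthetic_data import SyntheticConfig, generate

__all__ = [
    "read_hierarchy_config",
    "read_series_csv",
    "write_series_csv",
    "write_forecast_csv",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def read_hierarchy_config(path) -> HierarchySpec:
    """Load a hierarchy from a YAML/JSON file with a ``children`` mapping."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "children" not in data:
        raise ConfigError(f"{path}: expected a mapping with a 'children' key")
    spec = HierarchySpec.from_children(data["children"])
    declared = data.get("nodes")
    if declared is not None and set(declared) != set(spec.nodes):
        raise ConfigError(f"{path}: 'nodes' disagrees with 'children'")
    return spec


def read_series_csv(path, spec: HierarchySpec | None = None) -> HierarchicalSeries:
    """Read a long-format ``period,node,value`` CSV into a hierarchical series.

    Periods must be contiguous months and every (period, node) cell present;
    gaps are reported with the offending periods named. With ``spec`` given,
    unknown node labels are rejected and columns are ordered to match it.
    """
    raw = pd.read_csv(path)
    required = {"period", "node", "value"}
    if not required.issubset(raw.columns):
        raise ConfigError(f"{path}: need columns {sorted(required)}")
    try:
        raw["period"] = pd.PeriodIndex(raw["period"].astype(str), freq="M")
    except Exception as exc:
        raise ConfigError(f"{path}: unparseable period: {exc}") from exc
    if spec is not None:
        unknown = sorted(set(raw["node"]) - set(spec.nodes))
        if unknown:
            raise LabelError(f"{path}: unknown node labels {unknown}")
    wide = raw.pivot(index="period", columns="node", values="value")
    full_index = pd.period_range(wide.index.min(), wide.index.max(), freq="M")
    missing_months = full_index.difference(wide.index)
    if len(missing_months):
        raise GapError(f"{path}: missing months {[str(p) for p in missing_months]}")
    if wide.isna().any().any():
        gaps = wide.isna()
        offenders = [f"{period}/{node}" for period in gaps.index
                     for node in gaps.columns if gaps.loc[period, node]]
        raise GapError(f"{path}: missing cells {offenders[:20]}")
    cols = list(spec.nodes) if spec is not None else list(wide.columns)
    if spec is not None and set(wide.columns) != set(spec.nodes):
        absent = sorted(set(spec.nodes) - set(wide.columns))
        raise GapError(f"{path}: no data for nodes {absent}")
    wide = wide[cols]
    wide.columns.name = None
    wide.index.name = None
    return HierarchicalSeries(wide)


def write_series_csv(series: HierarchicalSeries, path) -> None:
    """Write a series in the same long dialect, full float precision."""
    long = series.data.stack().rename("value").reset_index()
    long.columns = ["period", "node", "value"]
    long["period"] = long["period"].astype(str)
    long.to_csv(path, index=False, float_format="%.17g")


def write_forecast_csv(forecasts, path, method: str | None = None,
                       base_model: str = "", round_units: bool = False) -> None:
    """Write reconciled forecasts as ``step,period,node,value,method,base_model``."""
    frame = forecasts.forecasts
    method = method or getattr(forecasts, "method", "")
    rows = frame.stack().rename("value").reset_index()
    rows.columns = ["period", "node", "value"]
    if isinstance(frame.index, pd.PeriodIndex):
        steps = {p: i + 1 for i, p in enumerate(frame.index)}
        rows.insert(0, "step", rows["period"].map(steps))
        rows["period"] = rows["period"].astype(str)
    else:
        rows.insert(0, "step", rows["period"])
        rows["period"] = ""
    if round_units:
        rows["value"] = rows["value"].round().astype(int)
    rows["method"] = method
    rows["base_model"] = base_model
    rows.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline settings.

    With no ``series_file`` a synthetic registry is generated from the
    default study conditions using ``seed``.
    """

    hierarchy_file: str | None = None
    series_file: str | None = None
    base_models: tuple = MODEL_ORDER
    methods: tuple = METHOD_ORDER
    horizon: int = 60
    holdout: int = 12
    seed: int = 0
    out_dir: str = "bloodhts_run"
    round_output: bool = False

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if self.holdout < 1:
            raise ConfigError("holdout must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """fit -> reconcile -> evaluate -> select -> refit -> forecast, on disk.

    Returns a manifest of artifact paths plus the selection; every CSV is
    deterministic given the config (identical config hashes give identical
    bytes).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = (read_hierarchy_config(config.hierarchy_file)
            if config.hierarchy_file else gender_abo_hierarchy())
    if config.series_file:
        series = read_series_csv(config.series_file, spec)
    else:
        series = generate(SyntheticConfig(seed=config.seed))
    if config.holdout >= len(series):
        raise ConfigError("holdout must be shorter than the series")

    model = HierarchicalForecastModel(
        series, spec, base_models=config.base_models, methods=config.methods,
        holdout=config.holdout)
    results = model.fit()
    forecasts = results.forecast(config.horizon)
    report = check_coherence(
        HierarchicalSeries(forecasts.forecasts), build_summing_matrix(spec))

    acc_csv = out / "accuracy.csv"
    results.accuracy.to_csv(acc_csv)
    acc_json = out / "accuracy.json"
    acc_json.write_text(json.dumps(
        {f"{m}/{meth}": results.accuracy.average_row[(m, meth)]
         for m, meth in results.accuracy.average_row.index}, indent=2))
    fc_csv = out / "forecast.csv"
    write_forecast_csv(forecasts, fc_csv, base_model=results.best_base_model,
                       round_units=config.round_output)
    log_path = out / "run_log.json"
    manifest = {
        "config_hash": config.config_hash(),
        "selected_method": results.best_method,
        "selected_base_model": results.best_base_model,
        "average_mape": {f"{m}/{meth}": float(results.accuracy.average_row[(m, meth)])
                         for m, meth in results.accuracy.average_row.index},
        "forecast_coherent": bool(report.passed),
        "max_coherence_violation": report.max_violation,
        "artifacts": {"accuracy_csv": str(acc_csv), "accuracy_json": str(acc_json),
                      "forecast_csv": str(fc_csv)},
    }
    log_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s under %s with average MAPEs %s",
                results.best_method, results.best_base_model,
                manifest["average_mape"])
    manifest["summary"] = results.summary()
    return manifest
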