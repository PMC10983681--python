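"""Model/Results front end tying the stages into one fitting workflow.

:class:`HierarchicalForecastModel` is built from a coherent historical
series and a hierarchy; ``fit()`` runs the full evaluation design — split
off a holdout, produce base forecasts per node for each base model,
reconcile with each scheme, score by MAPE, select the winner — and then
re-fits the winning base model on the complete history. The returned
:class:`HierarchicalForecastResults` carries the accuracy table, the
selection and the refitted per-node models, and produces coherent
out-of-sample forecasts for any horizon via ``forecast(h)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .base_forecasters import fit_all_nodes, forecast_all_nodes
from .errors import ConfigError
from .evaluation import (
    METHOD_ORDER,
    MODEL_ORDER,
    AccuracyTable,
    accuracy_table,
    select_best,
)
from .hierarchy import (
    HierarchicalSeries,
    HierarchySpec,
    SummingMatrix,
    build_summing_matrix,
    check_coherence,
)
from .reconciliation import ReconciledForecastSet, reconcile

__all__ = ["HierarchicalForecastModel", "HierarchicalForecastResults"]


class HierarchicalForecastModel:
    """Hierarchical donation-forecasting model.

    Parameters
    ----------
    series
        Coherent historical series covering every node of ``spec``.
    spec
        The node hierarchy.
    base_models, methods
        The (base model) x (reconciliation method) grid to evaluate.
    holdout
        Number of trailing months scored out-of-sample during ``fit``.
    season_length
        Months per seasonal cycle.
    """

    def __init__(self, series: HierarchicalSeries, spec: HierarchySpec,
                 base_models=MODEL_ORDER, methods=METHOD_ORDER,
                 holdout: int = 12, season_length: int = 12, **arima_kwargs):
        if tuple(series.node_labels) != tuple(spec.nodes):
            raise ConfigError("series columns must match the hierarchy node order")
        if not 0 < holdout < len(series):
            raise ConfigError("holdout must be positive and shorter than the series")
        unknown_m = set(methods) - set(METHOD_ORDER)
        unknown_b = set(base_models) - set(MODEL_ORDER)
        if unknown_m or unknown_b:
            raise ConfigError(f"unknown methods/models: {unknown_m | unknown_b}")
        self.series = series
        self.spec = spec
        self.summing: SummingMatrix = build_summing_matrix(spec)
        self.base_models = tuple(base_models)
        self.methods = tuple(methods)
        self.holdout = holdout
        self.season_length = season_length
        self.arima_kwargs = arima_kwargs

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: HierarchySpec, **kwargs):
        """Build from a (periods x nodes) frame with a monthly PeriodIndex."""
        return cls(HierarchicalSeries(data[list(spec.nodes)]), spec, **kwargs)

    def fit(self) -> "HierarchicalForecastResults":
        """Evaluate the grid out-of-sample, select, and refit on full history."""
        history, holdout = self.series.split(self.holdout)
        table = accuracy_table(history, holdout, self.spec,
                               methods=self.methods, base_models=self.base_models,
                               season_length=self.season_length,
                               **self.arima_kwargs)
        method, base_model = select_best(table)
        fitted = fit_all_nodes(self.series.data, base_model,
                               season_length=self.season_length,
                               **self.arima_kwargs)
        return HierarchicalForecastResults(
            model=self, accuracy=table, best_method=method,
            best_base_model=base_model, node_models=fitted)


@dataclass
class HierarchicalForecastResults:
    """Fit outcome: accuracy table, selected combination, refitted models."""

    model: HierarchicalForecastModel
    accuracy: AccuracyTable
    best_method: str
    best_base_model: str
    node_models: dict = field(repr=False)

    def forecast(self, h: int, method: str | None = None) -> ReconciledForecastSet:
        """Coherent h-step forecasts with the selected (or given) method."""
        m = self.model
        base = forecast_all_nodes(self.node_models, m.series.data, h)
        return reconcile(method or self.best_method, base, m.summing,
                         m.spec, m.series)

    def coherence_of(self, forecasts: ReconciledForecastSet, tol: float = 1e-6):
        frame = forecasts.forecasts
        if not isinstance(frame.index, pd.PeriodIndex):
            idx = pd.period_range(self.model.series.end_period + 1,
                                  periods=len(frame), freq="M")
            frame = frame.set_axis(idx)
        return check_coherence(HierarchicalSeries(frame), self.model.summing, tol)

    def summary(self) -> str:
        """Plain-text summary: selection, average MAPEs, per-node winners."""
        m = self.model
        lines = [
            "Hierarchical forecast reconciliation results",
            "=" * 44,
            f"Nodes: {len(m.spec.nodes)} ({m.spec.n_levels} levels); "
            f"sample {m.series.start_period}..{m.series.end_period} "
            f"({len(m.series)} months, holdout {m.holdout})",
            f"Selected: method={self.best_method.upper()} "
            f"base_model={self.best_base_model.upper()}",
            "",
            "Average MAPE (%) by (base model, method):",
        ]
        avg = self.accuracy.average_row
        for (model_name, method) in avg.index:
            marker = " <-- selected" if (model_name == self.best_base_model
                                         and method == self.best_method) else ""
            lines.append(f"  {model_name:>6} {method.upper():>5}: "
                         f"{avg[(model_name, method)]:7.2f}{marker}")
        return "\n".join(lines)
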