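"""Out-of-sample accuracy evaluation and method selection.

The accuracy measure throughout is MAPE, the mean absolute percentage
error, reported on the 0-100 scale:

    MAPE = 100/m * sum_t |y_t - yhat_t| / y_t

The evaluation design mirrors standard hierarchical-forecasting practice:
hold out the final months of the sample, produce base forecasts for the
holdout span from each base model, reconcile them with each scheme, score
every node, and pick the (method, base model) column whose *average* MAPE
across nodes is smallest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base_forecasters import fit_all_nodes, forecast_all_nodes
from .errors import ChronologyError, ZeroActualError
from .hierarchy import HierarchicalSeries, HierarchySpec, build_summing_matrix
from .reconciliation import ReconciledForecastSet, reconcile

__all__ = [
    "mape",
    "AccuracyTable",
    "accuracy_table",
    "select_best",
    "ValidationReport",
    "validate_holdout",
    "METHOD_ORDER",
    "MODEL_ORDER",
]

logger = logging.getLogger(__name__)

# Declared column order; also the deterministic tie-break order in
# select_best (first the ETS block, then the ARIMA block, methods in the
# order below within each block).
METHOD_ORDER = ("bu", "tdfp", "tdha", "tdhp", "oc")
MODEL_ORDER = ("ets", "arima")


def mape(actual, predicted) -> float:
    """Mean absolute percentage error, in percent.

    Raises :class:`ZeroActualError` if any actual value is zero — zeros are
    never silently skipped.
    """
    y = np.asarray(actual, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if len(y) != len(yhat) or len(y) == 0:
        raise ValueError("actual and predicted must have equal, non-zero length")
    if np.any(y == 0):
        raise ZeroActualError("actual values contain zeros; APE undefined")
    return float(100.0 * np.mean(np.abs((y - yhat) / y)))


@dataclass(frozen=True)
class AccuracyTable:
    """MAPE per node per (base model, reconciliation method).

    ``table`` has one row per node plus an ``"Average"`` row (the arithmetic
    mean of the node rows), and a (model, method) column MultiIndex in the
    declared order.
    """

    table: pd.DataFrame = field(repr=False)

    AVERAGE_ROW = "Average"

    def __post_init__(self) -> None:
        if self.AVERAGE_ROW not in self.table.index:
            raise ValueError("table must contain an 'Average' row")
        nodes = self.table.drop(index=self.AVERAGE_ROW)
        if len(nodes) and not np.allclose(nodes.mean(axis=0),
                                          self.table.loc[self.AVERAGE_ROW], atol=1e-9):
            raise ValueError("'Average' row must equal the mean of the node rows")
        if (self.table.to_numpy() < 0).any():
            raise ValueError("MAPE cells must be non-negative")

    @classmethod
    def from_node_rows(cls, node_rows: pd.DataFrame) -> "AccuracyTable":
        avg = node_rows.mean(axis=0).rename(cls.AVERAGE_ROW)
        return cls(pd.concat([node_rows, avg.to_frame().T]))

    @classmethod
    def from_average_row(cls, cells: dict[tuple[str, str], float]) -> "AccuracyTable":
        """Build a table holding only the Average row (e.g. a published one).

        ``cells`` maps (model, method) to the average MAPE.
        """
        cols = pd.MultiIndex.from_tuples(
            [(m, meth) for m in MODEL_ORDER for meth in METHOD_ORDER
             if (m, meth) in cells],
            names=("model", "method"))
        row = pd.DataFrame([[cells[c] for c in cols]], index=[cls.AVERAGE_ROW],
                           columns=cols)
        return cls(row)

    @property
    def average_row(self) -> pd.Series:
        return self.table.loc[self.AVERAGE_ROW]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def accuracy_table(history: HierarchicalSeries, holdout: HierarchicalSeries,
                   spec: HierarchySpec,
                   methods=METHOD_ORDER, base_models=MODEL_ORDER,
                   *, season_length: int = 12, **arima_kwargs) -> AccuracyTable:
    """Fit, reconcile and score every (base model, method) combination.

    The holdout must start exactly one month after the history ends.
    Returns MAPEs per node plus the Average row, columns ordered as the
    declared (model, method) grid.
    """
    if holdout.start_period != history.end_period + 1:
        raise ChronologyError(
            f"holdout starts {holdout.start_period}, expected {history.end_period + 1}"
        )
    if tuple(holdout.node_labels) != tuple(history.node_labels):
        raise ValueError("history and holdout must share the same hierarchy")
    summing = build_summing_matrix(spec)
    h = len(holdout)
    cells: dict[tuple[str, str], pd.Series] = {}
    for model in base_models:
        fitted = fit_all_nodes(history.data, model, season_length=season_length,
                               **arima_kwargs)
        base = forecast_all_nodes(fitted, history.data, h)
        for method in methods:
            rec = reconcile(method, base, summing, spec, history)
            cells[(model, method)] = pd.Series(
                {node: mape(holdout.data[node], rec.forecasts[node])
                 for node in spec.nodes})
    cols = pd.MultiIndex.from_tuples(
        [(m, meth) for m in MODEL_ORDER for meth in METHOD_ORDER
         if (m, meth) in cells], names=("model", "method"))
    node_rows = pd.DataFrame({c: cells[c] for c in cols}).loc[list(spec.nodes)]
    node_rows.columns = cols
    return AccuracyTable.from_node_rows(node_rows)


def select_best(table: AccuracyTable) -> tuple[str, str]:
    """Pick the (method, base model) with the smallest average MAPE.

    Ties break deterministically on the declared column order; a tie is
    logged so the arbitrariness is visible.
    """
    avg = table.average_row
    if len(avg) == 0:
        raise ValueError("accuracy table has no columns")
    best_val = avg.min()
    winners = [c for c in avg.index if avg[c] == best_val]
    if len(winners) > 1:
        logger.info("accuracy tie between %s at MAPE %.4f; keeping %s",
                    winners, best_val, winners[0])
    model, method = winners[0]
    return method, model


@dataclass(frozen=True)
class ValidationReport:
    """Per-period forecast errors for one node over a validation span.

    ``frame`` has columns actual / forecast / ape (percent); ``yearly_mape``
    aggregates by calendar year; ``overall_mape`` covers the whole span.
    """

    node: str
    frame: pd.DataFrame = field(repr=False)
    yearly_mape: dict[int, float] = field(default_factory=dict)
    overall_mape: float = float("nan")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="period")


def validate_holdout(forecasts, actual: HierarchicalSeries, node: str) -> ValidationReport:
    """Score one node's forecasts against actuals, month by month.

    ``forecasts`` may be a :class:`ReconciledForecastSet` or a frame with a
    matching monthly PeriodIndex. Windows are calendar years.
    """
    fc = forecasts.forecasts if isinstance(forecasts, ReconciledForecastSet) else forecasts
    if node not in fc.columns or node not in actual.data.columns:
        raise ValueError(f"node {node!r} missing from forecasts or actuals")
    common = actual.data.index.intersection(fc.index)
    if len(common) == 0:
        raise ChronologyError("forecast and actual periods do not overlap")
    y = actual.data.loc[common, node].to_numpy(dtype=float)
    yhat = fc.loc[common, node].to_numpy(dtype=float)
    if np.any(y == 0):
        raise ZeroActualError("actual values contain zeros; APE undefined")
    ape = 100.0 * np.abs((y - yhat) / y)
    frame = pd.DataFrame({"actual": y, "forecast": yhat, "ape": ape}, index=common)
    yearly = {int(year): float(grp["ape"].mean())
              for year, grp in frame.groupby(frame.index.year)}
    return ValidationReport(node, frame, yearly, float(ape.mean()))
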