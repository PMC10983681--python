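"""Reconciliation of independent base forecasts into coherent ones.

Base forecasts are produced node by node and generally violate the
aggregation constraints of the hierarchy (a male + female total that is not
the forecast total, say). Four classical schemes restore coherence:

* **bottom-up** — keep the bottom-node forecasts, rebuild every upper node
  as the sum of its descendants;
* **top-down** — keep the root forecast and split it down the tree with
  bottom-node proportions: average historical proportions (mean over time
  of each bottom share of the total), proportions of historical averages
  (ratio of time-means), or forecast proportions (recomputed per step from
  the base forecasts along each node's ancestor chain);
* **optimal combination** — regress the full base-forecast vector on the
  summing matrix S by (weighted) least squares and report S @ beta-hat, the
  orthogonal projection of the base forecasts onto the coherent subspace.

All schemes are pure linear algebra on the forecasts; negative base
forecasts pass through unchanged so the projection identities hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    IncompleteForecastError,
    LabelError,
    ZeroDenominatorError,
    ZeroTotalError,
)
from .hierarchy import HierarchicalSeries, HierarchySpec, SummingMatrix

__all__ = [
    "BaseForecastSet",
    "ProportionSet",
    "ReconciledForecastSet",
    "bottom_up",
    "average_historical_proportions",
    "proportions_of_historical_averages",
    "forecast_proportions",
    "top_down",
    "optimal_combination",
]

METHOD_LABELS = ("bu", "tdfp", "tdha", "tdhp", "oc")


@dataclass(frozen=True)
class BaseForecastSet:
    """Independent h-step point forecasts per node, prior to reconciliation.

    ``forecasts`` is (h x nodes); columns follow the hierarchy node order.
    ``provenance`` optionally records the base model per node.
    """

    forecasts: pd.DataFrame = field(repr=False)
    provenance: dict[str, str] | None = None

    @property
    def horizon(self) -> int:
        return len(self.forecasts)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self.forecasts.columns)

    def require(self, labels) -> None:
        missing = [n for n in labels if n not in self.forecasts.columns]
        if missing:
            raise IncompleteForecastError(f"missing base forecasts for {missing}")


@dataclass(frozen=True)
class ProportionSet:
    """Bottom-node disaggregation proportions.

    ``proportions`` is (h x bottom) for the per-step forecast-proportion
    scheme and (1 x bottom) for the two historical schemes; every row sums
    to one.
    """

    method: str  # "ahp" | "pha" | "fp"
    proportions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        rows = self.proportions.to_numpy()
        if (rows < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if not np.allclose(rows.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("proportions must sum to 1 in every row")

    def for_step(self, step: int) -> np.ndarray:
        """Proportion row for 1-based forecast step ``step``."""
        if len(self.proportions) == 1:
            return self.proportions.iloc[0].to_numpy()
        return self.proportions.iloc[step - 1].to_numpy()


@dataclass(frozen=True)
class ReconciledForecastSet:
    """Coherent forecasts for every node, tagged with the method used."""

    forecasts: pd.DataFrame = field(repr=False)
    method: str

    @property
    def horizon(self) -> int:
        return len(self.forecasts)

    @property
    def node_labels(self) -> tuple[str, ...]:
        return tuple(self.forecasts.columns)


def _as_full_frame(values: np.ndarray, summing: SummingMatrix, like: pd.DataFrame | None):
    idx = like.index if like is not None else pd.RangeIndex(1, len(values) + 1, name="step")
    return pd.DataFrame(values, index=idx, columns=list(summing.row_labels))


def bottom_up(base: BaseForecastSet, summing: SummingMatrix) -> ReconciledForecastSet:
    """Aggregate the bottom-node base forecasts upward; upper bases are ignored."""
    base.require(summing.col_labels)
    bottom = base.forecasts[list(summing.col_labels)].to_numpy(dtype=float)
    full = bottom @ summing.entries.T
    return ReconciledForecastSet(_as_full_frame(full, summing, base.forecasts), "bu")


def _bottom_history(history: HierarchicalSeries, spec: HierarchySpec):
    bottoms = history.data[list(spec.bottom_nodes)].to_numpy(dtype=float)
    totals = history.data[spec.root].to_numpy(dtype=float)
    if (totals <= 0).any():
        raise ZeroTotalError("top-level series must be strictly positive at every period")
    return bottoms, totals


def average_historical_proportions(history: HierarchicalSeries, spec: HierarchySpec,
                                   *, within_parent: bool = False) -> ProportionSet:
    """Average-historical-proportions scheme: p_i = mean over t of Y_it / Y_t.

    By default each bottom node's share is taken against the root total, the
    textbook formula. With ``within_parent=True`` the share is the product,
    along the node's ancestor chain, of the time-averaged share of each node
    within its parent — an equivalent reading when shares are constant, and
    a different one otherwise.
    """
    bottoms, totals = _bottom_history(history, spec)
    if not within_parent:
        p = (bottoms / totals[:, None]).mean(axis=0)
    else:
        data = history.data
        p = np.ones(len(spec.bottom_nodes))
        for j, leaf in enumerate(spec.bottom_nodes):
            node = leaf
            for parent in spec.ancestors_of(leaf):
                denom = data[parent].to_numpy(dtype=float)
                if (denom <= 0).any():
                    raise ZeroTotalError(f"series {parent!r} has non-positive values")
                p[j] *= (data[node].to_numpy(dtype=float) / denom).mean()
                node = parent
    frame = pd.DataFrame(p[None, :], columns=list(spec.bottom_nodes))
    return ProportionSet("ahp", frame)


def proportions_of_historical_averages(history: HierarchicalSeries,
                                       spec: HierarchySpec) -> ProportionSet:
    """Proportions-of-historical-averages scheme: p_i = mean(Y_i) / mean(Y)."""
    bottoms, totals = _bottom_history(history, spec)
    p = bottoms.mean(axis=0) / totals.mean()
    frame = pd.DataFrame(p[None, :], columns=list(spec.bottom_nodes))
    return ProportionSet("pha", frame)


def forecast_proportions(base: BaseForecastSet, spec: HierarchySpec) -> ProportionSet:
    """Per-step forecast proportions from the base forecasts themselves.

    For each bottom node the proportion is the product, over its ancestor
    chain, of (the node's base forecast) / (the summed base forecasts of the
    node and its siblings), recomputed at every horizon step. The telescoping
    product makes each step's proportions sum to one.
    """
    base.require(spec.nodes)
    h = base.horizon
    fc = base.forecasts
    p = np.ones((h, len(spec.bottom_nodes)))
    for j, leaf in enumerate(spec.bottom_nodes):
        node = leaf
        for parent in spec.ancestors_of(leaf):
            siblings = spec.children_of(parent)
            denom = fc[list(siblings)].to_numpy(dtype=float).sum(axis=1)
            if np.any(denom == 0):
                step = int(np.nonzero(denom == 0)[0][0]) + 1
                raise ZeroDenominatorError(
                    f"sibling-group {siblings} has zero summed forecast at step {step}"
                )
            p[:, j] *= fc[node].to_numpy(dtype=float) / denom
            node = parent
    frame = pd.DataFrame(p, index=fc.index, columns=list(spec.bottom_nodes))
    return ProportionSet("fp", frame)


def top_down(top_forecast, proportions: ProportionSet,
             summing: SummingMatrix) -> ReconciledForecastSet:
    """Split the root forecast across bottom nodes, then rebuild upper levels."""
    if tuple(proportions.proportions.columns) != summing.col_labels:
        raise LabelError("proportion labels do not match the hierarchy's bottom nodes")
    like = top_forecast.to_frame() if isinstance(top_forecast, pd.Series) else None
    top = np.asarray(top_forecast, dtype=float).ravel()
    h = len(top)
    if len(proportions.proportions) not in (1, h):
        raise ValueError("per-step proportions must cover every horizon step")
    bottom = np.vstack([top[k - 1] * proportions.for_step(k) for k in range(1, h + 1)])
    full = bottom @ summing.entries.T
    label = {"ahp": "tdhp", "pha": "tdha", "fp": "tdfp"}[proportions.method]
    return ReconciledForecastSet(_as_full_frame(full, summing, like), label)


def optimal_combination(base: BaseForecastSet, summing: SummingMatrix,
                        weights=None) -> ReconciledForecastSet:
    """Least-squares projection of all base forecasts onto the coherent subspace.

    Per step, solves ``min_b (yhat - S b)' W (yhat - S b)`` and returns
    ``S @ b``. ``weights`` is an optional positive diagonal (one entry per
    node); the default (OLS, identity weights) gives the projection
    ``S (S'S)^{-1} S' yhat``. Already-coherent inputs are returned unchanged.
    """
    base.require(summing.row_labels)
    Y = base.forecasts[list(summing.row_labels)].to_numpy(dtype=float)
    S = summing.entries
    if weights is None:
        W = np.eye(S.shape[0])
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape[0] != S.shape[0] or (w <= 0).any():
            raise ValueError("weights must be one strictly positive entry per node")
        W = np.diag(w)
    gram = S.T @ W @ S
    try:
        beta = np.linalg.solve(gram, S.T @ W @ Y.T)  # (n_bottom, h)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - impossible for strict trees
        raise ZeroDenominatorError(f"normal equations are singular: {exc}") from exc
    full = (S @ beta).T
    return ReconciledForecastSet(_as_full_frame(full, summing, base.forecasts), "oc")


def reconcile(method: str, base: BaseForecastSet, summing: SummingMatrix,
              spec: HierarchySpec, history: HierarchicalSeries | None = None,
              *, oc_weights=None) -> ReconciledForecastSet:
    """Dispatch a reconciliation method by its short label.

    ``history`` is required for the two historical top-down schemes
    (``tdhp`` = average historical proportions, ``tdha`` = proportions of
    historical averages).
    """
    method = method.lower()
    if method == "bu":
        return bottom_up(base, summing)
    if method == "oc":
        return optimal_combination(base, summing, weights=oc_weights)
    if method == "tdfp":
        props = forecast_proportions(base, spec)
    elif method == "tdhp":
        if history is None:
            raise ValueError("tdhp requires the historical series")
        props = average_historical_proportions(history, spec)
    elif method == "tdha":
        if history is None:
            raise ValueError("tdha requires the historical series")
        props = proportions_of_historical_averages(history, spec)
    else:
        raise ValueError(f"unknown reconciliation method {method!r}")
    base.require([spec.root])
    return top_down(base.forecasts[spec.root], props, summing)
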