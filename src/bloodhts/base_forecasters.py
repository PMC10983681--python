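"""Univariate point forecasters for single hierarchy nodes.

Two families are provided, mirroring what donation planners actually run:

* seasonal ARIMA with automatic order selection — a stepwise AICc search in
  the spirit of the Hyndman–Khandakar algorithm, with differencing orders
  decided up front (KPSS unit-root test for ``d``, an STL seasonal-strength
  heuristic for ``D``), and an exhaustive-grid fallback for small bounds;
* Holt-Winters / ETS exponential smoothing with additive trend and either
  additive or multiplicative monthly seasonality, picked by AICc.

Model estimation is delegated to statsmodels (SARIMAX and
ExponentialSmoothing); the order search, the degenerate-series handling and
the frozen-state forecasting layer are this module's own. All fitting is
deterministic: no random restarts, no seed dependence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.tsa.holtwinters import ExponentialSmoothing
from statsmodels.tsa.seasonal import STL
from statsmodels.tsa.statespace.sarimax import SARIMAX
from statsmodels.tsa.stattools import kpss

from .errors import NumericalError

__all__ = [
    "ArimaModel",
    "EtsState",
    "fit_arima",
    "forecast_arima",
    "fit_ets",
    "forecast_ets",
    "unit_root_diffs",
    "seasonal_strength",
]

_SEASONAL_STRENGTH_THRESHOLD = 0.64  # D = 1 when the STL seasonal share exceeds this


# --------------------------------------------------------------------------
# ARIMA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ArimaModel:
    """A fitted (or hand-specified) seasonal ARIMA model.

    ``trend`` is ``"c"`` when a constant is included (only when d + D == 0)
    and ``"n"`` otherwise; with p > 0 the constant is the ARMA-equation
    intercept, so the implied process mean is ``intercept / (1 - sum(AR))``.
    """

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int] = (0, 0, 0)
    season_length: int = 12
    trend: str = "n"
    ar_coeffs: tuple[float, ...] = ()
    ma_coeffs: tuple[float, ...] = ()
    seasonal_ar_coeffs: tuple[float, ...] = ()
    seasonal_ma_coeffs: tuple[float, ...] = ()
    intercept: float = 0.0
    innovation_variance: float = 1.0
    information_criterion_value: float = float("nan")

    def __post_init__(self) -> None:
        p, d, q = self.order
        if min(self.order) < 0 or min(self.seasonal_order) < 0:
            raise ValueError("orders must be non-negative")
        if len(self.ar_coeffs) != p or len(self.ma_coeffs) != q:
            raise ValueError("coefficient counts must match (p, q)")
        P, D, Q = self.seasonal_order
        if len(self.seasonal_ar_coeffs) != P or len(self.seasonal_ma_coeffs) != Q:
            raise ValueError("seasonal coefficient counts must match (P, Q)")

    @property
    def is_degenerate(self) -> bool:
        return (self.order == (0, 0, 0) and self.seasonal_order == (0, 0, 0))

    def params_vector(self) -> np.ndarray:
        """Parameters in SARIMAX order: trend, AR, MA, sAR, sMA, sigma2."""
        head = [self.intercept] if self.trend == "c" else []
        return np.array(
            head
            + list(self.ar_coeffs)
            + list(self.ma_coeffs)
            + list(self.seasonal_ar_coeffs)
            + list(self.seasonal_ma_coeffs)
            + [max(self.innovation_variance, 1e-12)]
        )


def unit_root_diffs(series, max_d: int = 2, alpha: float = 0.05) -> int:
    """Number of first differences needed for KPSS-stationarity.

    Differences until the KPSS level test no longer rejects stationarity at
    ``alpha`` or ``max_d`` is reached.
    """
    x = np.asarray(series, dtype=float)
    for d in range(max_d + 1):
        if np.ptp(x) == 0:  # constant after differencing: stationary
            return d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                _, pvalue, *_ = kpss(x, regression="c", nlags="auto")
            except (ValueError, OverflowError):
                return d
        if pvalue >= alpha or d == max_d:
            return d
        x = np.diff(x)
    return max_d


def seasonal_strength(series, period: int) -> float:
    """STL-based seasonal strength: 1 - Var(remainder)/Var(seasonal+remainder).

    Clamped to [0, 1]; 0 for series too short to decompose.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2 * period + 1 or np.ptp(x) == 0:
        return 0.0
    res = STL(pd.Series(x), period=period, robust=True).fit()
    denom = np.var(res.seasonal + res.resid)
    if denom <= 0:
        return 0.0
    return float(np.clip(1.0 - np.var(res.resid) / denom, 0.0, 1.0))


def _fit_sarimax(y, order, seasonal_order, trend, s):
    sorder = (*seasonal_order, s) if any(seasonal_order) else (0, 0, 0, 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mod = SARIMAX(y, order=order, seasonal_order=sorder, trend=trend)
            res = mod.fit(disp=0, maxiter=100)
        except (np.linalg.LinAlgError, ValueError, IndexError):
            return None
    if not np.isfinite(res.aicc):
        return None
    return res


def _extract_arima(res, order, seasonal_order, trend, s) -> ArimaModel:
    names = res.model.param_names
    vals = dict(zip(names, np.asarray(res.params, dtype=float)))
    return ArimaModel(
        order=order,
        seasonal_order=seasonal_order,
        season_length=s,
        trend=trend,
        ar_coeffs=tuple(vals[n] for n in names if n.startswith("ar.L")),
        ma_coeffs=tuple(vals[n] for n in names if n.startswith("ma.L")),
        seasonal_ar_coeffs=tuple(vals[n] for n in names if n.startswith("ar.S.")),
        seasonal_ma_coeffs=tuple(vals[n] for n in names if n.startswith("ma.S.")),
        intercept=float(vals.get("intercept", 0.0)),
        innovation_variance=float(vals.get("sigma2", 1.0)),
        information_criterion_value=float(res.aicc),
    )


def fit_arima(series, *, seasonal: bool = True, season_length: int = 12,
              max_p: int = 3, max_q: int = 3, max_P: int = 1, max_Q: int = 1,
              max_d: int = 2, max_D: int = 1, stepwise: bool = True) -> ArimaModel:
    """Automatic seasonal ARIMA selection by AICc.

    Differencing orders are fixed first (KPSS for ``d``, seasonal strength
    for ``D``); then either a stepwise neighbourhood search from the usual
    four starting models, or — with ``stepwise=False`` — an exhaustive grid
    over ``p <= max_p, q <= max_q, P <= max_P, Q <= max_Q``. A constant is
    included only when ``d + D == 0``. Constant series short-circuit to a
    (0,0,0) model whose intercept is the constant.
    """
    y = np.asarray(series, dtype=float).ravel()
    if np.ptp(y) == 0:
        return ArimaModel((0, 0, 0), (0, 0, 0), season_length, "c",
                          intercept=float(y[0]), innovation_variance=0.0,
                          information_criterion_value=float("-inf"))
    if seasonal and len(y) < 3 * season_length:
        raise ValueError(
            f"seasonal fitting needs >= {3 * season_length} observations, got {len(y)}"
        )
    if len(y) < 10:
        raise ValueError(f"series too short for ARIMA fitting: {len(y)}")

    s = season_length if seasonal else 0
    D = 0
    if seasonal:
        D = 1 if (max_D >= 1 and
                  seasonal_strength(y, season_length) >= _SEASONAL_STRENGTH_THRESHOLD) else 0
        yd = np.diff(y, n=season_length) if D else y
    else:
        yd = y
    d = unit_root_diffs(yd, max_d=max_d)
    trend = "c" if d + D == 0 else "n"

    cache: dict[tuple[int, int, int, int], float] = {}
    best: tuple[float, tuple, object] | None = None

    def evaluate(p, q, P, Q):
        nonlocal best
        if not (0 <= p <= max_p and 0 <= q <= max_q
                and 0 <= P <= (max_P if seasonal else 0)
                and 0 <= Q <= (max_Q if seasonal else 0)):
            return
        key = (p, q, P, Q)
        if key in cache:
            return
        res = _fit_sarimax(y, (p, d, q), (P, D, Q), trend, s)
        aicc = float("inf") if res is None else float(res.aicc)
        cache[key] = aicc
        if res is not None and (best is None or aicc < best[0]):
            best = (aicc, key, res)

    if stepwise:
        starts = [(2, 2, 1, 1), (0, 0, 0, 0), (1, 0, 1, 0), (0, 1, 0, 1)]
        for p, q, P, Q in starts:
            evaluate(min(p, max_p), min(q, max_q), P, Q)
        improved = True
        while improved and best is not None:
            improved = False
            p, q, P, Q = best[1]
            neighbours = [(p + 1, q, P, Q), (p - 1, q, P, Q),
                          (p, q + 1, P, Q), (p, q - 1, P, Q),
                          (p + 1, q + 1, P, Q), (p - 1, q - 1, P, Q),
                          (p, q, P + 1, Q), (p, q, P - 1, Q),
                          (p, q, P, Q + 1), (p, q, P, Q - 1),
                          (p, q, P + 1, Q + 1), (p, q, P - 1, Q - 1)]
            before = best[1]
            for cand in neighbours:
                evaluate(*cand)
            improved = best[1] != before
    else:
        for p in range(max_p + 1):
            for q in range(max_q + 1):
                for P in range((max_P if seasonal else 0) + 1):
                    for Q in range((max_Q if seasonal else 0) + 1):
                        evaluate(p, q, P, Q)

    if best is None:
        raise NumericalError("no ARIMA candidate could be estimated")
    _, (p, q, P, Q), res = best
    return _extract_arima(res, (p, d, q), (P, D, Q), trend, s or season_length)


def forecast_arima(model: ArimaModel, history, h: int) -> np.ndarray:
    """Deterministic h-step point forecasts of ``model`` applied to ``history``.

    The model is re-anchored to the given history via a Kalman-filter pass
    with the frozen parameters, so the same model can forecast from any
    series (e.g. after extending the estimation sample).
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    y = np.asarray(history, dtype=float).ravel()
    if model.is_degenerate:
        return np.full(h, model.intercept, dtype=float)
    sorder = ((*model.seasonal_order, model.season_length)
              if any(model.seasonal_order) else (0, 0, 0, 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = SARIMAX(y, order=model.order, seasonal_order=sorder, trend=model.trend)
        res = mod.filter(model.params_vector())
        return np.asarray(res.forecast(h), dtype=float)


# --------------------------------------------------------------------------
# Holt-Winters / ETS
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EtsState:
    """Frozen end-of-sample state of a Holt-Winters smoother.

    ``seasonal_indices[k]`` is the index used ``k + 1`` steps ahead (then
    cyclically); multiplicative indices are renormalized to average 1, with
    the scale folded into level and trend so forecasts are unchanged.
    """

    alpha: float
    beta: float
    gamma: float
    level: float
    trend: float
    seasonal_indices: tuple[float, ...]
    season_length: int
    seasonal_mode: str  # "multiplicative" | "additive"
    information_criterion_value: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.seasonal_mode not in ("multiplicative", "additive"):
            raise ValueError(f"unknown seasonal_mode {self.seasonal_mode!r}")
        if len(self.seasonal_indices) != self.season_length:
            raise ValueError("need one seasonal index per season position")


def _normalized_state(alpha, beta, gamma, level, trend, seas, s, mode, aicc):
    seas = np.asarray(seas, dtype=float)
    if mode == "multiplicative":
        scale = seas.mean()
        seas, level, trend = seas / scale, level * scale, trend * scale
    else:
        shift = seas.mean()
        seas, level = seas - shift, level + shift
    return EtsState(alpha, beta, gamma, float(level), float(trend),
                    tuple(float(v) for v in seas), s, mode, aicc)


def _fit_hw(y, mode: str, s: int):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = ExponentialSmoothing(
            y, trend="add",
            seasonal="mul" if mode == "multiplicative" else "add",
            seasonal_periods=s, initialization_method="estimated")
        return mod.fit(optimized=True)


def fit_ets(series, seasonal_mode: str = "auto", season_length: int = 12) -> EtsState:
    """Fit a Holt-Winters smoother with additive trend and seasonal cycle.

    ``seasonal_mode`` may be ``"multiplicative"``, ``"additive"`` or
    ``"auto"`` (fit both where admissible, keep the lower AICc).
    Multiplicative seasonality requires strictly positive observations.
    """
    y = np.asarray(series, dtype=float).ravel()
    s = season_length
    if len(y) < 2 * s:
        raise ValueError(f"need >= {2 * s} observations, got {len(y)}")
    if seasonal_mode not in ("auto", "multiplicative", "additive"):
        raise ValueError(f"unknown seasonal_mode {seasonal_mode!r}")
    positive = bool(np.all(y > 0))
    if seasonal_mode == "multiplicative" and not positive:
        raise ValueError("multiplicative seasonality requires strictly positive values")
    if np.ptp(y) == 0:
        mode = "additive" if seasonal_mode == "additive" else "multiplicative"
        seas = (1.0,) * s if mode == "multiplicative" else (0.0,) * s
        return EtsState(0.0, 0.0, 0.0, float(y[0]), 0.0, seas, s, mode)

    candidates = []
    modes = {"auto": (["multiplicative"] if positive else []) + ["additive"],
             "multiplicative": ["multiplicative"],
             "additive": ["additive"]}[seasonal_mode]
    for mode in modes:
        try:
            res = _fit_hw(y, mode, s)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if np.isfinite(res.aicc):
            candidates.append((float(res.aicc), mode, res))
    if not candidates:
        raise NumericalError("Holt-Winters estimation failed in every admissible mode")
    aicc, mode, res = min(candidates, key=lambda c: c[0])
    p = res.params
    seas_tail = np.asarray(res.season)[-s:]
    return _normalized_state(
        float(np.clip(p["smoothing_level"], 0, 1)),
        float(np.clip(p.get("smoothing_trend", 0.0), 0, 1)),
        float(np.clip(p.get("smoothing_seasonal", 0.0), 0, 1)),
        float(np.asarray(res.level)[-1]), float(np.asarray(res.trend)[-1]),
        seas_tail, s, mode, aicc)


def forecast_ets(state: EtsState, h: int) -> np.ndarray:
    """Closed-form h-step forecasts from a frozen Holt-Winters state.

    Step ``k`` ahead: ``(level + k*trend) (x or +) seasonal index`` of the
    matching season position.
    """
    if h < 1:
        raise ValueError("horizon must be >= 1")
    steps = np.arange(1, h + 1)
    base = state.level + steps * state.trend
    seas = np.asarray(state.seasonal_indices)[(steps - 1) % state.season_length]
    if state.seasonal_mode == "multiplicative":
        return base * seas
    return base + seas


# --------------------------------------------------------------------------
# Multi-node convenience layer
# --------------------------------------------------------------------------

def fit_all_nodes(data: pd.DataFrame, model: str, *, season_length: int = 12,
                  seasonal_mode: str = "auto", **arima_kwargs) -> dict:
    """Fit one base forecaster per column of a (periods x nodes) frame."""
    if model not in ("arima", "ets"):
        raise ValueError(f"unknown base model {model!r}")
    fitted = {}
    for node in data.columns:
        y = data[node].to_numpy(dtype=float)
        if model == "arima":
            fitted[node] = fit_arima(y, season_length=season_length, **arima_kwargs)
        else:
            fitted[node] = fit_ets(y, seasonal_mode=seasonal_mode,
                                   season_length=season_length)
    return fitted


def forecast_all_nodes(fitted: dict, data: pd.DataFrame, h: int):
    """h-step base forecasts for every fitted node, as a BaseForecastSet."""
    from .reconciliation import BaseForecastSet

    cols = {}
    provenance = {}
    for node, model in fitted.items():
        if isinstance(model, ArimaModel):
            cols[node] = forecast_arima(model, data[node].to_numpy(dtype=float), h)
            provenance[node] = "arima"
        else:
            cols[node] = forecast_ets(model, h)
            provenance[node] = "ets"
    idx = pd.period_range(data.index[-1] + 1, periods=h, freq="M") \
        if isinstance(data.index, pd.PeriodIndex) else pd.RangeIndex(1, h + 1, name="step")
    frame = pd.DataFrame(cols, index=idx)[list(data.columns)]
    return BaseForecastSet(frame, provenance)
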