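"""Packaged reference tables from the national blood service case study.

Two small tables ship with the package:

* the 2019/2020 monthly validation table — actual total donations against
  the model's point forecasts, whose yearly MAPEs (14.80 pre-pandemic,
  84.06 during the Covid-19 collapse) are the published validation result;
* the published average-MAPE row of the method x base-model evaluation
  grid, used to exercise the selection rule when the underlying registry
  data is unavailable.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import AccuracyTable

__all__ = ["load_validation_table", "published_average_mape_row"]


def load_validation_table() -> pd.DataFrame:
    """Monthly actual/forecast totals for 2019 and 2020.

    Returns a frame indexed by monthly period (2019-01..2020-12) with
    columns ``actual`` and ``forecast``.
    """
    ref = resources.files("bloodhts").joinpath("data/validation_2019_2020.csv")
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path)
    frames = []
    for year in (2019, 2020):
        idx = pd.period_range(f"{year}-01", periods=12, freq="M")
        frames.append(pd.DataFrame({
            "actual": raw[f"actual_{year}"].to_numpy(dtype=float),
            "forecast": raw[f"forecast_{year}"].to_numpy(dtype=float),
        }, index=idx))
    return pd.concat(frames)


#: Published average MAPE (%) per (base model, reconciliation method).
_PUBLISHED_AVERAGE = {
    ("ets", "bu"): 12.58, ("ets", "tdfp"): 12.65, ("ets", "tdha"): 12.62,
    ("ets", "tdhp"): 12.43, ("ets", "oc"): 12.57,
    ("arima", "bu"): 12.0, ("arima", "tdfp"): 11.3, ("arima", "tdha"): 11.52,
    ("arima", "tdhp"): 11.52, ("arima", "oc"): 11.52,
}


def published_average_mape_row() -> AccuracyTable:
    """The published evaluation grid's Average row as an AccuracyTable."""
    return AccuracyTable.from_average_row(dict(_PUBLISHED_AVERAGE))
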