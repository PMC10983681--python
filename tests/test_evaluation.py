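import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bloodhts as b
from bloodhts.errors import ChronologyError, ZeroActualError
from bloodhts.evaluation import METHOD_ORDER, MODEL_ORDER
from bloodhts.fixtures import load_validation_table, published_average_mape_row


class TestMape:
    def test_perfect_forecast_is_zero(self):
        assert b.mape([3.0, 4.0], [3.0, 4.0]) == 0.0

    def test_simple_ten_percent(self):
        assert b.mape([100.0], [90.0]) == pytest.approx(10.0)

    def test_zero_actual_rejected_not_skipped(self):
        with pytest.raises(ZeroActualError):
            b.mape([1.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            b.mape([1.0, 2.0], [1.0])

    @given(st.floats(0.01, 1000.0), st.integers(0, 50))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(10, 100, 12)
        yhat = y + rng.normal(0, 5, 12)
        assert b.mape(c * y, c * yhat) == pytest.approx(b.mape(y, yhat), rel=1e-9)

    @given(st.integers(0, 50))
    def test_zero_iff_exact(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(10, 100, 8)
        yhat = y.copy()
        yhat[3] += 0.5
        assert b.mape(y, y) == 0.0
        assert b.mape(y, yhat) > 0.0


class TestValidationFixture:
    def test_pre_pandemic_year_mape(self):
        t = load_validation_table()
        sub = t[t.index.year == 2019]
        assert round(b.mape(sub["actual"], sub["forecast"]), 2) == 14.80

    def test_pandemic_year_mape(self):
        t = load_validation_table()
        sub = t[t.index.year == 2020]
        assert round(b.mape(sub["actual"], sub["forecast"]), 2) == 84.06

    def test_validate_holdout_on_fixture(self, summing):
        t = load_validation_table()
        idx = t.index
        actual = pd.DataFrame({"Total": t["actual"]}, index=idx)
        # wrap the totals column as a 1-node hierarchy for the report
        spec1 = b.HierarchySpec.from_children({"Total": ["x"]})
        frame = pd.DataFrame({"Total": t["forecast"], "x": t["forecast"]}, index=idx)
        series = b.HierarchicalSeries(
            pd.DataFrame({"Total": t["actual"], "x": t["actual"]}, index=idx))
        report = b.validate_holdout(frame, series, "Total")
        assert report.yearly_mape[2019] == pytest.approx(14.80, abs=0.005)
        assert report.yearly_mape[2020] == pytest.approx(84.06, abs=0.005)
        assert report.overall_mape == pytest.approx(np.mean(report.frame["ape"]))

    def test_identical_forecasts_give_zero_apes(self):
        idx = pd.period_range("2019-01", periods=6, freq="M")
        data = pd.DataFrame({"Total": np.arange(6) + 10.0, "x": np.arange(6) + 10.0},
                            index=idx)
        series = b.HierarchicalSeries(data)
        report = b.validate_holdout(data, series, "Total")
        assert (report.frame["ape"] == 0).all()


class TestAccuracyTable:
    def test_average_row_is_mean_of_node_rows(self, spec):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_product([MODEL_ORDER, METHOD_ORDER])
        rows = pd.DataFrame(rng.uniform(5, 20, size=(11, 10)),
                            index=list(spec.nodes), columns=cols)
        table = b.AccuracyTable.from_node_rows(rows)
        recomputed = rows.mean(axis=0)
        assert np.allclose(table.average_row, recomputed, atol=1e-9)

    def test_negative_cells_rejected(self, spec):
        cols = pd.MultiIndex.from_product([("ets",), ("bu",)])
        rows = pd.DataFrame([[-1.0]] * 2, index=["Total", "M"], columns=cols)
        with pytest.raises(ValueError):
            b.AccuracyTable.from_node_rows(rows)

    def test_injected_perfect_forecasts_give_zero_cells(self, spec, summing):
        # degenerate check via the BU invariant: if base bottom forecasts
        # equal the holdout, BU cells are exactly zero at bottom nodes
        from bloodhts.reconciliation import BaseForecastSet

        rng = np.random.default_rng(1)
        bottom = rng.uniform(100, 200, size=(6, 8))
        holdout = b.aggregate(bottom, summing, start="2019-01")
        base = BaseForecastSet(holdout.data.copy())
        rec = b.bottom_up(base, summing)
        for node in spec.nodes:
            assert b.mape(holdout.data[node], rec.forecasts[node]) == 0.0


class TestSelectBest:
    def test_published_average_row_selects_tdfp_under_arima(self):
        table = published_average_mape_row()
        method, model = b.select_best(table)
        assert (method, model) == ("tdfp", "arima")
        assert round(table.average_row[("arima", "tdfp")], 2) == 11.30

    def test_single_column(self):
        table = b.AccuracyTable.from_average_row({("ets", "bu"): 9.9})
        assert b.select_best(table) == ("bu", "ets")

    def test_tie_breaks_on_declared_order(self, caplog):
        table = b.AccuracyTable.from_average_row(
            {("ets", "bu"): 5.0, ("ets", "tdfp"): 5.0, ("arima", "bu"): 7.0})
        with caplog.at_level("INFO"):
            assert b.select_best(table) == ("bu", "ets")

    def test_empty_table_rejected(self):
        table = published_average_mape_row()
        empty = b.AccuracyTable(table.table.iloc[:, :0])
        with pytest.raises(ValueError):
            b.select_best(empty)


class TestAccuracyTableEndToEnd:
    def test_chronology_enforced(self, series144, spec):
        history, holdout = series144.split(12)
        with pytest.raises(ChronologyError):
            b.accuracy_table(history, history, spec,
                             methods=("bu",), base_models=("ets",))

    def test_ets_only_table_shape_and_bu_invariant(self, series144, spec, summing):
        # BU leaves bottom forecasts unchanged, so its bottom-node cells
        # equal the unreconciled base-forecast MAPE
        from bloodhts.base_forecasters import fit_all_nodes, forecast_all_nodes

        history, holdout = series144.split(12)
        table = b.accuracy_table(history, holdout, spec,
                                 methods=("bu", "oc"), base_models=("ets",))
        assert list(table.table.index) == list(spec.nodes) + ["Average"]
        assert table.table.shape == (12, 2)
        fitted = fit_all_nodes(history.data, "ets")
        base = forecast_all_nodes(fitted, history.data, 12)
        for node in spec.bottom_nodes:
            raw = b.mape(holdout.data[node], base.forecasts[node])
            assert table.table.loc[node, ("ets", "bu")] == pytest.approx(raw, abs=1e-9)
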