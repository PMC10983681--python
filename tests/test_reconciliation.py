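import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bloodhts as b
from bloodhts.errors import (
    IncompleteForecastError,
    ZeroDenominatorError,
    ZeroTotalError,
)
from bloodhts.reconciliation import BaseForecastSet

from conftest import random_balanced_children


def base_set(spec, rows):
    frame = pd.DataFrame(np.atleast_2d(np.asarray(rows, dtype=float)),
                         columns=list(spec.nodes))
    return BaseForecastSet(frame)


def series_from_bottom(spec, bottom, start="2007-01"):
    S = b.build_summing_matrix(spec)
    return b.aggregate(np.atleast_2d(np.asarray(bottom, dtype=float)), S, start=start)


class TestBottomUp:
    def test_sums_published_jan19_bottom_row(self, spec, summing):
        bottoms = [913, 698, 148, 1906, 721, 544, 116, 1496]
        base = base_set(spec, [0, 0, 0] + bottoms)  # upper bases are ignored
        rec = b.bottom_up(base, summing)
        row = rec.forecasts.iloc[0]
        assert (row["M"], row["F"], row["Total"]) == (3665, 2877, 6542)
        assert list(row[list(summing.col_labels)]) == bottoms

    def test_unit_bottom_forecasts(self, spec, summing):
        rec = b.bottom_up(base_set(spec, [99, 99, 99] + [1] * 8), summing)
        row = rec.forecasts.iloc[0]
        assert row["M"] == 4 and row["F"] == 4 and row["Total"] == 8

    def test_idempotence(self, spec, summing):
        rng = np.random.default_rng(0)
        base = base_set(spec, rng.uniform(1, 100, 11))
        once = b.bottom_up(base, summing)
        twice = b.bottom_up(BaseForecastSet(once.forecasts), summing)
        pd.testing.assert_frame_equal(once.forecasts, twice.forecasts)

    def test_missing_bottom_node_raises(self, summing):
        frame = pd.DataFrame([[1.0, 2.0]], columns=["A_M", "B_M"])
        with pytest.raises(IncompleteForecastError):
            b.bottom_up(BaseForecastSet(frame), summing)


class TestHistoricalProportions:
    def test_constant_shares(self):
        spec = b.HierarchySpec.from_children({"T": ["x", "y"]})
        series = series_from_bottom(spec, [[3, 7], [30, 70], [0.3, 0.7]])
        ahp = b.average_historical_proportions(series, spec)
        pha = b.proportions_of_historical_averages(series, spec)
        assert np.allclose(ahp.proportions, [[0.3, 0.7]])
        assert np.allclose(pha.proportions, [[30.3 / 101.0, 70.7 / 101.0]])

    def test_symmetric_two_period_case(self):
        spec = b.HierarchySpec.from_children({"T": ["x", "y"]})
        series = series_from_bottom(spec, [[1, 3], [3, 1]])
        for props in (b.average_historical_proportions(series, spec),
                      b.proportions_of_historical_averages(series, spec)):
            assert np.allclose(props.proportions, [[0.5, 0.5]])

    def test_against_literal_loop_oracles(self, spec):
        rng = np.random.default_rng(77)
        bottom = rng.uniform(50, 500, size=(24, 8))
        series = series_from_bottom(spec, bottom)
        data = series.data
        total = data["Total"].to_numpy()
        ahp = b.average_historical_proportions(series, spec)
        pha = b.proportions_of_historical_averages(series, spec)
        for j, node in enumerate(spec.bottom_nodes):
            y = data[node].to_numpy()
            ahp_oracle = sum(y[t] / total[t] for t in range(24)) / 24
            pha_oracle = (y.sum() / 24) / (total.sum() / 24)
            assert ahp.proportions[node].iloc[0] == pytest.approx(ahp_oracle, abs=1e-12)
            assert pha.proportions[node].iloc[0] == pytest.approx(pha_oracle, abs=1e-12)

    def test_single_spike_separates_ahp_from_pha(self):
        spec = b.HierarchySpec.from_children({"T": ["x", "y"]})
        bottom = np.full((12, 2), 10.0)
        bottom[3, 0] = 1000.0  # one huge month for x
        series = series_from_bottom(spec, bottom)
        ahp = b.average_historical_proportions(series, spec).proportions["x"].iloc[0]
        pha = b.proportions_of_historical_averages(series, spec).proportions["x"].iloc[0]
        assert abs(ahp - pha) > 0.05

    def test_zero_total_rejected(self):
        spec = b.HierarchySpec.from_children({"T": ["x", "y"]})
        series = series_from_bottom(spec, [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ZeroTotalError):
            b.average_historical_proportions(series, spec)

    def test_within_parent_variant_matches_default_under_constant_shares(self, spec):
        bottom = np.outer(np.linspace(100, 120, 10),
                          [0.15, 0.1, 0.05, 0.24, 0.13, 0.09, 0.04, 0.2])
        series = series_from_bottom(spec, bottom)
        flat = b.average_historical_proportions(series, spec)
        nested = b.average_historical_proportions(series, spec, within_parent=True)
        assert np.allclose(flat.proportions, nested.proportions)


class TestForecastProportions:
    def test_only_children_give_unit_proportions(self):
        spec = b.HierarchySpec.from_children({"T": ["m"], "m": ["x"]})
        base = base_set(spec, [5.0, 3.0, 2.0])
        props = b.forecast_proportions(base, spec)
        assert np.allclose(props.proportions, 1.0)

    def test_worked_two_stage_example(self, spec):
        # M-hat = F-hat = 100; female groups A/B/AB/O = 20/15/10/55
        base = base_set(spec, [999, 100, 100, 25, 25, 25, 25, 20, 15, 10, 55])
        props = b.forecast_proportions(base, spec)
        assert props.proportions["O_F"].iloc[0] == pytest.approx(0.275, abs=1e-12)

    @given(st.integers(0, 300))
    def test_step_proportions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        spec = b.HierarchySpec.from_children(random_balanced_children(rng))
        frame = pd.DataFrame(rng.uniform(0.5, 100, size=(4, len(spec.nodes))),
                             columns=list(spec.nodes))
        props = b.forecast_proportions(BaseForecastSet(frame), spec)
        assert np.allclose(props.proportions.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_sibling_sum_rejected(self, spec):
        base = base_set(spec, [1.0, 0.0, 0.0] + [0.0] * 8)
        with pytest.raises(ZeroDenominatorError):
            b.forecast_proportions(base, spec)


class TestTopDown:
    def test_intro_shares_split(self):
        spec = b.HierarchySpec.from_children({"F": ["O_F", "A_F", "B_F", "AB_F"]})
        S = b.build_summing_matrix(spec)
        props = b.ProportionSet("ahp", pd.DataFrame(
            [[0.54, 0.24, 0.18, 0.04]], columns=["O_F", "A_F", "B_F", "AB_F"]))
        rec = b.top_down([1000.0], props, S)
        assert np.allclose(rec.forecasts.iloc[0][["O_F", "A_F", "B_F", "AB_F"]],
                           [540, 240, 180, 40])

    def test_concentrated_proportion(self, spec, summing):
        p = np.zeros(8)
        p[0] = 1.0
        props = b.ProportionSet("pha", pd.DataFrame([p], columns=list(summing.col_labels)))
        rec = b.top_down([123.0], props, summing)
        assert rec.forecasts.iloc[0]["A_M"] == pytest.approx(123.0)

    def test_disaggregate_then_reaggregate_conserves_top(self, spec, summing):
        rng = np.random.default_rng(8)
        p = rng.dirichlet(np.ones(8))
        props = b.ProportionSet("ahp", pd.DataFrame([p], columns=list(summing.col_labels)))
        top = rng.uniform(100, 1000, 6)
        rec = b.top_down(top, props, summing)
        assert np.allclose(rec.forecasts["Total"].to_numpy(), top, atol=1e-9)


class TestOptimalCombination:
    def test_hand_worked_single_child(self):
        spec = b.HierarchySpec.from_children({"Total": ["X"]})
        S = b.build_summing_matrix(spec)
        base = BaseForecastSet(pd.DataFrame([[10.0, 6.0]], columns=["Total", "X"]))
        rec = b.optimal_combination(base, S)
        assert np.allclose(rec.forecasts.to_numpy(), [[8.0, 8.0]], atol=1e-9)

    def test_hand_worked_two_children(self):
        spec = b.HierarchySpec.from_children({"T": ["c1", "c2"]})
        S = b.build_summing_matrix(spec)
        base = BaseForecastSet(pd.DataFrame([[10.0, 4.0, 4.0]],
                                            columns=["T", "c1", "c2"]))
        rec = b.optimal_combination(base, S)
        assert np.allclose(rec.forecasts.to_numpy(),
                           [[28 / 3, 14 / 3, 14 / 3]], atol=1e-9)

    def test_coherent_input_is_fixed_point(self, spec, summing):
        rng = np.random.default_rng(21)
        bottom = rng.uniform(10, 100, size=(5, 8))
        coherent = bottom @ summing.entries.T
        base = BaseForecastSet(pd.DataFrame(coherent, columns=list(spec.nodes)))
        rec = b.optimal_combination(base, summing)
        assert np.allclose(rec.forecasts.to_numpy(), coherent, atol=1e-9)

    def test_diagonal_weights_still_coherent(self, spec, summing):
        rng = np.random.default_rng(3)
        base = BaseForecastSet(pd.DataFrame(rng.uniform(1, 100, size=(3, 11)),
                                            columns=list(spec.nodes)))
        rec = b.optimal_combination(base, summing, weights=rng.uniform(0.5, 2.0, 11))
        series = b.HierarchicalSeries(rec.forecasts.set_axis(
            pd.period_range("2019-01", periods=3, freq="M")))
        assert b.check_coherence(series, summing, tol=1e-6).passed


class TestReconcileDispatch:
    @pytest.mark.parametrize("method", ["bu", "tdfp", "tdha", "tdhp", "oc"])
    def test_all_methods_produce_coherent_sets(self, method, spec, summing):
        rng = np.random.default_rng(4)
        history = series_from_bottom(spec, rng.uniform(50, 500, size=(36, 8)))
        base = BaseForecastSet(pd.DataFrame(rng.uniform(10, 1000, size=(6, 11)),
                                            columns=list(spec.nodes)))
        rec = b.reconcile(method, base, summing, spec, history)
        series = b.HierarchicalSeries(rec.forecasts.set_axis(
            pd.period_range("2010-01", periods=6, freq="M")))
        assert b.check_coherence(series, summing, tol=1e-6).passed
        assert rec.method == method

    def test_unknown_method_rejected(self, spec, summing):
        base = BaseForecastSet(pd.DataFrame(np.ones((1, 11)), columns=list(spec.nodes)))
        with pytest.raises(ValueError):
            b.reconcile("mint", base, summing, spec)
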