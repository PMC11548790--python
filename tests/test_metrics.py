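import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sparsemet.metrics import (
    PartitionMetrics,
    aggregate,
    evaluate_partition,
    nrmse,
    pearson_cor,
    percent_matching,
    relative_efficiency,
)


class TestPearsonCor:
    def test_perfect_and_antiperfect(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_cor(x, x) == pytest.approx(1.0)
        assert pearson_cor(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_cor([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cor([1, 1, 1], [1, 2, 3])


class TestNRMSE:
    def test_perfect_prediction(self):
        assert nrmse([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_shift(self):
        assert nrmse([2, 2, 2], [3, 3, 3]) == pytest.approx(0.5)

    def test_hand_computed_value(self):
        # RMSE = sqrt(9/3) = sqrt(3); mean obs = 2 -> NRMSE = sqrt(3)/2
        assert nrmse([1, 2, 3], [1, 2, 6]) == pytest.approx(np.sqrt(3) / 2)

    def test_zero_mean_suggests_sd(self):
        with pytest.raises(ValueError, match="sd"):
            nrmse([-1, 0, 1], [0, 0, 0])
        assert nrmse([-1, 0, 1], [0, 0, 0], normalizer="sd") > 0

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=12),
        st.floats(0.1, 50.0),
    )
    def test_scale_invariance_of_mean_normalization(self, obs, c):
        obs = np.asarray(obs)
        pred = obs + 1.0
        assert nrmse(c * obs, c * pred) == pytest.approx(nrmse(obs, pred), rel=1e-9)


class TestPercentMatching:
    def test_identical_ranking_is_100(self):
        s = pd.Series(np.arange(10.0), index=[f"L{i}" for i in range(10)])
        assert percent_matching(s, s * 3 + 1, 0.2) == 100.0

    def test_disjoint_and_half_overlap(self):
        obs = pd.Series(np.arange(10.0), index=[f"L{i}" for i in range(10)])
        pred = pd.Series(-np.arange(10.0), index=obs.index)
        assert percent_matching(obs, pred, 0.2) == 0.0
        # swap one of the top-2 into the predicted top-2
        pred2 = obs.copy()
        pred2["L9"] = -5.0  # drop the best line out of the predicted top set
        assert percent_matching(obs, pred2, 0.2) == 50.0

    def test_ceil_top_set_size(self):
        obs = pd.Series(np.arange(7.0), index=[f"L{i}" for i in range(7)])
        # ceil(0.2*7) = 2 lines; worst case overlap granularity is 50%
        assert percent_matching(obs, obs, 0.2) == 100.0

    @settings(max_examples=30, deadline=None)
    @given(st.permutations(list(range(8))), st.floats(0.11, 0.9))
    def test_invariance_to_monotone_transforms(self, ranks, frac):
        obs = pd.Series(np.array(ranks, dtype=float), index=[f"L{i}" for i in range(8)])
        pred = pd.Series(np.arange(8.0), index=obs.index)
        base = percent_matching(obs, pred, frac)
        assert percent_matching(np.exp(obs / 4.0), pred, frac) == base
        assert percent_matching(obs, pred * 7.0 + 2.0, frac) == base


class TestRelativeEfficiency:
    def test_equal_means_are_neutral(self):
        for kind in ("cor", "pm", "nrmse"):
            re, gain = relative_efficiency(0.8, 0.8, kind)
            assert re == 100.0 and gain == 0.0

    def test_cor_ratio(self):
        re, gain = relative_efficiency(0.90, 0.75, "cor")
        assert re == pytest.approx(120.0)
        assert gain == pytest.approx(20.0)

    def test_nrmse_ratio_is_inverted(self):
        re, gain = relative_efficiency(0.50, 0.60, "nrmse")
        assert re == pytest.approx(120.0)
        assert gain == pytest.approx(20.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.05, 5.0), st.floats(0.05, 5.0))
    def test_antisymmetry(self, a, b):
        re_ab, _ = relative_efficiency(a, b, "cor")
        re_ba, _ = relative_efficiency(b, a, "cor")
        assert re_ab * re_ba == pytest.approx(1e4, rel=1e-9)


class TestEvaluatePartition:
    def _toy(self):
        obs = pd.DataFrame(
            {
                "line": ["L1", "L1", "L2", "L2", "L3", "L4", "L5", "L5", "L6", "L6"],
                "env": ["E1", "E2", "E1", "E2", "E1", "E2", "E1", "E2", "E1", "E2"],
                "value": [4.0, 6.0, 3.0, 5.0, 8.0, 2.0, 7.0, 9.0, 1.0, 3.0],
            }
        )
        return obs

    def test_perfect_predictor(self):
        obs = self._toy()
        pred = pd.Series(
            obs["value"].to_numpy(),
            index=pd.MultiIndex.from_frame(obs[["line", "env"]]),
        )
        (m,) = evaluate_partition(obs, {"M": pred})
        assert m.cor == pytest.approx(1.0)
        assert m.nrmse == 0.0
        assert m.pm_10 == m.pm_20 == 100.0
        assert m.n_test_cells == len(obs)

    def test_constant_shift_keeps_ranking(self):
        obs = self._toy()
        shift = 2.0
        pred = pd.Series(
            obs["value"].to_numpy() + shift,
            index=pd.MultiIndex.from_frame(obs[["line", "env"]]),
        )
        (m,) = evaluate_partition(obs, {"M": pred})
        assert m.cor == pytest.approx(1.0)
        assert m.pm_10 == m.pm_20 == 100.0
        assert m.nrmse == pytest.approx(shift / obs["value"].mean())

    def test_hand_built_fixture_all_four_metrics(self):
        obs = self._toy()
        yhat = np.array([4.5, 5.5, 3.5, 4.5, 7.0, 3.0, 8.0, 8.0, 2.0, 2.0])
        pred = pd.Series(
            yhat, index=pd.MultiIndex.from_frame(obs[["line", "env"]])
        )
        (m,) = evaluate_partition(obs, {"M": pred})
        y = obs["value"].to_numpy()
        # independent arithmetic for the same quantities
        exp_cor = np.corrcoef(y, yhat)[0, 1]
        exp_nrmse = np.sqrt(np.mean((y - yhat) ** 2)) / y.mean()
        assert m.cor == pytest.approx(exp_cor)
        assert m.nrmse == pytest.approx(exp_nrmse)
        # line means: obs L1..L6 = 5,4,8,2,8,2 ; pred = 5,4,7,3,8,2
        # top-1 (10% of 6 -> ceil = 1): obs L3 (tie L3/L5 broken by id), pred L5 -> 0
        assert m.pm_10 == 0.0
        # top-2: obs {L3,L5}, pred {L5,L3} -> 100
        assert m.pm_20 == 100.0

    def test_line_scores_route_replicates_scores_over_cells(self):
        obs = self._toy()
        scores = pd.Series(
            [5.0, 4.0, 8.0, 2.0, 8.5, 1.0],
            index=["L1", "L2", "L3", "L4", "L5", "L6"],
        )
        (m,) = evaluate_partition(obs, {}, {"TRN": scores})
        yhat = scores.loc[obs["line"]].to_numpy()
        assert m.cor == pytest.approx(np.corrcoef(obs["value"], yhat)[0, 1])
        assert m.method_tag == "TRN"

    def test_missing_predictions_are_reported(self):
        obs = self._toy()
        pred = pd.Series(
            [1.0], index=pd.MultiIndex.from_tuples([("L1", "E1")])
        )
        with pytest.raises(ValueError, match="missing predictions"):
            evaluate_partition(obs, {"M": pred})


def _pm(cor, nr, p10, p20, method, alloc, part):
    return PartitionMetrics(cor, nr, p10, p20, method, alloc, part)


class TestAggregate:
    def test_two_partition_mean_and_sd(self):
        recs = [
            _pm(0.8, 0.5, 50, 60, "GBLUP", "IBD", 0),
            _pm(0.9, 0.4, 70, 80, "GBLUP", "IBD", 1),
            _pm(0.9, 0.45, 60, 70, "GBLUP_TRN", "IBD", 0),
            _pm(0.95, 0.35, 80, 90, "GBLUP_TRN", "IBD", 1),
        ]
        rep = aggregate(recs)
        row = rep.summary.set_index("method").loc["GBLUP"]
        assert row["cor_mean"] == pytest.approx(0.85)
        assert row["cor_sd"] == pytest.approx(np.std([0.8, 0.9], ddof=1))
        re_row = rep.relative_efficiencies.iloc[0]
        assert re_row["re_cor"] == pytest.approx(100 * 0.925 / 0.85)
        assert re_row["re_nrmse"] == pytest.approx(100 * 0.45 / 0.40)

    def test_single_partition_sd_zero_with_flag(self):
        rep = aggregate([_pm(0.8, 0.5, 50, 60, "GBLUP", "IBD", 0)])
        assert rep.single_partition_flag
        assert rep.summary["cor_sd"].iloc[0] == 0.0

    def test_partition_order_irrelevant(self):
        recs = [
            _pm(0.8, 0.5, 50, 60, "GBLUP", "IBD", 0),
            _pm(0.9, 0.4, 70, 80, "GBLUP", "IBD", 1),
        ]
        a = aggregate(recs).summary
        b = aggregate(recs[::-1]).summary
        pd.testing.assert_frame_equal(
            a, b.sort_values(list(a.columns[:2])).reset_index(drop=True)
        )

    def test_across_dataset_average_is_unweighted(self):
        d1 = [_pm(0.8, 0.5, 50, 60, "GBLUP", "IBD", i) for i in range(2)]
        d2 = [_pm(0.6, 0.7, 30, 40, "GBLUP", "IBD", i) for i in range(4)]
        rep = aggregate({"A": d1, "B": d2})
        across = rep.across_datasets.set_index("method").loc["GBLUP"]
        assert across["cor"] == pytest.approx(0.7)  # mean of dataset means
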