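import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaqsar.evaluation import (
    armser,
    comparison_report,
    friedman_nemenyi,
    friedman_null_rejection_rate,
    relative_rmse_reduction,
    spearman_agreement,
    wilcoxon_default_comparison,
)


def _armser_oracle(matrix: pd.DataFrame) -> pd.Series:
    """Direct product/root evaluation of the RMSE-ratio score."""
    cols = list(matrix.columns)
    m = len(cols)
    out = {}
    for p in cols:
        total = 0.0
        for q in cols:
            if q == p:
                total += 1.0
                continue
            ratios = (matrix[q] / matrix[p]).dropna()
            total += float(np.prod(ratios) ** (1.0 / len(ratios)))
        out[p] = total / m
    return pd.Series(out)


class TestArmser:
    def test_all_equal_matrix_gives_unit_scores(self):
        matrix = pd.DataFrame(0.7, index=list("abcde"), columns=list("xyz"))
        assert np.allclose(armser(matrix).to_numpy(), 1.0)

    def test_two_workflow_half_rmse_case(self):
        # p always has half of q's RMSE: scores (1+2)/2 and (1+0.5)/2
        matrix = pd.DataFrame({"p": [0.2, 0.3, 0.1], "q": [0.4, 0.6, 0.2]})
        scores = armser(matrix)
        assert scores["p"] == pytest.approx(1.5)
        assert scores["q"] == pytest.approx(0.75)

    def test_log_sum_agrees_with_direct_products(self, rng):
        for _ in range(5):
            matrix = pd.DataFrame(
                rng.uniform(0.05, 2.0, (5, 4)), columns=list("abcd")
            )
            got = armser(matrix)
            want = _armser_oracle(matrix)
            assert np.allclose(got.to_numpy(), want[got.index].to_numpy(),
                               atol=1e-10)

    def test_per_target_rescaling_invariance(self, rng):
        matrix = pd.DataFrame(rng.uniform(0.1, 1.0, (6, 3)), columns=list("abc"))
        scaled = matrix.mul(rng.uniform(0.5, 5.0, 6), axis=0)
        assert np.allclose(
            armser(matrix).to_numpy(), armser(scaled).to_numpy(), atol=1e-12
        )

    def test_missing_pairs_use_common_targets(self):
        matrix = pd.DataFrame({"p": [0.2, 0.4, np.nan], "q": [0.4, 0.8, 0.5]})
        scores = armser(matrix)
        assert scores["p"] == pytest.approx(1.5)  # geomean of (2, 2) over commons

    def test_nonpositive_rmse_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            armser(pd.DataFrame({"p": [0.0, 0.1], "q": [0.2, 0.3]}))


class TestSpearman:
    def test_identical_and_reversed_orderings(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman_agreement(a, a) == pytest.approx(1.0)
        assert spearman_agreement(a, a[::-1].copy()) == pytest.approx(-1.0)

    def test_tied_case_matches_manual_midrank_formula(self):
        pred = np.array([1.0, 2.0, 2.0, 4.0, 5.0])
        act = np.array([0.1, 0.3, 0.2, 0.5, 0.4])
        # manual mid-ranks and Pearson on ranks
        rp = stats.rankdata(pred)
        ra = stats.rankdata(act)
        manual = np.corrcoef(rp, ra)[0, 1]
        assert spearman_agreement(pred, act) == pytest.approx(manual)

    def test_too_few_common_items_rejected(self):
        with pytest.raises(ValueError):
            spearman_agreement(np.array([1.0, 2.0, np.nan]),
                               np.array([1.0, 2.0, 3.0]))


class TestReduction:
    @pytest.mark.parametrize(
        "default, method, expected",
        [((0.1964), 0.1709, 13.0), (0.1964, 0.2098, -6.8), (0.5, 0.5, 0.0)],
    )
    def test_percent_formula(self, default, method, expected):
        assert relative_rmse_reduction(default, method) == pytest.approx(
            expected, abs=0.05
        )

    def test_nonpositive_default_rejected(self):
        with pytest.raises(ValueError):
            relative_rmse_reduction(0.0, 0.1)


class TestFriedmanNemenyi:
    def test_identical_columns_give_zero_statistic(self):
        block = pd.DataFrame(np.tile([[0.3], [0.2], [0.5]], (1, 4)),
                             columns=list("abcd"))
        res = friedman_nemenyi(block)
        assert res.statistic == 0.0
        assert not res.significant.to_numpy().any()

    def test_strict_order_matches_hand_rank_sums(self, rng):
        # workflow a strictly best, c strictly worst, on all 10 targets:
        # mean ranks 1, 2, 3 -> chi2 = 12*10/12 * ((1-2)^2 + 0 + (3-2)^2) = 20
        base = rng.uniform(0.5, 1.0, 10)
        block = pd.DataFrame({"a": base - 0.2, "b": base, "c": base + 0.2})
        res = friedman_nemenyi(block)
        assert res.mean_ranks.to_list() == [1.0, 2.0, 3.0]
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(20.0, 2))

    def test_agrees_with_scipy_on_random_blocks(self, rng):
        block = pd.DataFrame(rng.uniform(size=(12, 4)), columns=list("abcd"))
        res = friedman_nemenyi(block)
        scipy_res = stats.friedmanchisquare(*[block[c] for c in block])
        assert res.statistic == pytest.approx(scipy_res.statistic)
        assert res.p_value == pytest.approx(scipy_res.pvalue)

    def test_pairwise_outcomes_symmetric_and_targets_dropped(self, rng):
        block = pd.DataFrame(rng.uniform(size=(15, 3)), columns=list("abc"))
        block.iloc[0, 0] = np.nan
        res = friedman_nemenyi(block)
        assert res.n_dropped == 1 and res.n_targets == 14
        for a, b in itertools.combinations(block.columns, 2):
            assert res.significant.loc[a, b] == res.significant.loc[b, a]
            assert res.nemenyi_p.loc[a, b] == pytest.approx(res.nemenyi_p.loc[b, a])


def test_friedman_type_one_error_calibrated():
    rate = friedman_null_rejection_rate(
        n_targets=20, n_workflows=4, n_reps=1000, alpha=0.05, seed=11
    )
    assert 0.03 <= rate <= 0.07


class TestWilcoxonComparison:
    def test_identical_series_claims_nothing(self, rng):
        vals = pd.Series(rng.uniform(0.2, 1.0, 20))
        cmp = wilcoxon_default_comparison(vals, vals)
        assert cmp["p_value"] == 1.0
        assert cmp["reduction_pct"] == 0.0

    def test_uniform_improvement_detected(self, rng):
        default = pd.Series(rng.uniform(0.5, 1.0, 25))
        method = default - 0.1
        cmp = wilcoxon_default_comparison(method, default)
        assert cmp["p_value"] < 0.05
        assert cmp["reduction_pct"] > 0

    def test_report_reduction_consistent_with_means(self, rng):
        default = pd.Series(rng.uniform(0.5, 1.0, 30))
        realized = {"m1": default * 0.9, "m2": default * 1.1}
        report = comparison_report(realized, default, default_name="Default")
        for name in realized:
            row = report.loc[name]
            expected = relative_rmse_reduction(
                report.loc["Default", "mean_rmse"], row["mean_rmse"]
            )
            assert row["reduction_pct"] == pytest.approx(expected)

    def test_too_few_pairs_rejected(self):
        s = pd.Series([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            wilcoxon_default_comparison(s, s)
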