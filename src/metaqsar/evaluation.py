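"""Comparison statistics for workflows and meta-learners.

*   aRMSEr — the average RMSE-ratio rank score. For workflow *p*,

        aRMSEr_p = (1/m) * sum_q geomean_i ( RMSE_q^i / RMSE_p^i )

    where the geometric mean runs over the targets *i* on which both *p*
    and *q* are defined, and *m* counts all workflows (the self term q = p
    contributes 1). A score above 1 means *p* beats the average opponent in
    geometric-mean ratio. Products are computed as sums of logs; the score
    is invariant to rescaling all workflows' RMSEs on any one target.

*   Spearman rank correlation between a predicted and the observed workflow
    ordering (mid-rank ties).

*   Relative RMSE reduction of a selection strategy against the fixed
    default workflow, ``(mRMSE_def - mRMSE_method) / mRMSE_def * 100``.

*   Friedman test over a block of workflows (mid-rank, tie-corrected
    chi-square) with the Nemenyi post-hoc pairwise comparison based on the
    studentized range distribution.

*   Paired Wilcoxon signed-rank on per-target RMSE differences against the
    default (the design is paired; the classical unpaired rank-sum variant
    is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def armser(matrix: pd.DataFrame, include_self: bool = True) -> pd.Series:
    """Average RMSE-ratio score per workflow (higher is better).

    Parameters
    ----------
    matrix : pandas.DataFrame
        Targets x workflows RMSE matrix; NaN marks structurally missing
        pairs. Every defined entry must be positive. For each opponent
        pair, the geometric mean is over their common targets.
    include_self : bool
        Whether the self-comparison term (identically 1) is included in the
        sum; the divisor is the number of summed opponents either way.
    """
    vals = matrix.to_numpy(dtype=float)
    if (vals[np.isfinite(vals)] <= 0).any():
        raise ValueError("RMSE entries must be positive")
    with np.errstate(invalid="ignore"):
        logs = np.log(vals)
    workflows = list(matrix.columns)
    m = len(workflows)
    scores = {}
    for p in range(m):
        total, terms = 0.0, 0
        for q in range(m):
            if q == p:
                if include_self:
                    total += 1.0
                    terms += 1
                continue
            common = np.isfinite(logs[:, p]) & np.isfinite(logs[:, q])
            if not common.any():
                continue
            total += float(np.exp(np.mean(logs[common, q] - logs[common, p])))
            terms += 1
        if terms == 0:
            raise ValueError(f"workflow {workflows[p]} has no comparable opponent")
        scores[workflows[p]] = total / terms
    return pd.Series(scores, name="aRMSEr")


def spearman_agreement(predicted, actual) -> float:
    """Spearman rank correlation between predicted scores and actual RMSEs.

    Both are "smaller is better" vectors over the same workflows; NaNs are
    dropped pairwise and at least 3 common workflows are required. Mid-rank
    tie handling.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must cover the same workflows")
    mask = np.isfinite(predicted) & np.isfinite(actual)
    if mask.sum() < 3:
        raise ValueError("need at least 3 common workflows")
    rho = stats.spearmanr(predicted[mask], actual[mask]).statistic
    return float(rho)


def relative_rmse_reduction(default_mean: float, method_mean: float) -> float:
    """Relative RMSE reduction in percent against the default strategy."""
    if default_mean <= 0:
        raise ValueError("default mean RMSE must be positive")
    return (default_mean - method_mean) / default_mean * 100.0


# ---------------------------------------------------------------------------
# Friedman + Nemenyi
# ---------------------------------------------------------------------------

@dataclass
class FriedmanNemenyiResult:
    statistic: float
    p_value: float
    mean_ranks: pd.Series
    critical_difference: float
    significant: pd.DataFrame  # pairwise booleans at the chosen alpha
    nemenyi_p: pd.DataFrame
    n_targets: int
    n_dropped: int


def friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an n x k mid-rank matrix."""
    n, k = ranks.shape
    centered = ranks - (k + 1) / 2.0
    denom = float((centered**2).sum())
    if denom == 0.0:
        return 0.0
    col_means = centered.mean(axis=0)
    return n * (k - 1) * float((col_means**2).sum()) * n / denom


def friedman_nemenyi(block: pd.DataFrame, alpha: float = 0.05) -> FriedmanNemenyiResult:
    """Friedman test with Nemenyi post-hoc over a targets x workflows block.

    Targets with any missing entry in the block are dropped (the test needs
    a complete block). Two workflows differ at level ``alpha`` when their
    mean ranks differ by more than the critical difference
    ``q_alpha * sqrt(k (k+1) / (6 n))``.
    """
    if block.shape[1] < 2:
        raise ValueError("need at least 2 workflows")
    complete = block.dropna(axis=0)
    n_dropped = len(block) - len(complete)
    if len(complete) < 2:
        raise ValueError("need at least 2 complete targets")
    ranks = np.apply_along_axis(stats.rankdata, 1, complete.to_numpy(dtype=float))
    n, k = ranks.shape
    statistic = friedman_statistic(ranks)
    p_value = float(stats.chi2.sf(statistic, k - 1))
    mean_ranks = pd.Series(ranks.mean(axis=0), index=complete.columns, name="mean_rank")

    q_alpha = stats.studentized_range.ppf(1 - alpha, k, np.inf)
    cd = q_alpha * np.sqrt(k * (k + 1) / (6.0 * n))
    diffs = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :])
    significant = pd.DataFrame(
        diffs > cd, index=complete.columns, columns=complete.columns
    )
    np.fill_diagonal(significant.to_numpy(), False)
    q_obs = diffs / np.sqrt(k * (k + 1) / (12.0 * n))
    nemenyi_p = pd.DataFrame(
        stats.studentized_range.sf(q_obs, k, np.inf),
        index=complete.columns,
        columns=complete.columns,
    )
    return FriedmanNemenyiResult(
        statistic=statistic,
        p_value=p_value,
        mean_ranks=mean_ranks,
        critical_difference=float(cd),
        significant=significant,
        nemenyi_p=nemenyi_p,
        n_targets=n,
        n_dropped=n_dropped,
    )


def friedman_null_rejection_rate(
    n_targets: int,
    n_workflows: int,
    n_reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the Friedman test under an exchangeable null.

    Simulates ``n_reps`` independent blocks of iid performance values (so
    the null of equivalent workflows holds by construction) and returns the
    fraction rejected at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    draws = rng.random((n_reps, n_targets, n_workflows))
    ranks = draws.argsort(axis=2).argsort(axis=2) + 1.0  # no ties a.s.
    centered = ranks - (n_workflows + 1) / 2.0
    denom = (centered**2).sum(axis=(1, 2))
    num = (centered.mean(axis=1) ** 2).sum(axis=1) * n_targets**2 * (n_workflows - 1)
    statistic = num / denom
    crit = stats.chi2.ppf(1 - alpha, n_workflows - 1)
    return float(np.mean(statistic > crit))


# ---------------------------------------------------------------------------
# default-vs-method comparison (Table-5-style report)
# ---------------------------------------------------------------------------

def wilcoxon_default_comparison(
    method_rmse: pd.Series,
    default_rmse: pd.Series,
    paired: bool = True,
) -> dict[str, float]:
    """Compare a method's per-target realized RMSEs with the default's.

    Returns the two mean RMSEs, the relative reduction, and the p-value of
    a Wilcoxon signed-rank test on the paired per-target differences
    (``paired=False`` runs the unpaired rank-sum test instead).
    """
    joined = pd.concat(
        {"method": method_rmse, "default": default_rmse}, axis=1
    ).dropna()
    if len(joined) < 5:
        raise ValueError("need at least 5 paired targets")
    diffs = joined["method"] - joined["default"]
    if paired:
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diffs[diffs != 0]).pvalue)
    else:
        p = float(stats.ranksums(joined["method"], joined["default"]).pvalue)
    mean_method = float(joined["method"].mean())
    mean_default = float(joined["default"].mean())
    return {
        "mean_rmse": mean_method,
        "default_mean_rmse": mean_default,
        "reduction_pct": relative_rmse_reduction(mean_default, mean_method),
        "p_value": p,
        "n_targets": int(len(joined)),
    }


def comparison_report(
    realized: dict[str, pd.Series],
    default_rmse: pd.Series,
    default_name: str = "Default",
    paired: bool = True,
) -> pd.DataFrame:
    """Assemble the default-vs-methods comparison table.

    One row per method (plus the default row) with mean RMSE, relative
    reduction in percent, and the Wilcoxon p-value.
    """
    rows = [
        {
            "method": default_name,
            "mean_rmse": float(default_rmse.dropna().mean()),
            "reduction_pct": 0.0,
            "p_value": np.nan,
        }
    ]
    for name, series in realized.items():
        cmp = wilcoxon_default_comparison(series, default_rmse, paired=paired)
        rows.append(
            {
                "method": name,
                "mean_rmse": cmp["mean_rmse"],
                "reduction_pct": cmp["reduction_pct"],
                "p_value": cmp["p_value"],
            }
        )
    return pd.DataFrame(rows).set_index("method")
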