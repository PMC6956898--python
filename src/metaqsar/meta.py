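"""Meta-learners: workflow selection and workflow ranking.

The meta-dataset pairs each target's meta-feature vector with the vector of
tenfold-CV RMSEs its workflows achieved. Three estimator families consume
it, all scikit-learn style (``fit(X, R)`` with the targets x workflows RMSE
frame as the response, ``get_params``/``set_params``, fitted attributes with
a trailing underscore):

``WorkflowSelector``
    A random-forest classifier (500 trees) predicting the winning workflow.
    With ``top_k`` set, the label space is restricted to the k workflows
    with the best training aRMSEr score and targets whose winner falls
    outside the set are relabelled to their best in-set workflow — so the
    top-k sets are derived from training folds only, never from held-out
    targets.

``KNNRanker``
    Ranks workflows for a query target by the mean of their within-target
    RMSE ranks across the k nearest training targets, with distances taken
    in standardized meta-feature space. ``k="all"`` degenerates to a single
    global ranking. Failed workflows rank worse than every observed one.

``MultiTargetRanker``
    A multivariate random-forest regression (500 trees) jointly predicting
    the full RMSE vector; the ranking is by ascending predicted RMSE.

`meta_cross_validate` evaluates any of them at the meta level: each
target's selection is made by a model never trained on it, and the realized
RMSE is looked up from the benchmark matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, clone
from sklearn.compose import ColumnTransformer, make_column_selector
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.utils.validation import check_is_fitted

from .benchmark import PerformanceMatrix
from .evaluation import armser, spearman_agreement
from .metafeatures import feature_group

logger = logging.getLogger(__name__)


@dataclass
class MetaDataset:
    """Aligned meta-features, performance rows, and winner labels."""

    M: pd.DataFrame  # targets x meta-features (numeric + categorical)
    R: pd.DataFrame  # targets x workflows RMSE, NaN = structural missing
    best_label: pd.Series
    feature_groups: pd.Series

    def __post_init__(self) -> None:
        if not (self.M.index.equals(self.R.index)
                and self.M.index.equals(self.best_label.index)):
            raise ValueError("M, R and best_label must share the target index")

    @property
    def workflow_ids(self) -> list[str]:
        return list(self.R.columns)


def _row_argmin(row: pd.Series) -> str:
    observed = row.dropna()
    best = observed.min()
    for col in row.index:  # first in column order wins ties
        if col in observed.index and observed[col] == best:
            return col
    raise ValueError("row has no observed entry")


def assemble_meta_dataset(
    metafeatures: pd.DataFrame, perf: PerformanceMatrix
) -> MetaDataset:
    """Join the meta-feature table with the benchmark performance matrix.

    Targets missing from either side, or with no successful workflow, are
    excluded (and logged). The winner label is the row argmin of R.
    """
    R = perf.matrix
    shared = [t for t in R.index if t in metafeatures.index]
    dropped = sorted(set(R.index) ^ set(metafeatures.index))
    if dropped:
        logger.warning("excluding %d unmatched target(s): %s", len(dropped), dropped)
    R = R.loc[shared]
    keep = R.notna().any(axis=1)
    if (~keep).any():
        logger.warning("excluding all-failed target(s): %s", list(R.index[~keep]))
    R = R.loc[keep]
    M = metafeatures.loc[R.index]
    best = pd.Series({t: _row_argmin(R.loc[t]) for t in R.index}, name="best_workflow")
    groups = pd.Series({c: feature_group(c) for c in M.columns}, name="feature_group")
    return MetaDataset(M=M, R=R, best_label=best.loc[R.index], feature_groups=groups)


def _encoder() -> ColumnTransformer:
    """Meta-feature preprocessor: impute + pass numerics, one-hot the
    grouping categoricals (unseen labels encode to all-zeros)."""
    return ColumnTransformer(
        [
            (
                "num",
                SimpleImputer(strategy="median"),
                make_column_selector(dtype_include=np.number),
            ),
            (
                "cat",
                OneHotEncoder(handle_unknown="ignore", sparse_output=False),
                make_column_selector(dtype_include=object),
            ),
        ]
    )


def rank_with_missing_worst(row: pd.Series) -> pd.Series:
    """Mid-ranks of a performance row; missing entries share the worst rank."""
    observed = row.dropna()
    ranks = pd.Series(np.nan, index=row.index, dtype=float)
    if not observed.empty:
        ranks[observed.index] = stats.rankdata(observed.to_numpy())
    n_obs, n_miss = len(observed), row.isna().sum()
    if n_miss:
        ranks[row.isna()] = n_obs + (n_miss + 1) / 2.0
    return ranks


class WorkflowSelector(BaseEstimator):
    """All-class or top-k workflow classification on meta-features.

    Parameters
    ----------
    top_k : "all" or int
        Size of the label space. An integer keeps only the k workflows
        ranked best by training aRMSEr and relabels out-of-set winners to
        their best in-set workflow.
    n_estimators, random_state
        Forwarded to the underlying random forest (500 trees by default).
    """

    def __init__(self, top_k="all", n_estimators: int = 500,
                 random_state: int | None = 0):
        self.top_k = top_k
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, R: pd.DataFrame):
        R = pd.DataFrame(R)
        if self.top_k == "all":
            allowed = list(R.columns)
        else:
            k = int(self.top_k)
            if k > R.shape[1]:
                raise ValueError(
                    f"top_k={k} exceeds the {R.shape[1]} available workflows"
                )
            scores = armser(R)
            allowed = list(scores.sort_values(ascending=False).index[:k])
        labels = pd.Series(
            {t: _row_argmin(R.loc[t, allowed]) for t in R.index}, name="label"
        )
        self.allowed_workflows_ = allowed
        self.workflow_ids_ = list(R.columns)
        self.labels_ = labels
        self.model_ = Pipeline(
            [
                ("encode", _encoder()),
                (
                    "forest",
                    RandomForestClassifier(
                        n_estimators=self.n_estimators,
                        random_state=self.random_state,
                    ),
                ),
            ]
        )
        self.model_.fit(X, labels.to_numpy())
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict(X)


class KNNRanker(BaseEstimator):
    """k-nearest-neighbour workflow ranking in meta-feature space."""

    def __init__(self, k="all"):
        self.k = k

    def fit(self, X: pd.DataFrame, R: pd.DataFrame):
        R = pd.DataFrame(R)
        if len(R) == 0:
            raise ValueError("empty training set")
        self.workflow_ids_ = list(R.columns)
        self.train_ranks_ = R.apply(rank_with_missing_worst, axis=1)
        self.space_ = make_pipeline(_encoder(), StandardScaler())
        Z = self.space_.fit_transform(X)
        k = len(R) if self.k == "all" else int(self.k)
        if k > len(R):
            raise ValueError(f"k={k} exceeds the {len(R)} training targets")
        self.n_neighbors_ = k
        self.nn_ = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(Z)
        return self

    def predict_ranking(self, X: pd.DataFrame) -> pd.DataFrame:
        """Mean neighbour rank per workflow (lower = recommended earlier)."""
        check_is_fitted(self, "nn_")
        Z = self.space_.transform(X)
        _, idx = self.nn_.kneighbors(Z)
        ranks = self.train_ranks_.to_numpy()
        scores = np.stack([ranks[row].mean(axis=0) for row in idx])
        return pd.DataFrame(scores, index=X.index, columns=self.workflow_ids_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Top-ranked workflow per query."""
        scores = self.predict_ranking(X)
        return np.asarray([_row_argmin(scores.loc[t]) for t in scores.index])


class MultiTargetRanker(BaseEstimator):
    """Multivariate random-forest regression of the full RMSE vector.

    Structurally missing training RMSEs are imputed with a pessimistic
    constant (the column's worst observed value plus 10% of its range) so a
    failed workflow is never predicted attractive.
    """

    def __init__(self, n_estimators: int = 500, min_train: int = 10,
                 random_state: int | None = 0):
        self.n_estimators = n_estimators
        self.min_train = min_train
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, R: pd.DataFrame):
        R = pd.DataFrame(R)
        if len(R) < self.min_train:
            raise ValueError(f"need at least {self.min_train} training targets")
        self.workflow_ids_ = list(R.columns)
        filled = R.copy()
        for col in filled.columns:
            observed = filled[col].dropna()
            if observed.empty:
                raise ValueError(f"workflow {col} failed on every training target")
            penalty = observed.max() + 0.1 * max(
                observed.max() - observed.min(), observed.max()
            )
            filled[col] = filled[col].fillna(penalty)
        self.model_ = Pipeline(
            [
                ("encode", _encoder()),
                (
                    "forest",
                    RandomForestRegressor(
                        n_estimators=self.n_estimators,
                        random_state=self.random_state,
                    ),
                ),
            ]
        )
        self.model_.fit(X, filled.to_numpy())
        return self

    def predict_ranking(self, X: pd.DataFrame) -> pd.DataFrame:
        """Predicted RMSE per workflow (ascending order = recommendation)."""
        check_is_fitted(self, "model_")
        pred = np.atleast_2d(self.model_.predict(X))
        return pd.DataFrame(pred, index=X.index, columns=self.workflow_ids_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.predict_ranking(X)
        return np.asarray([_row_argmin(scores.loc[t]) for t in scores.index])


# ---------------------------------------------------------------------------
# meta-level evaluation
# ---------------------------------------------------------------------------

def meta_cross_validate(
    meta: MetaDataset,
    estimator: BaseEstimator,
    folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Tenfold meta-level cross-validation of a selector or ranker.

    Every target's workflow is chosen by a model trained without it. The
    realized RMSE is looked up from the benchmark matrix; if the chosen
    workflow has no observed RMSE on that target, rankers fall back to
    their next-ranked observed workflow (selectors record NaN). For
    rankers, the per-target Spearman correlation between predicted and
    actual rankings is reported.

    Returns a frame indexed by target with columns ``selected``,
    ``realized_rmse``, ``spearman`` and ``correct``.
    """
    targets = np.asarray(meta.M.index)
    n_splits = min(folds, len(targets))
    splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
    records: dict[str, dict] = {}
    for train_idx, test_idx in splitter.split(targets):
        train_t, test_t = targets[train_idx], targets[test_idx]
        model = clone(estimator)
        model.fit(meta.M.loc[train_t], meta.R.loc[train_t])
        is_ranker = hasattr(model, "predict_ranking")
        ranking = model.predict_ranking(meta.M.loc[test_t]) if is_ranker else None
        selected = model.predict(meta.M.loc[test_t])
        for t, sel in zip(test_t, selected):
            actual = meta.R.loc[t]
            realized = actual.get(sel, np.nan)
            rho = np.nan
            if is_ranker:
                row = ranking.loc[t]
                if np.isnan(realized):
                    observed = actual.dropna()
                    if not observed.empty:
                        sel = _row_argmin(row[observed.index])
                        realized = actual[sel]
                        logger.info(
                            "target %s: fell back to next-ranked workflow %s", t, sel
                        )
                rho = spearman_agreement(
                    row.to_numpy(dtype=float), actual.to_numpy(dtype=float)
                )
            elif np.isnan(realized):
                logger.warning("target %s: selected workflow %s unobserved", t, sel)
            records[t] = {
                "selected": sel,
                "realized_rmse": float(realized) if np.isfinite(realized) else np.nan,
                "spearman": rho,
                "correct": sel == meta.best_label[t],
            }
    out = pd.DataFrame.from_dict(records, orient="index").loc[meta.M.index]
    out.index.name = "target_id"
    return out


def selection_accuracy(results: pd.DataFrame) -> float:
    """Fraction of targets whose selected workflow was the true winner."""
    return float(results["correct"].mean())


def majority_class_rate(best_label: pd.Series) -> float:
    """Accuracy of always predicting the most frequent winner."""
    return float(best_label.value_counts(normalize=True).iloc[0])


def oracle_realized(R: pd.DataFrame) -> pd.Series:
    """Per-target RMSE of a perfect selector (row minimum)."""
    return R.min(axis=1)


def fixed_realized(R: pd.DataFrame, workflow_id: str) -> pd.Series:
    """Per-target RMSE of always choosing one fixed workflow."""
    return R[workflow_id]


def metafeature_importance(
    selector: WorkflowSelector,
    X: pd.DataFrame,
    n_repeats: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation importance (mean decrease accuracy) of the meta-features.

    Computed on the data the selector was fitted to, against its own
    training labels, mirroring a forest's internal importance measure.
    Returns the per-feature table and a per-group summary; every column is
    assigned to exactly one group.
    """
    check_is_fitted(selector, "model_")
    result = permutation_importance(
        selector.model_,
        X,
        selector.labels_.loc[X.index].to_numpy(),
        n_repeats=n_repeats,
        random_state=seed,
        scoring="accuracy",
    )
    per_feature = pd.DataFrame(
        {
            "importance": result.importances_mean,
            "importance_sd": result.importances_std,
            "group": [feature_group(c) for c in X.columns],
        },
        index=X.columns,
    )
    summary = per_feature.groupby("group")["importance"].agg(
        ["mean", "median", "max", "count"]
    )
    return per_feature, summary
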