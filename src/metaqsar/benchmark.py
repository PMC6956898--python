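"""Tenfold-CV benchmarking of workflows over a collection.

Every compatible (target, workflow) pair is scored by the mean over folds
of the per-fold root mean squared error. Fold assignment is one seeded
shuffle per *target* (not per workflow or representation), so all workflows
see identical train/test splits on a target and downstream paired tests
(Friedman, Wilcoxon) compare like with like.

A workflow that raises on any fold is recorded as a failure for that
(target, workflow) pair — it never wins and is treated as structurally
missing downstream — rather than aborting the run.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .data import Collection, QSARDataset
from .workflows import WorkflowSpec

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_FAILED = "failed"


def fold_seed(seed: int, target_id: str) -> int:
    """Stable per-target fold seed shared by every workflow on that target."""
    return zlib.crc32(f"{seed}:{target_id}".encode()) & 0x7FFFFFFF


def cv_rmse(
    workflow: WorkflowSpec,
    dataset: QSARDataset,
    folds: int = 10,
    seed: int = 0,
) -> float:
    """Mean tenfold-cross-validated RMSE of one workflow on one dataset.

    Raises on estimator failure; callers that need failure tolerance wrap
    this (see :func:`run_benchmark`).
    """
    if dataset.representation != workflow.representation:
        raise ValueError(
            f"dataset representation {dataset.representation!r} is incompatible "
            f"with workflow {workflow.workflow_id!r}"
        )
    n = dataset.n_compounds
    if n < folds:
        raise ValueError(f"{n} compounds cannot be split into {folds} folds")
    X = dataset.X.to_numpy(dtype=float)
    y = dataset.y.to_numpy(dtype=float)
    splitter = KFold(
        n_splits=folds, shuffle=True, random_state=fold_seed(seed, dataset.target_id)
    )
    fold_rmses = []
    for train_idx, test_idx in splitter.split(X):
        est = workflow.make_estimator(random_state=fold_seed(seed, dataset.target_id))
        est.fit(X[train_idx], y[train_idx])
        pred = np.ravel(est.predict(X[test_idx]))
        fold_rmses.append(float(np.sqrt(np.mean((pred - y[test_idx]) ** 2))))
    return float(np.mean(fold_rmses))


@dataclass
class PerformanceMatrix:
    """Targets x workflows tenfold-CV RMSE with structural missingness.

    Stored tidily (one row per evaluated pair) and pivoted on demand.
    Failed pairs carry NaN RMSE with status ``"failed"``; pairs that were
    never compatible are simply absent and appear as NaN in the pivot.
    """

    records: pd.DataFrame  # columns: target_id, workflow_id, learner_id,
    #          representation, rmse, status

    COLUMNS = ("target_id", "workflow_id", "learner_id", "representation",
               "rmse", "status")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"performance records missing columns {sorted(missing)}")
        ok = self.records.loc[self.records["status"] == STATUS_OK, "rmse"]
        if (ok < 0).any() or not np.isfinite(ok).all():
            raise ValueError("RMSE entries must be finite and non-negative")

    @property
    def matrix(self) -> pd.DataFrame:
        """Targets x workflows RMSE pivot (NaN where missing or failed)."""
        piv = self.records.pivot_table(
            index="target_id", columns="workflow_id", values="rmse", aggfunc="first"
        )
        order = list(dict.fromkeys(self.records["workflow_id"]))
        return piv.reindex(columns=order)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PerformanceMatrix":
        return cls(pd.read_csv(path))


def run_benchmark(
    collection: Collection,
    workflows: list[WorkflowSpec],
    folds: int = 10,
    seed: int = 0,
    cache_path=None,
) -> PerformanceMatrix:
    """Score every workflow on every compatible dataset of the collection.

    Resumable: if ``cache_path`` exists, already-scored (target, workflow)
    pairs are reused and newly scored pairs are appended after each target.
    """
    if not collection.target_ids:
        raise ValueError("empty collection")
    done: dict[tuple[str, str], dict] = {}
    if cache_path is not None and Path(cache_path).exists():
        cached = pd.read_csv(cache_path)
        for row in cached.to_dict("records"):
            done[(row["target_id"], row["workflow_id"])] = row
        logger.info("benchmark cache: %d entries loaded", len(done))

    rows: list[dict] = []
    for t_i, tid in enumerate(collection.target_ids):
        datasets = collection.datasets(tid)
        for wf in workflows:
            key = (tid, wf.workflow_id)
            if key in done:
                rows.append(done[key])
                continue
            dataset = datasets.get(wf.representation)
            if dataset is None:
                continue
            try:
                rmse = cv_rmse(wf, dataset, folds=folds, seed=seed)
                status = STATUS_OK
            except Exception as exc:  # noqa: BLE001 - failures are data here
                logger.warning("workflow %s failed on %s: %s", wf.workflow_id, tid, exc)
                rmse, status = np.nan, STATUS_FAILED
            rows.append(
                {
                    "target_id": tid,
                    "workflow_id": wf.workflow_id,
                    "learner_id": wf.learner_id,
                    "representation": wf.representation,
                    "rmse": rmse,
                    "status": status,
                }
            )
        if cache_path is not None:
            pd.DataFrame(rows, columns=list(PerformanceMatrix.COLUMNS)).to_csv(
                cache_path, index=False
            )
        logger.info("benchmarked target %s (%d/%d)", tid, t_i + 1,
                    len(collection.target_ids))
    return PerformanceMatrix(pd.DataFrame(rows, columns=list(PerformanceMatrix.COLUMNS)))


def best_workflow_per_target(perf: PerformanceMatrix) -> pd.Series:
    """Winning workflow (lowest RMSE) per target.

    The best performer is the workflow with the lowest RMSE, however small
    the margin. Exact ties go to the earlier workflow in enumeration order
    (and are logged); targets where every workflow failed are excluded.
    """
    matrix = perf.matrix
    winners = {}
    for tid, row in matrix.iterrows():
        observed = row.dropna()
        if observed.empty:
            logger.warning("target %s: all workflows failed; excluded", tid)
            continue
        best = observed.min()
        tied = [w for w in matrix.columns if w in observed.index and observed[w] == best]
        if len(tied) > 1:
            logger.info("target %s: tie between %s; keeping %s", tid, tied, tied[0])
        winners[tid] = tied[0]
    return pd.Series(winners, name="best_workflow")


def win_counts(perf: PerformanceMatrix) -> dict[str, pd.Series]:
    """Win tallies by workflow, by learner, and by representation."""
    winners = best_workflow_per_target(perf)
    lookup = perf.records.drop_duplicates("workflow_id").set_index("workflow_id")
    by_workflow = winners.value_counts()
    by_learner = winners.map(lookup["learner_id"]).value_counts()
    by_representation = winners.map(lookup["representation"]).value_counts()
    return {
        "workflow": by_workflow,
        "learner": by_learner,
        "representation": by_representation,
    }
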