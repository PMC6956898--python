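import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

import metaqsar as mq
from metaqsar.benchmark import (
    PerformanceMatrix,
    best_workflow_per_target,
    cv_rmse,
    fold_seed,
    run_benchmark,
    win_counts,
)
from metaqsar.synthetic import MECHANISMS, SyntheticConfig
from metaqsar.workflows import WorkflowSpec


def _dataset(X, y, target_id="T1", representation="allmolprop.miss"):
    idx = [f"c{i}" for i in range(len(y))]
    return mq.QSARDataset(
        target_id,
        representation,
        pd.DataFrame(np.asarray(X, dtype=float), index=idx),
        pd.Series(np.asarray(y, dtype=float), index=idx),
        "continuous",
    )


class TestCvRmse:
    def test_noiseless_linear_response_interpolated_by_lm(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -2.0, 0.5] + 4.0
        rmse = cv_rmse(WorkflowSpec.from_id("lm.allmolprop.miss"), _dataset(X, y),
                       folds=5, seed=0)
        assert rmse < 1e-6

    def test_matches_hand_computed_nearest_neighbour_folds(self, rng):
        # independent oracle: re-predict each fold with brute-force 1-NN
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        ds = _dataset(X, y, target_id="T9")
        folds, seed = 4, 3
        splitter = KFold(n_splits=folds, shuffle=True,
                         random_state=fold_seed(seed, "T9"))
        expected_folds = []
        for train, test in splitter.split(X):
            preds = []
            for i in test:
                d2 = ((X[train] - X[i]) ** 2).sum(axis=1)
                preds.append(y[train][int(np.argmin(d2))])
            expected_folds.append(
                float(np.sqrt(np.mean((np.asarray(preds) - y[test]) ** 2)))
            )
        expected = float(np.mean(expected_folds))
        got = cv_rmse(WorkflowSpec.from_id("fnn.allmolprop.miss"), ds,
                      folds=folds, seed=seed)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_incompatible_representation_rejected(self, rng):
        ds = _dataset(rng.normal(size=(30, 2)), rng.normal(size=30))
        with pytest.raises(ValueError, match="incompatible"):
            cv_rmse(WorkflowSpec.from_id("fnn.fpFCFP4"), ds)

    def test_scale_equivariance_of_rmse(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, 0.5, -1.0] + rng.normal(0, 0.3, 40)
        wf = WorkflowSpec.from_id("fnn.allmolprop.miss")
        r1 = cv_rmse(wf, _dataset(X, y), folds=5, seed=1)
        r3 = cv_rmse(wf, _dataset(X, 3.0 * y), folds=5, seed=1)
        assert r3 == pytest.approx(3.0 * r1, rel=1e-9)
        assert r1 >= 0.0


class TestRunBenchmark:
    def test_matrix_shape_and_determinism(self, tiny_collection, cheap_workflows,
                                          tiny_perf):
        m = tiny_perf.matrix
        assert m.shape == (len(tiny_collection.target_ids), len(cheap_workflows))
        again = run_benchmark(tiny_collection, cheap_workflows, folds=5, seed=7)
        pd.testing.assert_frame_equal(again.matrix, m)

    def test_cache_resume_agrees_with_fresh_run(self, tmp_path, tiny_collection,
                                                cheap_workflows, tiny_perf):
        cache = tmp_path / "bench.csv"
        first = run_benchmark(tiny_collection, cheap_workflows, folds=5, seed=7,
                              cache_path=cache)
        assert cache.exists()
        resumed = run_benchmark(tiny_collection, cheap_workflows, folds=5, seed=7,
                                cache_path=cache)
        pd.testing.assert_frame_equal(resumed.matrix, first.matrix)
        pd.testing.assert_frame_equal(first.matrix, tiny_perf.matrix)

    def test_ksvmfp_scored_only_on_fingerprints(self, tiny_collection):
        wfs = [WorkflowSpec.from_id("ksvmfp.fpFCFP4"),
               WorkflowSpec.from_id("lm.basicmolprop.miss")]
        perf = run_benchmark(tiny_collection, wfs, folds=5, seed=0)
        recs = perf.records
        assert (recs.loc[recs.workflow_id == "ksvmfp.fpFCFP4",
                         "representation"] == "fpFCFP4").all()
        assert len(recs) == 2 * len(tiny_collection.target_ids)

    def test_learner_failure_recorded_not_raised(self, tiny_collection, monkeypatch):
        wf = WorkflowSpec.from_id("lm.basicmolprop.miss")

        class Exploding:
            def fit(self, X, y):
                raise RuntimeError("boom")

        monkeypatch.setattr(WorkflowSpec, "make_estimator",
                            lambda self, random_state=None: Exploding())
        perf = run_benchmark(tiny_collection, [wf], folds=5, seed=0)
        assert (perf.records["status"] == "failed").all()
        assert perf.records["rmse"].isna().all()


class TestWinners:
    def _toy_perf(self):
        rows = []
        rmse = {
            "T1": {"a": 0.5, "b": 0.9, "c": 0.7},
            "T2": {"a": 0.8, "b": 0.2, "c": 0.9},
            "T3": {"a": 0.4, "b": 0.6, "c": 0.8},
        }
        for t, per in rmse.items():
            for w, r in per.items():
                rows.append(
                    dict(target_id=t, workflow_id=w, learner_id=w,
                         representation="fpFCFP4", rmse=r, status="ok")
                )
        return PerformanceMatrix(pd.DataFrame(rows))

    def test_counts_match_hand_tally(self):
        perf = self._toy_perf()
        winners = best_workflow_per_target(perf)
        assert winners.to_dict() == {"T1": "a", "T2": "b", "T3": "a"}
        counts = win_counts(perf)
        assert counts["workflow"].to_dict() == {"a": 2, "b": 1}
        assert counts["workflow"].sum() == 3  # wins sum to scoreable targets

    def test_exact_tie_goes_to_enumeration_order(self):
        perf = self._toy_perf()
        recs = perf.records.copy()
        recs.loc[(recs.target_id == "T1") & (recs.workflow_id == "c"), "rmse"] = 0.5
        winners = best_workflow_per_target(PerformanceMatrix(recs))
        assert winners["T1"] == "a"

    def test_all_failed_target_excluded(self):
        perf = self._toy_perf()
        recs = perf.records.copy()
        recs.loc[recs.target_id == "T2", "rmse"] = np.nan
        recs.loc[recs.target_id == "T2", "status"] = "failed"
        winners = best_workflow_per_target(PerformanceMatrix(recs))
        assert "T2" not in winners.index
        assert len(winners) == 2


@pytest.mark.parametrize("mechanism", MECHANISMS)
def test_planted_winner_family_has_lowest_mean_rmse(mechanism):
    """Single-mechanism collections are won by the matched learner family."""
    mix = {m: (1.0 if m == mechanism else 0.0) for m in MECHANISMS}
    cfg = SyntheticConfig(
        n_targets=8, compounds_range=(100, 180), mechanism_mix=mix,
        noise_sd=0.3, seed=17,
    )
    col = mq.generate_collection(cfg)
    wids = [
        "rforest.fpFCFP4", "gbm.fpFCFP4", "fnn.fpFCFP4",
        "glmnet.allmolprop.miss", "ridge.basicmolprop.miss",
        "ksvm.allmolprop.miss",
    ]
    workflows = [
        WorkflowSpec.from_id(w, n_estimators=150) if w.startswith("rforest")
        else WorkflowSpec.from_id(w)
        for w in wids
    ]
    perf = run_benchmark(col, workflows, folds=5, seed=5)
    mean_rmse = perf.matrix.mean()
    family = {
        "linear-descriptor": {"glmnet.allmolprop.miss"},
        "substructure-rule": {"rforest.fpFCFP4", "gbm.fpFCFP4"},
        "smooth-nonlinear": {"ksvm.allmolprop.miss"},
    }[mechanism]
    assert mean_rmse.idxmin() in family
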