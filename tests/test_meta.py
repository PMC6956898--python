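import numpy as np
import pandas as pd
import pytest

import metaqsar as mq
from metaqsar.meta import (
    KNNRanker,
    MultiTargetRanker,
    WorkflowSelector,
    assemble_meta_dataset,
    fixed_realized,
    majority_class_rate,
    meta_cross_validate,
    metafeature_importance,
    oracle_realized,
    rank_with_missing_worst,
    selection_accuracy,
)


def _toy_meta(n=12, n_wf=4, seed=0, missing=False):
    """Meta-dataset where feature f0 identifies the winning workflow."""
    rng = np.random.default_rng(seed)
    targets = [f"T{i}" for i in range(n)]
    winners = rng.integers(0, n_wf, n)
    M = pd.DataFrame(
        {
            "ds_f0": winners.astype(float),
            "ds_noise": rng.normal(size=n),
            "class_L1": [f"c{c}" for c in rng.integers(0, 2, n)],
        },
        index=targets,
    )
    R = pd.DataFrame(
        rng.uniform(0.5, 1.0, (n, n_wf)),
        index=targets,
        columns=[f"w{j}" for j in range(n_wf)],
    )
    for i, w in enumerate(winners):
        R.iloc[i, w] = 0.1
    if missing:
        R.iloc[0, (winners[0] + 1) % n_wf] = np.nan
    groups = pd.Series({c: "information-theory" if c.startswith("ds_")
                        else "target-grouping" for c in M.columns})
    best = R.idxmin(axis=1)
    return mq.MetaDataset(M=M, R=R, best_label=best, feature_groups=groups)


class TestAssembly:
    def test_shapes_and_labels(self, tiny_meta, tiny_collection):
        n = len(tiny_collection.target_ids)
        assert tiny_meta.M.shape[0] == n
        assert tiny_meta.R.shape == (n, 3)
        for t in tiny_meta.R.index:
            row = tiny_meta.R.loc[t]
            assert row[tiny_meta.best_label[t]] == row.min()

    def test_targets_without_metafeatures_excluded(self, tiny_perf, tiny_collection):
        features = mq.collection_metafeatures(tiny_collection, seed=0)
        meta = assemble_meta_dataset(features.iloc[:-1], tiny_perf)
        assert meta.M.shape[0] == len(tiny_collection.target_ids) - 1

    def test_every_column_grouped(self, tiny_meta):
        assert set(tiny_meta.feature_groups.unique()) <= {
            "information-theory", "aggregated-fingerprint",
            "target-property", "target-grouping",
        }
        assert len(tiny_meta.feature_groups) == tiny_meta.M.shape[1]


class TestRankWithMissing:
    def test_missing_entries_rank_worst(self):
        row = pd.Series({"a": 0.3, "b": np.nan, "c": 0.1, "d": np.nan})
        ranks = rank_with_missing_worst(row)
        assert ranks["c"] == 1.0 and ranks["a"] == 2.0
        assert ranks["b"] == ranks["d"] == 3.5  # shared worst mid-rank


class TestWorkflowSelector:
    def test_single_label_degenerate_always_predicted(self):
        meta = _toy_meta()
        R = meta.R.copy()
        R["w0"] = 0.01  # w0 wins everywhere
        sel = WorkflowSelector(n_estimators=50).fit(meta.M, R)
        assert set(sel.predict(meta.M)) == {"w0"}

    def test_top_k_restriction_respected(self):
        meta = _toy_meta(n=20)
        sel = WorkflowSelector(top_k=2, n_estimators=50).fit(meta.M, meta.R)
        assert len(sel.allowed_workflows_) == 2
        assert set(sel.predict(meta.M)) <= set(sel.allowed_workflows_)
        assert set(sel.labels_.unique()) <= set(sel.allowed_workflows_)

    def test_top_k_larger_than_registry_rejected(self):
        meta = _toy_meta()
        with pytest.raises(ValueError, match="top_k"):
            WorkflowSelector(top_k=10).fit(meta.M, meta.R)

    def test_informative_feature_learned(self):
        meta = _toy_meta(n=40, seed=3)
        sel = WorkflowSelector(n_estimators=100, random_state=0).fit(meta.M, meta.R)
        acc = float(np.mean(sel.predict(meta.M) == meta.best_label.to_numpy()))
        assert acc > 0.9  # f0 literally encodes the label


class TestKNNRanker:
    def test_k1_returns_single_neighbour_ordering(self):
        meta = _toy_meta(n=8, seed=1)
        ranker = KNNRanker(k=1).fit(meta.M, meta.R)
        scores = ranker.predict_ranking(meta.M)
        # each training target is its own nearest neighbour: predicted
        # ordering equals the observed ranking
        for t in meta.M.index:
            assert scores.loc[t].idxmin() == meta.best_label[t]

    def test_k_all_is_query_independent(self):
        meta = _toy_meta(n=10, seed=2)
        ranker = KNNRanker(k="all").fit(meta.M, meta.R)
        scores = ranker.predict_ranking(meta.M)
        assert (scores.nunique(axis=0) == 1).all()

    def test_two_neighbour_toy_matches_hand_averaged_ranks(self):
        M = pd.DataFrame({"f": [0.0, 0.1, 10.0]}, index=["a", "b", "c"])
        R = pd.DataFrame(
            {"w0": [0.1, 0.2, 0.9], "w1": [0.2, 0.1, 0.5], "w2": [0.3, 0.3, 0.1]},
            index=["a", "b", "c"],
        )
        ranker = KNNRanker(k=2).fit(M, R)
        q = pd.DataFrame({"f": [0.05]}, index=["q"])
        scores = ranker.predict_ranking(q).loc["q"]
        # neighbours of q are a and b; ranks a: (1,2,3), b: (2,1,3)
        assert scores["w0"] == pytest.approx(1.5)
        assert scores["w1"] == pytest.approx(1.5)
        assert scores["w2"] == pytest.approx(3.0)

    def test_k_exceeding_training_set_rejected(self):
        meta = _toy_meta(n=5)
        with pytest.raises(ValueError, match="exceeds"):
            KNNRanker(k=9).fit(meta.M, meta.R)


class TestMultiTargetRanker:
    def test_identical_training_rows_reproduced(self):
        meta = _toy_meta(n=12)
        R = pd.DataFrame(
            np.tile([0.4, 0.2, 0.6, 0.8], (12, 1)),
            index=meta.R.index, columns=meta.R.columns,
        )
        ranker = MultiTargetRanker(n_estimators=50).fit(meta.M, R)
        scores = ranker.predict_ranking(meta.M)
        assert (scores.idxmin(axis=1) == "w1").all()
        order = scores.iloc[0].sort_values().index.to_list()
        assert order == ["w1", "w0", "w2", "w3"]

    def test_prediction_is_over_all_workflows(self):
        meta = _toy_meta(n=15, missing=True)
        ranker = MultiTargetRanker(n_estimators=50).fit(meta.M, meta.R)
        scores = ranker.predict_ranking(meta.M)
        assert list(scores.columns) == meta.workflow_ids
        assert np.isfinite(scores.to_numpy()).all()

    def test_min_train_enforced(self):
        meta = _toy_meta(n=5)
        with pytest.raises(ValueError, match="at least"):
            MultiTargetRanker().fit(meta.M, meta.R)


class TestMetaCrossValidation:
    def test_determinism_and_columns(self):
        meta = _toy_meta(n=20, seed=4)
        est = WorkflowSelector(n_estimators=50, random_state=1)
        r1 = meta_cross_validate(meta, est, folds=5, seed=9)
        r2 = meta_cross_validate(meta, est, folds=5, seed=9)
        pd.testing.assert_frame_equal(r1, r2)
        assert list(r1.columns) == ["selected", "realized_rmse", "spearman", "correct"]

    def test_oracle_lower_bounds_any_method(self):
        meta = _toy_meta(n=20, seed=5)
        res = meta_cross_validate(meta, KNNRanker(k=3), folds=5, seed=0)
        assert res["realized_rmse"].mean() >= oracle_realized(meta.R).mean() - 1e-12

    def test_fixed_default_column_lookup(self):
        meta = _toy_meta(n=16, seed=6)
        fixed = fixed_realized(meta.R, "w0")
        pd.testing.assert_series_equal(fixed, meta.R["w0"])

    def test_ranker_reports_spearman(self):
        meta = _toy_meta(n=20, seed=7)
        res = meta_cross_validate(meta, MultiTargetRanker(n_estimators=50),
                                  folds=4, seed=0)
        assert res["spearman"].notna().all()
        assert res["spearman"].between(-1, 1).all()
        acc = selection_accuracy(res)
        assert 0.0 <= acc <= 1.0
        assert 0.0 < majority_class_rate(meta.best_label) <= 1.0


class TestImportance:
    def test_label_defining_feature_dominates(self):
        meta = _toy_meta(n=40, seed=8)
        sel = WorkflowSelector(n_estimators=100, random_state=0).fit(meta.M, meta.R)
        per_feature, summary = metafeature_importance(sel, meta.M, n_repeats=5, seed=0)
        assert per_feature["importance"].idxmax() == "ds_f0"
        assert abs(per_feature.loc["ds_noise", "importance"]) < 0.15
        assert per_feature["group"].notna().all()
        assert int(summary["count"].sum()) == meta.M.shape[1]
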