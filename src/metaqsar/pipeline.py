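"""One-command experiment pipeline.

Stages: generate (or load) a collection -> benchmark the workflow registry
-> extract meta-features -> run the configured meta-learners under
meta-level cross-validation -> emit the default-vs-methods comparison
report. Every stage persists its artifact in the output directory and is
resumed from disk when re-run, so the pipeline is cheap to iterate on and
deterministic given the configuration.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .benchmark import PerformanceMatrix, run_benchmark
from .data import Collection
from .evaluation import comparison_report
from .meta import (
    KNNRanker,
    MetaDataset,
    MultiTargetRanker,
    WorkflowSelector,
    assemble_meta_dataset,
    majority_class_rate,
    meta_cross_validate,
    selection_accuracy,
)
from .metafeatures import collection_metafeatures, read_metafeatures, write_metafeatures
from .synthetic import SyntheticConfig, generate_collection
from .workflows import DESK_WORKFLOW_IDS, WorkflowSpec

logger = logging.getLogger(__name__)

DEFAULT_METHODS = (
    {"name": "mRF"},
    {"name": "kNN", "k": 50},
    {"name": "cl", "top_k": "all"},
)


@dataclass
class ExperimentConfig:
    """Everything one experiment depends on, YAML-serialisable.

    Either ``synthetic`` (a :class:`SyntheticConfig` mapping) or
    ``collection_dir`` must be given. Seeds are explicit — no wall-clock
    seeding anywhere.
    """

    synthetic: dict | None = None
    collection_dir: str | None = None
    workflow_ids: tuple[str, ...] = DESK_WORKFLOW_IDS
    base_folds: int = 10
    meta_folds: int = 10
    seed: int = 0
    methods: tuple[dict, ...] = DEFAULT_METHODS
    default_workflow: str = "rforest.fpFCFP4"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.collection_dir is None):
            raise ValueError("give exactly one of synthetic / collection_dir")
        for wid in (*self.workflow_ids, self.default_workflow):
            WorkflowSpec.from_id(wid)  # validates learner and representation
        if self.default_workflow not in self.workflow_ids:
            raise ValueError("default_workflow must be among workflow_ids")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("workflow_ids", "methods"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_method(spec: dict, seed: int = 0):
    """Instantiate a configured meta-learner; returns (display name, estimator)."""
    kind = spec["name"]
    if kind == "mRF":
        return "mRF", MultiTargetRanker(random_state=seed)
    if kind == "kNN":
        k = spec.get("k", "all")
        name = "All-NN" if k == "all" else f"{k}-NN"
        return name, KNNRanker(k=k)
    if kind == "cl":
        top_k = spec.get("top_k", "all")
        name = "cl.All" if top_k == "all" else f"cl.Top{top_k}"
        return name, WorkflowSelector(top_k=top_k, random_state=seed)
    raise ValueError(f"unknown meta-learner {kind!r}")


@dataclass
class ExperimentResult:
    collection: Collection
    perf: PerformanceMatrix
    metafeatures: pd.DataFrame
    meta: MetaDataset
    per_method: dict[str, pd.DataFrame]
    report: pd.DataFrame
    summary: pd.DataFrame = field(default=None)


def _timed(stage: str, t0: float) -> None:
    logger.info("stage %s finished in %.1f s", stage, time.perf_counter() - t0)


STAGES = ("generate", "benchmark", "metafeatures", "metalearn", "report")


def run_experiment(
    config: ExperimentConfig, out_dir, through: str = "report"
) -> ExperimentResult:
    """Run (or resume) the pipeline, stopping after stage ``through``.

    Writes every completed stage's artifact to ``out_dir``; stages already
    on disk are reused. Stops early with a partial result when ``through``
    names an intermediate stage.
    """
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    stop = STAGES.index(through)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    partial = ExperimentResult(
        collection=None, perf=None, metafeatures=None, meta=None,
        per_method={}, report=None,
    )

    t0 = time.perf_counter()
    if config.synthetic is not None:
        collection = generate_collection(SyntheticConfig.from_dict(config.synthetic))
    else:
        collection = Collection.read(config.collection_dir)
    logger.info("collection: %d targets", len(collection.target_ids))
    _timed("generate", t0)
    partial.collection = collection
    if stop < STAGES.index("benchmark"):
        return partial

    t0 = time.perf_counter()
    workflows = [WorkflowSpec.from_id(wid) for wid in config.workflow_ids]
    perf = run_benchmark(
        collection,
        workflows,
        folds=config.base_folds,
        seed=config.seed,
        cache_path=out / "benchmark.csv",
    )
    _timed("benchmark", t0)
    partial.perf = perf
    if stop < STAGES.index("metafeatures"):
        return partial

    t0 = time.perf_counter()
    features_path = out / "metafeatures.csv"
    if features_path.exists():
        features = read_metafeatures(features_path)
    else:
        features = collection_metafeatures(collection, seed=config.seed)
        write_metafeatures(features, features_path)
    _timed("metafeatures", t0)
    partial.metafeatures = features
    if stop < STAGES.index("metalearn"):
        return partial

    t0 = time.perf_counter()
    meta = assemble_meta_dataset(features, perf)
    per_method: dict[str, pd.DataFrame] = {}
    for spec in config.methods:
        name, estimator = make_method(spec, seed=config.seed)
        results = meta_cross_validate(
            meta, estimator, folds=config.meta_folds, seed=config.seed
        )
        results.to_csv(out / f"metalearn_{name.replace('.', '_')}.csv")
        per_method[name] = results
    _timed("metalearn", t0)
    partial.meta = meta
    partial.per_method = per_method
    if stop < STAGES.index("report"):
        return partial

    t0 = time.perf_counter()
    default_rmse = meta.R[config.default_workflow]
    report = comparison_report(
        {name: res["realized_rmse"] for name, res in per_method.items()},
        default_rmse,
        default_name=f"Default ({config.default_workflow})",
    )
    summary_rows = {}
    for name, res in per_method.items():
        summary_rows[name] = {
            "selection_accuracy": selection_accuracy(res),
            "mean_spearman": float(res["spearman"].mean()),
        }
    summary = pd.DataFrame.from_dict(summary_rows, orient="index")
    summary["majority_class_rate"] = majority_class_rate(meta.best_label)
    report.to_csv(out / "report.csv")
    summary.to_csv(out / "summary.csv")
    _timed("report", t0)

    return ExperimentResult(
        collection=collection,
        perf=perf,
        metafeatures=features,
        meta=meta,
        per_method=per_method,
        report=report,
        summary=summary,
    )
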