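import warnings

import numpy as np
import pytest

import metaqsar as mq
from metaqsar.workflows import WorkflowSpec

# benchmark runs intentionally use small folds / few samples; convergence
# chatter from individual learners is part of normal operation
warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
try:
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


CHEAP_WORKFLOW_IDS = (
    "fnn.fpFCFP4",
    "ridge.basicmolprop.miss",
    "lm.allmolprop.miss",
)


@pytest.fixture(scope="session")
def tiny_collection():
    """Six targets, two per mechanism, small compound tables."""
    cfg = mq.SyntheticConfig(
        n_targets=6, compounds_range=(40, 60), n_fp_bits=32, n_basic_desc=8,
        n_all_desc=24, seed=123,
    )
    return mq.generate_collection(cfg)


@pytest.fixture(scope="session")
def cheap_workflows():
    return [WorkflowSpec.from_id(w) for w in CHEAP_WORKFLOW_IDS]


@pytest.fixture(scope="session")
def tiny_perf(tiny_collection, cheap_workflows):
    return mq.run_benchmark(tiny_collection, cheap_workflows, folds=5, seed=7)


@pytest.fixture(scope="session")
def tiny_meta(tiny_collection, tiny_perf):
    features = mq.collection_metafeatures(tiny_collection, seed=0)
    return mq.assemble_meta_dataset(features, tiny_perf)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
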