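"""Baseline QSAR learner registry and workflow enumeration.

A *workflow* is a (learner, representation) combination — the unit the
meta-learner selects between. The registry maps the benchmark's learner
short names to concrete scikit-learn estimators with fixed hyperparameter
settings: settings are chosen once to perform reasonably on most QSAR
datasets and are never tuned per dataset.

The full registry holds 18 learners, 17 of which run on every
representation while the Tanimoto-kernel SVM (``ksvmfp``) runs only on the
binary fingerprint representation, giving 17 x 3 + 1 = 52 workflows.

Some of the benchmark's original learners have no scikit-learn equivalent
and are realised as documented nearest equivalents: conditional trees and
forests as variance-split CART trees/forests with the same node-size
settings, adaptive regression splines as a spline-basis ridge expansion,
the relevance vector machine as RBF kernel ridge, and response-surface
regression as a quadratic polynomial ridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNetCV, LinearRegression, Ridge, RidgeCV
from sklearn.kernel_ridge import KernelRidge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.svm import SVR, NuSVR
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .data import FINGERPRINT_REPRESENTATION, REPRESENTATIONS


def tanimoto_kernel(A, B=None) -> np.ndarray:
    """Tanimoto (Jaccard) similarity between rows of binary matrices.

    ``K[i, j] = |a_i AND b_j| / |a_i OR b_j|``, with the 0/0 case of two
    all-zero vectors defined as 1 (identical emptiness). Accepts single
    vectors or matrices; entries must be 0/1.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = A if B is None else np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("fingerprint lengths differ")
    for M in (A, B):
        if not np.isin(M, (0.0, 1.0)).all():
            raise ValueError("tanimoto_kernel requires binary (0/1) input")
    inter = A @ B.T
    counts_a = A.sum(axis=1, keepdims=True)
    counts_b = B.sum(axis=1, keepdims=True)
    union = counts_a + counts_b.T - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
    return K


class TanimotoSVR(RegressorMixin, BaseEstimator):
    """Support vector regression with a Tanimoto kernel on binary fingerprints.

    The kernel matrix is precomputed with :func:`tanimoto_kernel`, making
    this the fingerprint-native kernel machine of the registry.
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1):
        self.C = C
        self.epsilon = epsilon

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.X_fit_ = X
        self.svr_ = SVR(kernel="precomputed", C=self.C, epsilon=self.epsilon)
        self.svr_.fit(tanimoto_kernel(X, X), np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        check_is_fitted(self, "svr_")
        return self.svr_.predict(tanimoto_kernel(np.asarray(X, dtype=float), self.X_fit_))


class AdaptivePLS(RegressorMixin, BaseEstimator):
    """PLS regression whose component count adapts to the fold size."""

    def __init__(self, max_components: int = 10):
        self.max_components = max_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        ncomp = max(1, min(self.max_components, X.shape[0] - 1, X.shape[1]))
        self.pls_ = PLSRegression(n_components=ncomp)
        self.pls_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        check_is_fitted(self, "pls_")
        return np.ravel(self.pls_.predict(np.asarray(X, dtype=float)))


class TwoLayerMLP(RegressorMixin, BaseEstimator):
    """Two-hidden-layer network sized relative to the input dimension.

    Layer widths are 1/3 and 2/3 of the number of inputs, resolved at fit
    time; inputs are standardised first.
    """

    def __init__(self, max_iter: int = 500, random_state: int | None = None):
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n_inputs = X.shape[1]
        sizes = (max(1, round(n_inputs / 3)), max(1, round(2 * n_inputs / 3)))
        self.model_ = make_pipeline(
            StandardScaler(),
            MLPRegressor(
                hidden_layer_sizes=sizes,
                max_iter=self.max_iter,
                random_state=self.random_state,
            ),
        )
        self.model_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


class AdaptivePCR(RegressorMixin, BaseEstimator):
    """Principal component regression with fold-size-capped components."""

    def __init__(self, max_components: int = 10):
        self.max_components = max_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        ncomp = max(1, min(self.max_components, X.shape[0] - 1, X.shape[1]))
        self.model_ = make_pipeline(
            StandardScaler(), PCA(n_components=ncomp), LinearRegression()
        )
        self.model_.fit(X, np.asarray(y, dtype=float))
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_TREE_NODE_SETTINGS = dict(min_samples_split=20, min_samples_leaf=7)


def _registry_factories() -> dict:
    return {
        "ctree": lambda rs, hp: DecisionTreeRegressor(
            **{**_TREE_NODE_SETTINGS, "random_state": rs, **hp}
        ),
        "rtree": lambda rs, hp: DecisionTreeRegressor(
            **{**_TREE_NODE_SETTINGS, "random_state": rs, **hp}
        ),
        "cforest": lambda rs, hp: RandomForestRegressor(
            **{
                "n_estimators": 500,
                **_TREE_NODE_SETTINGS,
                "max_features": 1.0 / 3.0,
                "random_state": rs,
                **hp,
            }
        ),
        "rforest": lambda rs, hp: RandomForestRegressor(
            **{
                "n_estimators": 500,
                **_TREE_NODE_SETTINGS,
                "max_features": 1.0 / 3.0,
                "random_state": rs,
                **hp,
            }
        ),
        "gbm": lambda rs, hp: GradientBoostingRegressor(
            **{
                "n_estimators": 100,
                "max_depth": 1,
                "min_samples_leaf": 10,
                "random_state": rs,
                **hp,
            }
        ),
        "fnn": lambda rs, hp: KNeighborsRegressor(**{"n_neighbors": 1, **hp}),
        "earth": lambda rs, hp: make_pipeline(
            SplineTransformer(n_knots=hp.get("n_knots", 5), degree=hp.get("degree", 3)),
            Ridge(alpha=hp.get("alpha", 1.0)),
        ),
        "glmnet": lambda rs, hp: make_pipeline(
            StandardScaler(),
            ElasticNetCV(
                **{"l1_ratio": 1.0, "alphas": 50, "cv": 5, "random_state": rs, **hp}
            ),
        ),
        "ridge": lambda rs, hp: make_pipeline(
            StandardScaler(), RidgeCV(alphas=hp.get("alphas", np.logspace(-3, 3, 13)))
        ),
        "lm": lambda rs, hp: LinearRegression(**hp),
        "pcr": lambda rs, hp: AdaptivePCR(**hp),
        "plsr": lambda rs, hp: AdaptivePLS(**hp),
        "rsm": lambda rs, hp: make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=hp.get("degree", 2), include_bias=False),
            Ridge(alpha=hp.get("alpha", 1.0)),
        ),
        "rvm": lambda rs, hp: make_pipeline(
            StandardScaler(), KernelRidge(**{"kernel": "rbf", "alpha": 0.1, **hp})
        ),
        "ksvm": lambda rs, hp: make_pipeline(
            StandardScaler(), NuSVR(**{"nu": 0.2, "kernel": "rbf", "C": 10.0, **hp})
        ),
        "ksvmfp": lambda rs, hp: TanimotoSVR(**{"epsilon": 0.1, **hp}),
        "nnet": lambda rs, hp: make_pipeline(
            StandardScaler(),
            MLPRegressor(
                **{
                    "hidden_layer_sizes": (3,),
                    "max_iter": 1000,
                    "random_state": rs,
                    **hp,
                }
            ),
        ),
        "nneth2o": lambda rs, hp: TwoLayerMLP(**{"random_state": rs, **hp}),
    }


#: Learners restricted to the fingerprint representation.
FINGERPRINT_ONLY_LEARNERS = frozenset({"ksvmfp"})

#: Canonical learner order (fingerprint-only learners last).
LEARNER_IDS = (
    "ctree", "rtree", "cforest", "rforest", "gbm", "fnn", "earth", "glmnet",
    "ridge", "lm", "pcr", "plsr", "rsm", "rvm", "ksvm", "nnet", "nneth2o",
    "ksvmfp",
)


@dataclass(frozen=True)
class WorkflowSpec:
    """A (learner, representation) combination with fixed hyperparameters."""

    learner_id: str
    representation: str
    hyperparameters: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.learner_id not in _registry_factories():
            raise ValueError(f"unknown learner {self.learner_id!r}")
        if (
            self.learner_id in FINGERPRINT_ONLY_LEARNERS
            and self.representation != FINGERPRINT_REPRESENTATION
        ):
            raise ValueError(
                f"{self.learner_id} runs only on {FINGERPRINT_REPRESENTATION}"
            )

    @property
    def workflow_id(self) -> str:
        return f"{self.learner_id}.{self.representation}"

    def make_estimator(self, random_state: int | None = None):
        """Instantiate a fresh estimator for this workflow."""
        factory = _registry_factories()[self.learner_id]
        return factory(random_state, dict(self.hyperparameters))

    @classmethod
    def from_id(cls, workflow_id: str, **hyperparameters) -> "WorkflowSpec":
        learner_id, _, representation = workflow_id.partition(".")
        return cls(learner_id, representation, tuple(sorted(hyperparameters.items())))


def enumerate_workflows(
    learner_ids=LEARNER_IDS,
    representations=REPRESENTATIONS,
    hyperparameters: dict | None = None,
) -> list[WorkflowSpec]:
    """Enumerate all compatible (learner, representation) workflows.

    General learners pair with every representation; fingerprint-only
    learners pair with the fingerprint representation only. The order is
    deterministic: learners in the given order, representations in the
    given order within each learner. With the full registry and the three
    standard representations this yields 52 workflows.
    """
    if not learner_ids:
        raise ValueError("empty learner registry")
    hyperparameters = hyperparameters or {}
    out: list[WorkflowSpec] = []
    for lid in learner_ids:
        hp = tuple(sorted(hyperparameters.get(lid, {}).items()))
        if lid in FINGERPRINT_ONLY_LEARNERS:
            if FINGERPRINT_REPRESENTATION not in representations:
                raise ValueError(
                    f"{lid} needs the {FINGERPRINT_REPRESENTATION} representation"
                )
            out.append(WorkflowSpec(lid, FINGERPRINT_REPRESENTATION, hp))
        else:
            for rep in representations:
                out.append(WorkflowSpec(lid, rep, hp))
    return out


#: Compact desk-scale registry: one strong member of each learner family,
#: paired with the representation it is naturally suited to. Used for
#: planted-collection experiments where running all 52 workflows would
#: dominate runtime without adding information.
DESK_WORKFLOW_IDS = (
    "rforest.fpFCFP4",
    "gbm.fpFCFP4",
    "fnn.fpFCFP4",
    "ksvmfp.fpFCFP4",
    "glmnet.allmolprop.miss",
    "ridge.basicmolprop.miss",
    "lm.basicmolprop.miss",
    "ksvm.allmolprop.miss",
)


def desk_workflows() -> list[WorkflowSpec]:
    return [WorkflowSpec.from_id(wid) for wid in DESK_WORKFLOW_IDS]
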