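"""Uniform probability-estimator contract over the comparator learners.

Every learner — the stable DNN ensemble, random forest, RBF-kernel SVM,
gradient boosting and the logistic baseline — is exposed behind the same
two-method contract: ``fit(design, outcomes)`` and
``predict_probability(design)`` returning values clipped into
[ε, 1−ε].  The permutation importance test and the evaluator only ever
talk to this contract, so the machinery is estimator-agnostic.

Comparator defaults follow the reference analysis: random forest with
1000 trees, minimum terminal-node size 3 and 4 candidate variables per
split; boosting with 5 iterations; an RBF-kernel margin classifier with
sigmoid-calibrated probabilities; an unpenalized logistic baseline.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .stable_dnn import (
    CLIP_EPSILON,
    NetworkSpec,
    StableDNNClassifier,
    TrainConfig,
    binary_cross_entropy,
    clip_probabilities,
)

VALID_NAMES = ("stable_dnn", "random_forest", "svm", "xgboost", "logistic", "prevalence")

__all__ = [
    "VALID_NAMES",
    "EstimatorFactory",
    "ProbabilityEstimator",
    "make_estimator",
    "tune_by_cv",
]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class EstimatorFactory:
    """Recipe for fresh, unfitted estimators; same factory+seed ⇒ exchangeable fits."""

    name: str
    hyperparameters: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in VALID_NAMES:
            raise ConfigurationError(
                f"unknown estimator {self.name!r}; valid names: {list(VALID_NAMES)}"
            )

    def with_seed(self, seed: int) -> "EstimatorFactory":
        return replace(self, seed=int(seed))

    def with_hyperparameters(self, **updates) -> "EstimatorFactory":
        merged = {**dict(self.hyperparameters), **updates}
        return replace(self, hyperparameters=merged)

    def make(self) -> "ProbabilityEstimator":
        return make_estimator(self)


class _PrevalenceStub:
    """Uninformative baseline: always predicts the training prevalence."""

    def fit(self, design, z):
        self.prevalence_ = float(np.mean(z))
        return self

    def predict_proba(self, design):
        p = np.full(len(design), self.prevalence_)
        return np.column_stack([1 - p, p])

    @property
    def classes_(self):
        return np.array([0, 1])


class ProbabilityEstimator:
    """Adapter enforcing the fit / predict_probability contract with clipping."""

    def __init__(self, name: str, model, clip_epsilon: float = CLIP_EPSILON,
                 clip_max_features: bool = False):
        self.name = name
        self.model = model
        self.clip_epsilon = clip_epsilon
        self._clip_max_features = clip_max_features
        self._fitted = False

    def fit(self, design: np.ndarray, z: np.ndarray) -> "ProbabilityEstimator":
        design = np.asarray(design, dtype=float)
        z = np.asarray(z, dtype=int)
        if self._clip_max_features:
            # the tree default of 4 candidate variables per split cannot
            # exceed the number of design columns
            mf = self.model.get_params()["max_features"]
            if isinstance(mf, (int, np.integer)) and mf > design.shape[1]:
                self.model.set_params(max_features=design.shape[1])
        self.model.fit(design, z)
        self._fitted = True
        return self

    def predict_probability(self, design: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("estimator not fitted")
        design = np.asarray(design, dtype=float)
        if hasattr(self.model, "predict_probability"):
            p = self.model.predict_probability(design)
        else:
            classes = np.asarray(self.model.classes_)
            pos = int(np.flatnonzero(classes == 1)[0])
            p = self.model.predict_proba(design)[:, pos]
        return clip_probabilities(p, self.clip_epsilon)


def make_estimator(factory: EstimatorFactory) -> ProbabilityEstimator:
    """Instantiate a fresh estimator under the probability contract."""
    hp = dict(factory.hyperparameters)
    seed = int(factory.seed)
    name = factory.name
    if name == "logistic":
        model = LogisticRegression(
            C=hp.pop("C", np.inf),  # unpenalized maximum likelihood by default
            max_iter=hp.pop("max_iter", 2000),
            solver="lbfgs",
            **hp,
        )
        return ProbabilityEstimator(name, model)
    if name == "random_forest":
        model = RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 1000),
            min_samples_leaf=hp.pop("min_samples_leaf", 3),
            max_features=hp.pop("max_features", 4),
            random_state=seed,
            n_jobs=1,
            **hp,
        )
        return ProbabilityEstimator(name, model, clip_max_features=True)
    if name == "xgboost":
        model = XGBClassifier(
            n_estimators=hp.pop("n_estimators", 5),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **hp,
        )
        return ProbabilityEstimator(name, model)
    if name == "svm":
        model = SVC(
            kernel=hp.pop("kernel", "rbf"),
            C=hp.pop("C", 1.0),
            gamma=hp.pop("gamma", "scale"),
            probability=True,  # sigmoid calibration of the margin scores
            random_state=seed,
            **hp,
        )
        return ProbabilityEstimator(name, model)
    if name == "stable_dnn":
        model = StableDNNClassifier(
            spec=NetworkSpec(hidden_widths=tuple(hp.pop("hidden_widths", (50, 40, 30, 20)))),
            cfg=TrainConfig(
                epochs=hp.pop("epochs", 100),
                batch_size=hp.pop("batch_size", 32),
                initial_learning_rate=hp.pop("initial_learning_rate", 1e-3),
                seed=seed,
            ),
            n_members=hp.pop("n_members", 100),
        )
        if hp:
            raise ConfigurationError(f"unknown stable_dnn hyperparameters: {sorted(hp)}")
        return ProbabilityEstimator(name, model)
    if name == "prevalence":
        return ProbabilityEstimator(name, _PrevalenceStub())
    raise ConfigurationError(
        f"unknown estimator {name!r}; valid names: {list(VALID_NAMES)}"
    )


def tune_by_cv(factory: EstimatorFactory, design: np.ndarray, z: np.ndarray,
               grid: Sequence[Mapping], folds: int = 5, seed: int = 0) -> EstimatorFactory:
    """Pick the grid point minimizing stratified-CV binary cross-entropy.

    Tuning folds are drawn only from the rows passed in, so evaluation
    rows held out by the caller are never seen here.  Ties break toward
    the first grid point in order.
    """
    if not grid:
        raise ConfigurationError("hyperparameter grid is empty")
    if folds < 2:
        raise ConfigurationError("need at least 2 tuning folds")
    design = np.asarray(design, dtype=float)
    z = np.asarray(z, dtype=int)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    try:
        splits = list(splitter.split(design, z))
    except ValueError as err:
        raise ConfigurationError(f"cannot build stratified tuning folds: {err}") from None
    losses = []
    for point in grid:
        fold_losses = []
        for tr, va in splits:
            if len(np.unique(z[tr])) < 2:
                raise ConfigurationError("degenerate single-class tuning fold")
            est = factory.with_hyperparameters(**point).make()
            est.fit(design[tr], z[tr])
            fold_losses.append(binary_cross_entropy(z[va], est.predict_probability(design[va])))
        losses.append(float(np.mean(fold_losses)))
    best = int(np.argmin(losses))  # first minimum wins on ties
    return factory.with_hyperparameters(**grid[best])
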