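"""Stable bagged deep-network ensemble with out-of-bag score filtering.

A single feedforward network trained by stochastic gradient descent is
sensitive to its random initialization, which makes its predictions (and
any feature-importance test built on them) unstable.  The remedy here is
bagging plus filtering: train K networks on bootstrap resamples, score
each member on its out-of-bag (OOB) rows with the mean log-likelihood
improvement over the constant predictor equal to the member's own OOB
mean,

    λ_k = (1/n_Ok) Σ_{i∈D_Ok} [ y_i log(ŷ_ik / ȳ_Ok)
                               + (1−y_i) log((1−ŷ_ik) / (1−ȳ_Ok)) ],

then keep only the top-λ members, choosing the ensemble size m that
minimizes the binary cross-entropy training loss of the averaged top-m
prediction.  A member that predicts its own OOB mean everywhere scores
exactly 0; anti-predictive members score negative.

The per-member network is a scikit-learn multilayer perceptron
(mini-batch SGD with an adaptive learning-rate schedule, ReLU hidden
units, logistic output); the default architecture is four hidden layers
of (50, 40, 30, 20) units with no dropout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier

CLIP_EPSILON = 1e-6  #: probabilities are clipped into [ε, 1−ε] wherever logged

SERIAL_SCHEMA_VERSION = 1

__all__ = [
    "CLIP_EPSILON",
    "NetworkSpec",
    "TrainConfig",
    "BootstrapPartition",
    "ScoredMember",
    "StableEnsemble",
    "StableDNNClassifier",
    "clip_probabilities",
    "binary_cross_entropy",
    "draw_bootstrap_partitions",
    "train_member",
    "oob_performance_score",
    "select_top_ensemble",
    "ensemble_predict",
]


def clip_probabilities(p: np.ndarray, eps: float = CLIP_EPSILON) -> np.ndarray:
    return np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps)


def binary_cross_entropy(z: np.ndarray, p: np.ndarray, eps: float = CLIP_EPSILON) -> float:
    z = np.asarray(z, dtype=float)
    p = clip_probabilities(p, eps)
    return float(-np.mean(z * np.log(p) + (1.0 - z) * np.log(1.0 - p)))


@dataclass(frozen=True)
class NetworkSpec:
    """Feedforward architecture: hidden widths, ReLU hidden units, logistic output."""

    hidden_widths: tuple[int, ...] = (50, 40, 30, 20)
    hidden_activation: str = "relu"

    def __post_init__(self) -> None:
        if not self.hidden_widths or any(w <= 0 for w in self.hidden_widths):
            raise ValueError("hidden_widths must be positive integers")


@dataclass(frozen=True)
class TrainConfig:
    """Per-member optimizer settings (config defaults, not tuned values)."""

    epochs: int = 100
    batch_size: int = 32
    initial_learning_rate: float = 1e-3
    lr_adaptation: str = "adaptive"  # divide the rate when training loss plateaus
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) <= 0 or self.initial_learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning rate must be positive")


@dataclass
class BootstrapPartition:
    """One bootstrap resample: in-bag multiset + its out-of-bag complement."""

    in_bag_indices: np.ndarray  # size n, drawn with replacement
    oob_indices: np.ndarray     # rows absent from in_bag

    @property
    def n_oob(self) -> int:
        return len(self.oob_indices)


@dataclass
class ScoredMember:
    network: object                 # fitted per-member model
    partition: BootstrapPartition
    lambda_k: float
    oob_predictions: np.ndarray
    oob_mean: float


@dataclass
class StableEnsemble:
    members: list[ScoredMember]
    selected: list[int]             # indices into members, λ-descending
    clip_epsilon: float = CLIP_EPSILON

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValueError("ensemble must select at least one member")
        sel = [self.members[i].lambda_k for i in self.selected]
        rest = [
            m.lambda_k for i, m in enumerate(self.members) if i not in set(self.selected)
        ]
        if rest and min(sel) < max(rest) - 1e-12:
            raise ValueError("selected members must be a top set under the λ ordering")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def draw_bootstrap_partitions(n: int, K: int, seed: int) -> list[BootstrapPartition]:
    """K uniform-with-replacement resamples of size n, each with nonempty OOB.

    A draw whose OOB set is empty is redrawn (logged as a warning); 100
    consecutive empty draws raise.
    """
    if n < 2 or K < 1:
        raise ValueError("need n >= 2 and K >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for _ in range(K):
        for attempt in range(100):
            in_bag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), in_bag)
            if len(oob) > 0:
                if attempt > 0:
                    warnings.warn(f"redrew bootstrap {attempt} time(s): empty OOB set")
                parts.append(BootstrapPartition(in_bag, oob))
                break
        else:
            raise RuntimeError("could not draw a bootstrap with a nonempty OOB set")
    return parts


# ---------------------------------------------------------------------------
# Member training
# ---------------------------------------------------------------------------

class SingleClassBagError(RuntimeError):
    """In-bag sample contains only one outcome class; member cannot be fit."""


def train_member(design_in_bag: np.ndarray, z_in_bag: np.ndarray,
                 spec: NetworkSpec, cfg: TrainConfig):
    """Fit one network on the in-bag rows by mini-batch SGD.

    The risk minimized is the binary cross-entropy; the learning rate is
    adapted downward when the training loss plateaus.  Deterministic given
    ``cfg.seed``.  Raises :class:`SingleClassBagError` when the bag holds a
    single outcome class (callers skip such members with a warning).
    """
    z_in_bag = np.asarray(z_in_bag, dtype=int)
    if len(np.unique(z_in_bag)) < 2:
        raise SingleClassBagError("in-bag sample has a single outcome class")
    net = MLPClassifier(
        hidden_layer_sizes=spec.hidden_widths,
        activation=spec.hidden_activation,
        solver="sgd",
        learning_rate="adaptive" if cfg.lr_adaptation == "adaptive" else "constant",
        learning_rate_init=cfg.initial_learning_rate,
        batch_size=min(cfg.batch_size, len(z_in_bag)),
        max_iter=cfg.epochs,
        momentum=0.9,
        early_stopping=False,
        n_iter_no_change=cfg.epochs,  # run the full epoch budget
        tol=0.0,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(design_in_bag, z_in_bag)
    return net


def _member_probabilities(net, design: np.ndarray) -> np.ndarray:
    pos = int(np.flatnonzero(net.classes_ == 1)[0])
    return net.predict_proba(design)[:, pos]


# ---------------------------------------------------------------------------
# OOB score and filtering
# ---------------------------------------------------------------------------

def oob_performance_score(z_oob: np.ndarray, yhat_oob: np.ndarray,
                          clip_epsilon: float = CLIP_EPSILON) -> float:
    """λ score: OOB log-likelihood gain over the member's own OOB mean."""
    z = np.asarray(z_oob, dtype=float)
    if len(z) == 0:
        raise ValueError("empty OOB set: bootstrap partition contract violated")
    if len(z) != len(yhat_oob):
        raise ValueError("outcome/prediction length mismatch")
    yhat = clip_probabilities(yhat_oob, clip_epsilon)
    ybar = float(np.clip(np.mean(yhat), clip_epsilon, 1.0 - clip_epsilon))
    terms = z * np.log(yhat / ybar) + (1.0 - z) * np.log((1.0 - yhat) / (1.0 - ybar))
    return float(np.mean(terms))


def select_top_ensemble(members: list[ScoredMember], design_train: np.ndarray,
                        z_train: np.ndarray,
                        clip_epsilon: float = CLIP_EPSILON) -> StableEnsemble:
    """Keep the top-m members under the λ ordering, m minimizing training loss.

    Members are sorted λ-descending (stable; original order breaks ties).
    For each prefix size m the binary cross-entropy of the averaged top-m
    prediction on the full training split is evaluated; the smallest m
    attaining the minimum wins.
    """
    if not members:
        raise ValueError("no scored members to select from")
    order = sorted(range(len(members)), key=lambda i: (-members[i].lambda_k, i))
    preds = np.stack(
        [_member_probabilities(members[i].network, design_train) for i in order]
    )
    running = np.cumsum(preds, axis=0) / np.arange(1, len(order) + 1)[:, None]
    losses = [binary_cross_entropy(z_train, running[m], clip_epsilon)
              for m in range(len(order))]
    best_m = int(np.argmin(losses)) + 1  # argmin returns the first minimum: ties → smallest m
    return StableEnsemble(members=members, selected=order[:best_m],
                          clip_epsilon=clip_epsilon)


def ensemble_predict(ens: StableEnsemble, design_new: np.ndarray) -> np.ndarray:
    """Unweighted mean of the selected members' probabilities, clipped."""
    width = ens.members[ens.selected[0]].network.n_features_in_
    if design_new.shape[1] != width:
        raise ValueError(
            f"design has {design_new.shape[1]} columns, ensemble expects {width}"
        )
    preds = np.stack(
        [_member_probabilities(ens.members[i].network, design_new) for i in ens.selected]
    )
    return clip_probabilities(preds.mean(axis=0), ens.clip_epsilon)


# ---------------------------------------------------------------------------
# sklearn-style wrapper used by the model zoo
# ---------------------------------------------------------------------------

@dataclass
class StableDNNClassifier:
    """fit/predict_probability wrapper over the bag–score–filter pipeline.

    One master ``seed`` determines the bootstrap partitions, every member's
    initialization and batch order, making the whole fit reproducible.
    ``K`` counts attempted bootstrap members; members whose bag is
    single-class are skipped with a warning.
    """

    spec: NetworkSpec = field(default_factory=NetworkSpec)
    cfg: TrainConfig = field(default_factory=TrainConfig)
    n_members: int = 100
    clip_epsilon: float = CLIP_EPSILON
    ensemble_: StableEnsemble | None = None
    n_skipped_: int = 0

    def fit(self, design: np.ndarray, z: np.ndarray) -> "StableDNNClassifier":
        design = np.asarray(design, dtype=float)
        z = np.asarray(z, dtype=int)
        parts = draw_bootstrap_partitions(len(z), self.n_members, self.cfg.seed)
        member_seeds = np.random.SeedSequence(self.cfg.seed).generate_state(
            self.n_members
        ) % (2**31)
        members: list[ScoredMember] = []
        self.n_skipped_ = 0
        for part, mseed in zip(parts, member_seeds):
            mcfg = TrainConfig(
                epochs=self.cfg.epochs,
                batch_size=self.cfg.batch_size,
                initial_learning_rate=self.cfg.initial_learning_rate,
                lr_adaptation=self.cfg.lr_adaptation,
                seed=int(mseed),
            )
            try:
                net = train_member(design[part.in_bag_indices], z[part.in_bag_indices],
                                   self.spec, mcfg)
            except SingleClassBagError:
                warnings.warn("skipping bagged member: single-class in-bag sample")
                self.n_skipped_ += 1
                continue
            yhat = clip_probabilities(
                _member_probabilities(net, design[part.oob_indices]), self.clip_epsilon
            )
            lam = oob_performance_score(z[part.oob_indices], yhat, self.clip_epsilon)
            members.append(
                ScoredMember(net, part, lam, yhat, float(np.mean(yhat)))
            )
        if not members:
            raise RuntimeError("every bagged member was skipped; cannot build ensemble")
        self.ensemble_ = select_top_ensemble(members, design, z, self.clip_epsilon)
        return self

    def predict_probability(self, design: np.ndarray) -> np.ndarray:
        if self.ensemble_ is None:
            raise RuntimeError("classifier not fitted")
        return ensemble_predict(self.ensemble_, np.asarray(design, dtype=float))

    # single-archive serialization with a schema version
    def save(self, path) -> None:
        joblib.dump({"schema_version": SERIAL_SCHEMA_VERSION, "model": self}, path)

    @staticmethod
    def load(path) -> "StableDNNClassifier":
        payload = joblib.load(path)
        if payload.get("schema_version") != SERIAL_SCHEMA_VERSION:
            raise ValueError("unrecognized ensemble archive version")
        return payload["model"]
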