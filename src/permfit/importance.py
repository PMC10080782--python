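"""Cross-fitted permutation feature-importance hypothesis test.

For a fitted conditional-probability model π̂ and a feature X_j, the
importance score contrasts the held-out log-likelihood of π̂ evaluated on
the original design with that on a design whose j-th feature has been
replaced by a random permutation of its own values (other features
untouched).  The per-subject term is

    Δ_ij = Z_i log( π̂(X_i) / π̂(X_i^(j)) )
         + (1−Z_i) log( (1−π̂(X_i)) / (1−π̂(X_i^(j))) ),

whose expectation under the true π is the KL divergence between
Bernoulli(π(X_i)) and Bernoulli(π(X_i^(j))) — zero exactly when X_j
contributes nothing conditional on the rest, positive otherwise.

Cross-fitting: the data are split into stratified folds; π̂ is fit on the
training part of each fold and the terms are evaluated on the disjoint
validation part only, removing the overfitting bias that would otherwise
inflate importance on training rows.  Terms are pooled over folds, and
the test statistic is

    δ = Δ̂ / sqrt( Var̂[terms] / n_V ),

compared against a one-sided upper standard-normal tail (importance is
nonnegative in expectation under the alternative).

Permutation acts on a whole clinical feature — the entire dummy-column
block of a categorical feature moves under a single shared row
permutation — so each feature receives exactly one coherent test.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .cohort_io import DesignMatrix, OutcomeVector
from .model_zoo import EstimatorFactory
from .stable_dnn import CLIP_EPSILON, clip_probabilities

__all__ = [
    "PermutedTable",
    "ImportanceRecord",
    "PermFITConfig",
    "derive_seed",
    "permute_feature_block",
    "importance_terms",
    "importance_test",
    "crossfit_importance",
    "significant_features",
    "records_table",
]


def derive_seed(master: int, *keys) -> int:
    """Deterministic sub-seed from a master seed and stable string/int keys.

    Keyed on content (not call order), so adding a feature or fold does
    not perturb the streams of the others.  Always < 2**31.
    """
    h = zlib.crc32(repr((int(master),) + tuple(keys)).encode())
    return int(h % (2**31))


# ---------------------------------------------------------------------------
# Permutation of a feature block
# ---------------------------------------------------------------------------

@dataclass
class PermutedTable:
    """A design with one feature's whole column block row-permuted."""

    matrix: np.ndarray
    feature: str
    permutation: np.ndarray


def permute_feature_block(design: DesignMatrix, feature: str,
                          rng: np.random.Generator,
                          permutation: np.ndarray | None = None) -> PermutedTable:
    """Permute all columns of *feature*'s block by one shared row permutation.

    Columns outside the block are bit-identical to the source.  An explicit
    *permutation* (e.g. the identity, or an enumerated one) overrides the
    rng draw.
    """
    sl = design.block_slice(feature)  # raises KeyError listing valid names
    n = design.n
    if permutation is None:
        permutation = rng.permutation(n)
    permutation = np.asarray(permutation)
    out = design.matrix.copy()
    out[:, sl] = design.matrix[permutation, sl]
    return PermutedTable(matrix=out, feature=feature, permutation=permutation)


# ---------------------------------------------------------------------------
# Importance terms and the test
# ---------------------------------------------------------------------------

def importance_terms(z: np.ndarray, p_orig: np.ndarray, p_perm: np.ndarray,
                     clip_epsilon: float = CLIP_EPSILON) -> np.ndarray:
    """Per-subject log-likelihood-ratio terms Δ_ij; their mean is Δ̂_j."""
    z = np.asarray(z, dtype=float)
    if not (len(z) == len(p_orig) == len(p_perm)):
        raise ValueError("z, p_orig and p_perm must have equal lengths")
    po = clip_probabilities(p_orig, clip_epsilon)
    pp = clip_probabilities(p_perm, clip_epsilon)
    return z * np.log(po / pp) + (1.0 - z) * np.log((1.0 - po) / (1.0 - pp))


def importance_test(terms: np.ndarray, n_V: int | None = None):
    """Z-type test of H0: feature irrelevant, from pooled per-subject terms.

    Returns ``(delta_hat, var_hat, delta_statistic, p_value)`` where
    ``var_hat`` is the variance of the mean: the per-term sample variance
    (1/n_V)Σ(term−Δ̂)² divided again by n_V.  The p-value is the one-sided
    upper normal tail.  Degenerate zero-variance inputs resolve by the
    sign of Δ̂ (positive → p=0, negative → p=1, both with a warning;
    exactly zero → δ=0, p=0.5).
    """
    terms = np.asarray(terms, dtype=float)
    if n_V is None:
        n_V = len(terms)
    if n_V < 2 or len(terms) < 2:
        raise ValueError("need at least 2 per-subject terms")
    delta_hat = float(np.mean(terms))
    per_term_var = float(np.mean((terms - delta_hat) ** 2))
    var_hat = per_term_var / n_V
    if var_hat == 0.0:
        if delta_hat > 0:
            warnings.warn("zero-variance terms with positive mean: p degenerates to 0")
            return delta_hat, 0.0, float("inf"), 0.0
        if delta_hat < 0:
            warnings.warn("zero-variance terms with negative mean: p degenerates to 1")
            return delta_hat, 0.0, float("-inf"), 1.0
        return 0.0, 0.0, 0.0, 0.5
    delta_stat = delta_hat / np.sqrt(var_hat)
    p_value = float(norm.sf(delta_stat))
    return delta_hat, var_hat, float(delta_stat), p_value


@dataclass
class ImportanceRecord:
    """Everything the test produced for one clinical feature."""

    feature: str
    delta_hat: float
    terms: np.ndarray          # pooled per-subject terms, fold order
    var_hat: float
    delta_statistic: float
    p_value: float
    n_V: int
    n_permutations: int
    degenerate: bool = False

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_hat))


@dataclass(frozen=True)
class PermFITConfig:
    """Knobs of the cross-fitted test; one master seed drives everything."""

    n_folds: int = 5
    n_permutations: int = 100
    alpha: float = 0.05
    seed: int = 0
    multiplicity_adjustment: str = "none"  # or "benjamini_hochberg"

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_permutations < 1:
            raise ValueError("need n_folds >= 2 and n_permutations >= 1")
        if not 0 < self.alpha <= 1:  # alpha = 1 allowed: "report everything"
            raise ValueError("alpha must lie in (0, 1]")
        if self.multiplicity_adjustment not in ("none", "benjamini_hochberg"):
            raise ValueError("multiplicity_adjustment must be none or benjamini_hochberg")


# ---------------------------------------------------------------------------
# Cross-fitted estimation
# ---------------------------------------------------------------------------

def crossfit_importance(
    design: DesignMatrix,
    z: OutcomeVector | np.ndarray,
    factory: EstimatorFactory,
    cfg: PermFITConfig,
    perm_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> list[ImportanceRecord]:
    """Run the full cross-fitted permutation importance test per feature.

    Per fold: fit a fresh estimator from *factory* on the training rows;
    for each feature draw ``cfg.n_permutations`` row permutations of the
    validation block and average the per-subject terms across permutations
    (variance reduction; a single permutation reproduces the plain
    single-shuffle estimator).  Terms are concatenated across folds and
    one :func:`importance_test` is run per feature on the pooled terms.

    ``perm_sampler(rng, n) -> index array`` replaces the uniform shuffle
    (used by tests to force the identity permutation or to enumerate all
    n! permutations).  Everything is deterministic under ``cfg.seed``; the
    per-feature permutation streams are keyed by feature name, so adding a
    feature leaves the other features' permutations unchanged.
    """
    zarr = z.as_int() if isinstance(z, OutcomeVector) else np.asarray(z, dtype=int)
    n = design.n
    if len(zarr) != n:
        raise ValueError("design and outcome lengths differ")
    splitter = StratifiedKFold(
        n_splits=cfg.n_folds, shuffle=True,
        random_state=derive_seed(cfg.seed, "folds"),
    )
    folds = list(splitter.split(design.matrix, zarr))

    features = list(design.feature_order)
    pooled_terms: dict[str, list[np.ndarray]] = {f: [] for f in features}
    degenerate_votes: dict[str, list[bool]] = {f: [] for f in features}

    for fold_id, (train_idx, val_idx) in enumerate(folds):
        if set(train_idx) & set(val_idx):
            raise RuntimeError("leakage: validation rows present in training set")
        if len(np.unique(zarr[train_idx])) < 2:
            raise ValueError("a training fold contains a single outcome class")
        est = factory.with_seed(derive_seed(cfg.seed, "estimator", fold_id)).make()
        est.fit(design.matrix[train_idx], zarr[train_idx])

        val_design = design.select_rows(val_idx)
        z_val = zarr[val_idx]
        p_orig = est.predict_probability(val_design.matrix)

        for feature in features:
            sl = design.block_slice(feature)
            block = val_design.matrix[:, sl]
            degenerate_votes[feature].append(bool(np.all(block == block[0])))
            rng = np.random.default_rng(
                derive_seed(cfg.seed, "perm", fold_id, feature)
            )
            acc = np.zeros(len(val_idx))
            for _ in range(cfg.n_permutations):
                perm = (perm_sampler(rng, len(val_idx)) if perm_sampler is not None
                        else rng.permutation(len(val_idx)))
                permuted = permute_feature_block(val_design, feature, rng, permutation=perm)
                p_perm = est.predict_probability(permuted.matrix)
                acc += importance_terms(z_val, p_orig, p_perm)
            pooled_terms[feature].append(acc / cfg.n_permutations)

    records = []
    for feature in features:
        terms = np.concatenate(pooled_terms[feature])
        if all(degenerate_votes[feature]):
            records.append(ImportanceRecord(
                feature=feature, delta_hat=0.0, terms=terms, var_hat=0.0,
                delta_statistic=0.0, p_value=1.0, n_V=len(terms),
                n_permutations=cfg.n_permutations, degenerate=True,
            ))
            continue
        delta_hat, var_hat, delta_stat, p = importance_test(terms)
        records.append(ImportanceRecord(
            feature=feature, delta_hat=delta_hat, terms=terms, var_hat=var_hat,
            delta_statistic=delta_stat, p_value=p, n_V=len(terms),
            n_permutations=cfg.n_permutations,
        ))
    return records


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _adjusted_pvalues(records: Sequence[ImportanceRecord], cfg: PermFITConfig) -> np.ndarray:
    p = np.array([r.p_value for r in records])
    if cfg.multiplicity_adjustment == "benjamini_hochberg":
        return multipletests(p, method="fdr_bh")[1]
    return p


def records_table(records: Sequence[ImportanceRecord],
                  cfg: PermFITConfig | None = None) -> pd.DataFrame:
    """Per-feature results table (feature, Δ̂, SE, δ, p, significant flag)."""
    cfg = cfg or PermFITConfig()
    p_adj = _adjusted_pvalues(records, cfg)
    return pd.DataFrame({
        "feature": [r.feature for r in records],
        "delta_hat": [r.delta_hat for r in records],
        "se": [r.se for r in records],
        "delta_statistic": [r.delta_statistic for r in records],
        "p_value": [r.p_value for r in records],
        "p_adjusted": p_adj,
        "significant": p_adj <= cfg.alpha,
        "degenerate": [r.degenerate for r in records],
    })


def significant_features(records: Sequence[ImportanceRecord],
                         cfg: PermFITConfig) -> pd.DataFrame:
    """Features with (adjusted) p ≤ α, ordered by p ascending then schema order."""
    table = records_table(records, cfg)
    table["_order"] = np.arange(len(table))
    out = (table[table["significant"]]
           .sort_values(["p_adjusted", "_order"], kind="stable")
           .drop(columns="_order")
           .reset_index(drop=True))
    return out
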