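"""Cross-validated prediction evaluation and the feature-restriction contrast.

Protocol: stratified 10-fold cross-validation producing out-of-fold
probabilities (each row predicted exactly once, by a model that never saw
it), classification at the 0.5 cutoff (strictly greater → positive),
and five metrics — accuracy, rank-method AUC, PR-AUC (average precision),
sensitivity, specificity — each with a 95% stratified-bootstrap interval.

The comparison re-runs the whole cross-validation twice per learner: once
with all features and once restricted to that learner's own significant
features from the permutation importance test.  Selection is not redone
inside each fold (two-stage presentation; the resulting optimism caveat
is documented in the README).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cohort_io import ClinicalFeatureTable, DesignMatrix, OutcomeVector, encode_design_matrix
from .importance import (
    PermFITConfig,
    crossfit_importance,
    derive_seed,
    records_table,
    significant_features,
)
from .model_zoo import EstimatorFactory

__all__ = [
    "CVFolds",
    "PredictionMetrics",
    "make_folds",
    "oof_predict",
    "classify_at_cutoff",
    "compute_metrics",
    "run_comparison",
    "roc_points",
    "run_full_pipeline",
]

N_BOOTSTRAP = 2000


@dataclass
class CVFolds:
    n_folds: int
    assignment: np.ndarray  # row -> fold id
    stratified: bool
    seed: int

    def split(self):
        for k in range(self.n_folds):
            val = np.flatnonzero(self.assignment == k)
            train = np.flatnonzero(self.assignment != k)
            yield train, val


@dataclass
class PredictionMetrics:
    accuracy: float
    auc: float
    pr_auc: float
    sensitivity: float
    specificity: float
    accuracy_ci: tuple[float, float]
    auc_ci: tuple[float, float]
    pr_auc_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    cutoff: float
    n: int

    def as_row(self) -> dict:
        row = {"n": self.n, "cutoff": self.cutoff}
        for name in ("accuracy", "auc", "pr_auc", "sensitivity", "specificity"):
            lo, hi = getattr(self, f"{name}_ci")
            row[name] = getattr(self, name)
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        return row


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_folds(z: OutcomeVector | np.ndarray, n_folds: int = 10, seed: int = 0) -> CVFolds:
    """Stratified fold assignment; per-class fold sizes differ by ≤ 1."""
    zarr = z.as_int() if isinstance(z, OutcomeVector) else np.asarray(z, dtype=int)
    n = len(zarr)
    if n < n_folds:
        raise ValueError("more folds than rows")
    assignment = np.empty(n, dtype=int)
    counts = np.bincount(zarr, minlength=2)
    if counts.min() < n_folds:
        warnings.warn(
            f"minority class has {counts.min()} members for {n_folds} folds; "
            "assigning that class round-robin"
        )
        rng = np.random.default_rng(seed)
        offset = 0  # stagger classes so all folds get filled
        for cls in np.unique(zarr):
            rows = rng.permutation(np.flatnonzero(zarr == cls))
            assignment[rows] = (offset + np.arange(len(rows))) % n_folds
            offset += len(rows)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for k, (_, val) in enumerate(splitter.split(np.zeros((n, 1)), zarr)):
            assignment[val] = k
    folds = CVFolds(n_folds=n_folds, assignment=assignment, stratified=True, seed=seed)
    for train, _ in folds.split():
        if len(np.unique(zarr[train])) < 2:
            raise ValueError("a training complement holds a single outcome class")
    return folds


# ---------------------------------------------------------------------------
# Out-of-fold prediction
# ---------------------------------------------------------------------------

def _restandardize(matrix: np.ndarray, cont_cols: Sequence[int],
                   train_idx: np.ndarray) -> np.ndarray:
    """Re-fit continuous-column standardization on the training rows only.

    Standardization is affine-equivariant, so re-z-scoring an already
    standardized column against the training rows equals standardizing the
    raw column against them.
    """
    out = matrix.copy()
    for c in cont_cols:
        mu = out[train_idx, c].mean()
        sd = out[train_idx, c].std() or 1.0
        out[:, c] = (out[:, c] - mu) / sd
    return out


def oof_predict(design: DesignMatrix, z: OutcomeVector | np.ndarray,
                factory: EstimatorFactory, folds: CVFolds,
                feature_subset: Sequence[str] | None = None) -> np.ndarray:
    """Out-of-fold probabilities: every row predicted once, never by a model
    that trained on it.  ``feature_subset`` restricts the design to those
    features' blocks (the significant-features-only arm)."""
    zarr = z.as_int() if isinstance(z, OutcomeVector) else np.asarray(z, dtype=int)
    d = design if feature_subset is None else design.subset_features(feature_subset)
    preds = np.full(d.n, np.nan)
    for fold_id, (train, val) in enumerate(folds.split()):
        if set(train) & set(val):
            raise RuntimeError("leakage: validation rows present in training set")
        mat = _restandardize(d.matrix, d.continuous_columns, train)
        est = factory.with_seed(derive_seed(factory.seed, "oof", fold_id)).make()
        est.fit(mat[train], zarr[train])
        preds[val] = est.predict_probability(mat[val])
    if np.isnan(preds).any():
        raise RuntimeError("some rows were never predicted")
    return preds


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classify_at_cutoff(probabilities: np.ndarray, cutoff: float = 0.5) -> np.ndarray:
    """ẑ = 1 iff π̂ strictly exceeds the cutoff (π̂ = cutoff → class 0)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p > cutoff).astype(int)


def _point_metrics(z: np.ndarray, p: np.ndarray, cutoff: float) -> dict[str, float]:
    zhat = classify_at_cutoff(p, cutoff)
    pos = z == 1
    neg = ~pos
    return {
        "accuracy": float(np.mean(zhat == z)),
        "auc": float(roc_auc_score(z, p)),
        "pr_auc": float(average_precision_score(z, p)),
        "sensitivity": float(np.mean(zhat[pos] == 1)) if pos.any() else float("nan"),
        "specificity": float(np.mean(zhat[neg] == 0)) if neg.any() else float("nan"),
    }


def compute_metrics(z: OutcomeVector | np.ndarray, probabilities: np.ndarray,
                    cutoff: float = 0.5, ci_method: str = "stratified_bootstrap",
                    seed: int = 0, n_bootstrap: int = N_BOOTSTRAP) -> PredictionMetrics:
    """Five metrics with 95% stratified-bootstrap intervals.

    Resampling is within-class (positives and negatives separately), so
    every resample retains both classes; intervals are percentile 2.5–97.5
    and are widened, if needed, to contain the point estimate.
    """
    zarr = z.as_int() if isinstance(z, OutcomeVector) else np.asarray(z, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(zarr)) < 2:
        raise ValueError("both outcome classes must be present")
    if ci_method != "stratified_bootstrap":
        raise ValueError("only stratified_bootstrap intervals are implemented")
    point = _point_metrics(zarr, p, cutoff)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(zarr == 1)
    neg_idx = np.flatnonzero(zarr == 0)
    samples = {k: np.empty(n_bootstrap) for k in point}
    for b in range(n_bootstrap):
        idx = np.concatenate([
            rng.choice(pos_idx, size=len(pos_idx), replace=True),
            rng.choice(neg_idx, size=len(neg_idx), replace=True),
        ])
        m = _point_metrics(zarr[idx], p[idx], cutoff)
        for k, v in m.items():
            samples[k][b] = v
    def ci(name):
        lo, hi = np.percentile(samples[name], [2.5, 97.5])
        return (float(min(lo, point[name])), float(max(hi, point[name])))
    return PredictionMetrics(
        **point,
        **{f"{k}_ci": ci(k) for k in point},
        cutoff=cutoff,
        n=len(zarr),
    )


def roc_points(z: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(z, p)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# The all-features vs significant-features comparison
# ---------------------------------------------------------------------------

def run_comparison(
    design: DesignMatrix,
    z: OutcomeVector | np.ndarray,
    factories: Mapping[str, EstimatorFactory],
    cfg: PermFITConfig,
    n_eval_folds: int = 10,
    significant_sets: Mapping[str, Sequence[str]] | None = None,
    n_bootstrap: int = N_BOOTSTRAP,
):
    """Per learner: metrics with all features vs its own significant set.

    When ``significant_sets`` is not supplied, each learner's set is
    computed here by the cross-fitted permutation importance test.  A
    learner whose significant set is empty has its restricted arm scored
    with the prevalence-predicting stub and flagged.

    Returns ``(metrics_table, importance_tables, roc_tables)``.
    """
    zarr = z.as_int() if isinstance(z, OutcomeVector) else np.asarray(z, dtype=int)
    folds = make_folds(zarr, n_folds=n_eval_folds, seed=derive_seed(cfg.seed, "eval"))
    rows = []
    importance_tables: dict[str, pd.DataFrame] = {}
    rocs: dict[tuple[str, str], pd.DataFrame] = {}
    for name, factory in factories.items():
        if significant_sets is not None:
            sig = list(significant_sets[name])
        else:
            records = crossfit_importance(design, zarr, factory, cfg)
            sig_table = significant_features(records, cfg)
            importance_tables[name] = sig_table
            sig = list(sig_table["feature"])
        arms = {"all_features": (factory, None, False)}
        if sig:
            arms["significant_only"] = (factory, sig, False)
        else:
            warnings.warn(f"{name}: empty significant set; restricted arm uses the "
                          "prevalence stub")
            arms["significant_only"] = (EstimatorFactory("prevalence"), None, True)
        for arm, (fac, subset, flagged) in arms.items():
            p = oof_predict(design, zarr, fac, folds, feature_subset=subset)
            m = compute_metrics(zarr, p, seed=derive_seed(cfg.seed, "boot", name, arm),
                                n_bootstrap=n_bootstrap)
            row = {"model": name, "arm": arm,
                   "n_features": len(subset) if subset else len(design.feature_order),
                   "empty_significant_set": flagged}
            row.update(m.as_row())
            rows.append(row)
            rocs[(name, arm)] = roc_points(zarr, p)
    return pd.DataFrame(rows), importance_tables, rocs


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------

def run_full_pipeline(table: ClinicalFeatureTable, outcome: OutcomeVector,
                      factory: EstimatorFactory, cfg: PermFITConfig,
                      n_eval_folds: int = 10,
                      n_bootstrap: int = N_BOOTSTRAP):
    """Encode → importance test → significant set → two-arm evaluation.

    Returns ``(importance_df, metrics_df)`` — the per-feature results
    table and the two-arm metrics table.  Fully deterministic under
    ``cfg.seed`` (one master seed fans out to folds, estimator seeds,
    permutation streams and bootstrap draws), so running it twice yields
    byte-identical CSV serializations.
    """
    design = encode_design_matrix(table)
    zarr = outcome.as_int()
    records = crossfit_importance(design, zarr, factory, cfg)
    importance_df = records_table(records, cfg)
    sig = list(significant_features(records, cfg)["feature"])
    metrics_df, _, _ = run_comparison(
        design, zarr, {factory.name: factory}, cfg,
        n_eval_folds=n_eval_folds,
        significant_sets={factory.name: sig},
        n_bootstrap=n_bootstrap,
    )
    return importance_df, metrics_df
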