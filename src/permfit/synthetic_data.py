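"""Synthetic under-2 head-trauma cohorts with known ground truth.

The generator emulates the public cohort's marginals — age in months
drawn from a right-skewed gamma shape matched to mean ≈ 9.3 / SD ≈ 6.75
and truncated to [0, 24); categorical levels drawn from the published
baseline frequencies where available; the structural "Not applicable"
links enforced exactly (e.g. hematoma size is "Not applicable" iff the
location is) — while attaching a fully known risk surface:

    logit π(x) = intercept + smooth non-monotone age term
               + categorical main effects
               + an age × hematoma-location interaction,

restricted to a declared signal-feature set.  Null features contribute
exactly zero, so permuting any null feature's column leaves the true
probabilities unchanged row-wise — the property that makes type-I-error
simulation honest.  The intercept is calibrated by bisection so the mean
risk hits the target prevalence (default 0.085, the cohort's ≈ 8.5%).

Features are sampled independently apart from the structural links;
realistic cross-feature correlation is deliberately not modelled (it
would break the null-feature guarantee).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort_io import (
    NOT_APPLICABLE,
    ClinicalFeatureTable,
    FeatureSchema,
    FeatureSpec,
    OutcomeVector,
    pecarn_schema,
)

__all__ = [
    "AgeInteraction",
    "RiskModel",
    "SyntheticConfig",
    "SyntheticCohort",
    "default_level_frequencies",
    "default_risk_model",
    "simulation_schema",
    "simulation_config",
    "sample_features",
    "true_risk",
    "calibrate_intercept",
    "generate_cohort",
]

AGE_MEAN = 9.30
AGE_SD = 6.75
AGE_MAX = 24.0

_CALIBRATION_SAMPLE = 100_000
_CALIBRATION_SEED = 20230406  # fixed: the intercept is a property of the config,
                              # not of the cohort seed
_PREVALENCE_TOL = 0.002


# ---------------------------------------------------------------------------
# Risk surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeInteraction:
    """Extra logit term coef·(center − age) for rows with feature ∈ levels."""

    feature: str
    levels: tuple[str, ...]
    coefficient: float
    age_center: float = 12.0


@dataclass(frozen=True)
class RiskModel:
    """Declared effects of the signal features on the logit scale.

    The age term is a smooth non-monotone bump plus a mild linear drift:
    ``bump_height·exp(−½((age−bump_center)/bump_width)²) + slope·age``.
    """

    age_feature: str = "age_months"
    age_bump_height: float = 0.0
    age_bump_center: float = 3.0
    age_bump_width: float = 3.5
    age_slope: float = 0.0
    categorical_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    interactions: tuple[AgeInteraction, ...] = ()

    @property
    def signal_features(self) -> frozenset[str]:
        names = set()
        if self.age_bump_height != 0.0 or self.age_slope != 0.0 or self.interactions:
            names.add(self.age_feature)
        names.update(
            f for f, eff in self.categorical_effects.items()
            if any(v != 0.0 for v in eff.values())
        )
        names.update(i.feature for i in self.interactions if i.coefficient != 0.0)
        return frozenset(names)

    def fingerprint(self) -> str:
        cat = tuple(sorted(
            (f, tuple(sorted(eff.items()))) for f, eff in self.categorical_effects.items()
        ))
        return repr((self.age_feature, self.age_bump_height, self.age_bump_center,
                     self.age_bump_width, self.age_slope, cat, self.interactions))

    def logit_contribution(self, values: pd.DataFrame) -> np.ndarray:
        """Signal-feature logit terms (no intercept); nulls contribute zero."""
        n = len(values)
        eta = np.zeros(n)
        if self.age_feature in values.columns:
            age = values[self.age_feature].to_numpy(dtype=float)
            if self.age_bump_height != 0.0:
                eta += self.age_bump_height * np.exp(
                    -0.5 * ((age - self.age_bump_center) / self.age_bump_width) ** 2
                )
            eta += self.age_slope * age
        for feature, effects in self.categorical_effects.items():
            col = values[feature]
            for level, coef in effects.items():
                if coef != 0.0:
                    eta += coef * (col == level).to_numpy(dtype=float)
        for inter in self.interactions:
            if inter.coefficient == 0.0:
                continue
            age = values[self.age_feature].to_numpy(dtype=float)
            mask = values[inter.feature].isin(inter.levels).to_numpy()
            eta += inter.coefficient * (inter.age_center - age) * mask
        return eta


def default_risk_model() -> RiskModel:
    """Default nonlinear, interactive risk surface on the 24-feature schema.

    Signal set mirrors the flagship findings qualitatively: age (smooth
    non-monotone), caregiver-reported acting-normally, altered mental
    status, injury mechanism, hematoma location and size, plus a
    younger-age × non-frontal-hematoma interaction.  Everything else is
    null by construction.
    """
    return RiskModel(
        age_bump_height=1.1,
        age_bump_center=3.0,
        age_bump_width=3.5,
        age_slope=-0.03,
        categorical_effects={
            "acting_normally": {"No": 0.8},
            "altered_mental_status": {"Yes": 1.0},
            "injury_mechanism": {
                "Motor vehicle collision": 1.2,
                "Pedestrian struck by moving vehicle": 1.0,
                "Fall from an elevation": 0.5,
                "Fall down stairs": 0.4,
            },
            "hematoma_location": {
                "Frontal": 0.3,
                "Occipital": 1.2,
                "Parietal/Temporal": 1.0,
            },
            "hematoma_size": {"Small": 0.1, "Medium": 0.4, "Large": 1.0},
        },
        interactions=(
            AgeInteraction(
                feature="hematoma_location",
                levels=("Occipital", "Parietal/Temporal"),
                coefficient=0.06,
                age_center=12.0,
            ),
        ),
    )


# ---------------------------------------------------------------------------
# Marginal level frequencies
# ---------------------------------------------------------------------------

def default_level_frequencies() -> dict[str, dict[str, float]]:
    """Per-feature sampling frequencies for the 24-feature schema.

    Features whose published baseline counts are available use those
    proportions (n = 1429 denominators; linked features use proportions
    conditional on being applicable).  The remainder use realistic values
    for a minor-head-trauma ED cohort.
    """
    n = 1429.0
    return {
        "injury_mechanism": {
            "Fall from an elevation": 858 / n,
            "Motor vehicle collision": 31 / n,
            "Pedestrian struck by moving vehicle": 12 / n,
            "Bike rider struck by automobile": 1 / n,
            "Bike collision or fall from bike": 2 / n,
            "Other wheeled transport crash": 11 / n,
            "Fall from standing/walking/running": 97 / n,
            "Walked or ran into stationary object": 42 / n,
            "Fall down stairs": 188 / n,
            "Sports": 0.0,
            "Assault": 15 / n,
            "Object struck head - accidental": 72 / n,
            "Other": 100 / n,
        },
        "injury_severity": {"Low": 0.55, "Moderate": 0.35, "High": 0.10},
        "loss_of_consciousness": {"No": 0.95, "Yes": 0.05},
        "post_traumatic_seizure": {"No": 1386 / n, "Yes": 43 / n},
        "seizure_duration": {"<1 min": 20 / 43, "1-<5 min": 20 / 43,
                             "5-15 min": 3 / 43, ">15 min": 0.0},
        "acting_normally": {"Yes": 962 / n, "No": 467 / n},
        "vomiting": {"No": 0.88, "Yes": 0.12},
        "vomiting_episodes": {"1": 0.5, "2": 0.3, ">2": 0.2},
        "altered_mental_status": {"No": 1013 / n, "Yes": 416 / n},
        "fontanelle_bulging": {"No": 0.99, "Yes": 0.01},
        "scalp_hematoma": {"No": 719 / n, "Yes": 710 / n},
        "hematoma_location": {"Frontal": 350 / 710, "Occipital": 94 / 710,
                              "Parietal/Temporal": 266 / 710},
        "hematoma_size": {"Small": 120 / 710, "Medium": 391 / 710, "Large": 199 / 710},
        "trauma_above_clavicles": {"No": 600 / n, "Yes": 829 / n},
        "trauma_face": {"No": 0.65, "Yes": 0.35},
        "trauma_neck": {"No": 0.97, "Yes": 0.03},
        "trauma_scalp_frontal": {"No": 488 / 829, "Yes": 341 / 829},
        "trauma_scalp_occipital": {"No": 0.85, "Yes": 0.15},
        "trauma_scalp_parietal": {"No": 672 / 829, "Yes": 157 / 829},
        "trauma_scalp_temporal": {"No": 0.92, "Yes": 0.08},
        "gender": {"Boy": 765 / n, "Girl": 664 / n},
        "ethnicity": {"Non-Hispanic": 0.75, "Hispanic": 0.25},
        "race": {"White": 0.55, "Black": 0.25, "Asian": 0.05, "Other": 0.15},
    }


# ---------------------------------------------------------------------------
# Config / cohort containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one generated cohort."""

    n: int = 1429
    seed: int = 0
    schema: FeatureSchema | None = None       # default: packaged 24-feature schema
    risk: RiskModel | None = None             # default: default_risk_model()
    level_frequencies: Mapping[str, Mapping[str, float]] | None = None
    target_prevalence: float = 0.085

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.n < 1:
            raise ValueError("n must be positive")

    def resolved_schema(self) -> FeatureSchema:
        return self.schema if self.schema is not None else pecarn_schema()

    def resolved_risk(self) -> RiskModel:
        return self.risk if self.risk is not None else default_risk_model()

    def resolved_frequencies(self) -> Mapping[str, Mapping[str, float]]:
        return (self.level_frequencies if self.level_frequencies is not None
                else default_level_frequencies())

    @property
    def signal_features(self) -> frozenset[str]:
        return self.resolved_risk().signal_features

    def fingerprint(self) -> str:
        schema = self.resolved_schema()
        freqs = self.resolved_frequencies()
        return repr((
            tuple((f.name, f.kind, f.levels, f.na_linked_to) for f in schema),
            tuple(sorted((k, tuple(sorted(v.items()))) for k, v in freqs.items())),
            self.resolved_risk().fingerprint(),
            self.target_prevalence,
        ))


@dataclass
class SyntheticCohort:
    table: ClinicalFeatureTable
    outcome: OutcomeVector
    true_probabilities: np.ndarray
    signal_features: frozenset[str]
    intercept: float


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_age(n: int, rng: np.random.Generator) -> np.ndarray:
    """Gamma draw matched to the cohort age moments, rejected onto [0, AGE_MAX)."""
    shape = (AGE_MEAN / AGE_SD) ** 2
    scale = AGE_SD**2 / AGE_MEAN
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.gamma(shape, scale, size=2 * (n - filled) + 10)
        draw = draw[draw < AGE_MAX]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _validated_frequencies(spec: FeatureSpec, freq: Mapping[str, float],
                           conditional: bool) -> tuple[list[str], np.ndarray]:
    levels = [l for l in spec.levels if not (conditional and l == NOT_APPLICABLE)]
    missing = [l for l in levels if l not in freq]
    if missing:
        raise ValueError(f"frequency map for {spec.name!r} missing levels {missing}")
    p = np.array([freq[l] for l in levels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"frequency map for {spec.name!r} sums to {p.sum():.6f}, not 1"
        )
    return levels, p


def sample_features(cfg: SyntheticConfig, rng: np.random.Generator) -> ClinicalFeatureTable:
    """Draw an n-row feature table honoring marginals and structural NA links."""
    schema = cfg.resolved_schema()
    freqs = cfg.resolved_frequencies()
    n = cfg.n
    columns: dict[str, np.ndarray | pd.Series] = {}
    for spec in schema:
        if spec.kind == "continuous":
            columns[spec.name] = _sample_age(n, rng)
            continue
        conditional = spec.na_linked_to is not None
        levels, p = _validated_frequencies(spec, freqs[spec.name], conditional)
        draw = np.asarray(levels, dtype=object)[rng.choice(len(levels), size=n, p=p)]
        if conditional:
            parent = np.asarray(columns[spec.na_linked_to], dtype=object)
            forced = np.isin(parent, ("No", NOT_APPLICABLE))
            draw = np.where(forced, NOT_APPLICABLE, draw)
        columns[spec.name] = draw
    values = pd.DataFrame(columns)
    return ClinicalFeatureTable(schema=schema, values=values,
                                subject_ids=np.arange(n))


# ---------------------------------------------------------------------------
# Risk and calibration
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


_intercept_cache: dict[str, float] = {}


def calibrate_intercept(cfg: SyntheticConfig,
                        rng: np.random.Generator | None = None) -> float:
    """Bisection on the intercept until mean risk hits the target prevalence.

    Uses a 100,000-row calibration sample (its own fixed stream, so the
    intercept is a deterministic property of the config, shared across
    cohort seeds).  Tolerance ±0.002 on the mean risk.
    """
    key = cfg.fingerprint()
    if rng is None and key in _intercept_cache:
        return _intercept_cache[key]
    rng = rng or np.random.default_rng(_CALIBRATION_SEED)
    calib_cfg = SyntheticConfig(
        n=_CALIBRATION_SAMPLE, seed=cfg.seed, schema=cfg.schema, risk=cfg.risk,
        level_frequencies=cfg.level_frequencies,
        target_prevalence=cfg.target_prevalence,
    )
    eta = cfg.resolved_risk().logit_contribution(sample_features(calib_cfg, rng).values)
    lo, hi = -30.0, 30.0
    if not (_sigmoid(lo + eta).mean() <= cfg.target_prevalence <= _sigmoid(hi + eta).mean()):
        raise ValueError(
            f"target prevalence {cfg.target_prevalence} unreachable with these "
            f"effects (bracket [{lo}, {hi}] gives "
            f"[{_sigmoid(lo + eta).mean():.4f}, {_sigmoid(hi + eta).mean():.4f}])"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean_pi = float(_sigmoid(mid + eta).mean())
        if abs(mean_pi - cfg.target_prevalence) <= _PREVALENCE_TOL:
            break
        if mean_pi < cfg.target_prevalence:
            lo = mid
        else:
            hi = mid
    _intercept_cache[key] = mid
    return mid


def true_risk(table: ClinicalFeatureTable, cfg: SyntheticConfig,
              intercept: float | None = None) -> np.ndarray:
    """True conditional probability π(x) for every row of *table*."""
    if intercept is None:
        intercept = calibrate_intercept(cfg)
    eta = cfg.resolved_risk().logit_contribution(table.values)
    return _sigmoid(intercept + eta)


def generate_cohort(cfg: SyntheticConfig) -> SyntheticCohort:
    """Sample features, evaluate the true risk, draw Bernoulli outcomes."""
    intercept = calibrate_intercept(cfg)
    rng = np.random.default_rng(cfg.seed)
    table = sample_features(cfg, rng)
    pi = true_risk(table, cfg, intercept=intercept)
    z = rng.binomial(1, pi).astype(float)
    return SyntheticCohort(
        table=table,
        outcome=OutcomeVector(z),
        true_probabilities=pi,
        signal_features=cfg.signal_features,
        intercept=intercept,
    )


# ---------------------------------------------------------------------------
# Compact simulation schema (type-I error / power studies)
# ---------------------------------------------------------------------------

def simulation_schema() -> FeatureSchema:
    """Small mixed-type schema for operating-characteristic simulations.

    One planted binary signal, one continuous null (age) and four
    categorical nulls of varying arity — enough structure to exercise the
    block permutation without the cost of the full 24-feature layout.
    """
    return FeatureSchema((
        FeatureSpec("age_months", "continuous"),
        FeatureSpec("signal_flag", "binary", ("No", "Yes")),
        FeatureSpec("null_even", "binary", ("No", "Yes")),
        FeatureSpec("null_rare", "binary", ("No", "Yes")),
        FeatureSpec("null_three", "categorical", ("A", "B", "C")),
        FeatureSpec("null_four", "categorical", ("A", "B", "C", "D")),
    ))


def simulation_config(n: int = 1500, seed: int = 0, effect: float = 2.0,
                      target_prevalence: float = 0.085) -> SyntheticConfig:
    """Study conditions for the type-I-error / power simulations.

    The planted signal is a binary feature with logit effect *effect* on
    its "Yes" level (prevalence 0.3); every other feature is null.
    """
    freqs = {
        "signal_flag": {"No": 0.7, "Yes": 0.3},
        "null_even": {"No": 0.5, "Yes": 0.5},
        "null_rare": {"No": 0.9, "Yes": 0.1},
        "null_three": {"A": 0.5, "B": 0.3, "C": 0.2},
        "null_four": {"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.1},
    }
    risk = RiskModel(categorical_effects={"signal_flag": {"Yes": float(effect)}})
    return SyntheticConfig(
        n=n, seed=seed, schema=simulation_schema(), risk=risk,
        level_frequencies=freqs, target_prevalence=target_prevalence,
    )
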