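"""Reading, filtering, summarizing and encoding clinical cohort tables.

The cohort layout mirrors the public-use pediatric head-trauma dataset:
one row per child, 24 mixed-type clinical features (one continuous age in
months, the rest binary/categorical with structured "Not applicable"
levels), and a binary CT-confirmed TBI outcome.

The design-matrix encoder keeps a block map from each clinical feature to
its contiguous columns so that downstream permutation importance can act
on a whole feature (all of a categorical feature's dummy columns at once)
rather than on individual encoded columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

NOT_APPLICABLE = "Not applicable"

__all__ = [
    "NOT_APPLICABLE",
    "FeatureSpec",
    "FeatureSchema",
    "ClinicalFeatureTable",
    "OutcomeVector",
    "DesignMatrix",
    "DesignEncoder",
    "pecarn_schema",
    "read_cohort_csv",
    "apply_cohort_filters",
    "summarize_cohort",
    "encode_design_matrix",
]


class SchemaError(ValueError):
    """Raised when a schema or a table violating its schema is encountered."""


class EmptyCohortError(ValueError):
    """Raised when cohort filtering removes every row."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """One clinical feature: its kind and, for categoricals, its level set.

    ``na_linked_to`` names a parent feature whose "No"/"Not applicable"
    value structurally forces this feature to "Not applicable" (e.g. the
    hematoma size is "Not applicable" exactly when no hematoma location
    was recorded).
    """

    name: str
    kind: str  # {"continuous", "binary", "categorical"}
    levels: tuple[str, ...] = ()
    na_linked_to: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "continuous":
            if self.levels:
                raise SchemaError(f"continuous feature {self.name!r} cannot declare levels")
        else:
            if len(self.levels) < 2:
                raise SchemaError(f"feature {self.name!r} needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"duplicate levels in feature {self.name!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary feature {self.name!r} must have exactly 2 levels")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` describing one cohort layout."""

    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names in schema")
        for f in self.features:
            if f.na_linked_to is not None and f.na_linked_to not in names:
                raise SchemaError(
                    f"feature {f.name!r} links to unknown feature {f.na_linked_to!r}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def continuous_names(self) -> list[str]:
        return [f.name for f in self.features if f.kind == "continuous"]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "FeatureSchema":
        feats = []
        for e in entries:
            feats.append(
                FeatureSpec(
                    name=e["name"],
                    kind=e["kind"],
                    levels=tuple(e.get("levels", ()) or ()),
                    na_linked_to=e.get("na_linked_to"),
                )
            )
        return cls(tuple(feats))

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["features"])

    def to_yaml(self, path) -> None:
        doc = {
            "features": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    **({"levels": list(f.levels)} if f.levels else {}),
                    **({"na_linked_to": f.na_linked_to} if f.na_linked_to else {}),
                }
                for f in self.features
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def pecarn_schema() -> FeatureSchema:
    """The packaged 24-feature schema for the under-2 head-trauma cohort.

    Exactly one continuous feature (age in months); categorical level sets
    follow the published baseline-characteristics table, including the
    13-level injury mechanism and the structurally linked "Not applicable"
    levels of hematoma location/size and the seizure/vomiting/trauma-region
    follow-up questions.
    """
    ref = resources.files("permfit") / "data" / "pecarn_schema.yaml"
    with resources.as_file(ref) as path:
        schema = FeatureSchema.from_yaml(path)
    if len(schema) != 24:
        raise SchemaError("packaged cohort schema must have exactly 24 features")
    if len(schema.continuous_names) != 1:
        raise SchemaError("packaged cohort schema must have exactly one continuous feature")
    return schema


# ---------------------------------------------------------------------------
# Tables and outcomes
# ---------------------------------------------------------------------------

@dataclass
class ClinicalFeatureTable:
    """An n-by-p grid of feature values with its schema and subject ids.

    ``values`` columns are ordered as the schema; categorical cells are the
    literal level labels (strings), continuous cells floats.  Before cohort
    filtering a table may contain missing cells (NaN / labels outside the
    declared levels); :meth:`validate` enforces the complete-case contract.
    """

    schema: FeatureSchema
    values: pd.DataFrame
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        if list(self.values.columns) != self.schema.names:
            self.values = self.values[self.schema.names]
        self.subject_ids = np.asarray(self.subject_ids)
        if len(self.subject_ids) != len(self.values):
            raise ValueError("subject_ids length must match table rows")

    @property
    def n(self) -> int:
        return len(self.values)

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of cells that are missing or outside declared levels."""
        masks = {}
        for f in self.schema:
            col = self.values[f.name]
            if f.kind == "continuous":
                num = pd.to_numeric(col, errors="coerce")
                masks[f.name] = ~np.isfinite(num.to_numpy(dtype=float))
            else:
                masks[f.name] = ~col.isin(f.levels)
        return pd.DataFrame(masks, index=self.values.index)

    def validate(self) -> None:
        mask = self.missing_mask()
        if mask.to_numpy().any():
            bad = mask.any(axis=1)
            raise SchemaError(
                f"{int(bad.sum())} rows contain missing or out-of-schema cells; "
                "apply cohort filters first"
            )

    def select_rows(self, idx: np.ndarray) -> "ClinicalFeatureTable":
        return ClinicalFeatureTable(
            schema=self.schema,
            values=self.values.iloc[idx].reset_index(drop=True),
            subject_ids=self.subject_ids[idx],
        )


@dataclass
class OutcomeVector:
    """Binary outcome per subject; NaN allowed only before cohort filtering."""

    z: np.ndarray
    positive_label_meaning: str = "CT-confirmed TBI"

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    @property
    def n(self) -> int:
        return len(self.z)

    def known_mask(self) -> np.ndarray:
        return np.isfinite(self.z)

    def validate(self) -> None:
        if not np.all(np.isin(self.z, (0.0, 1.0))):
            raise ValueError("outcome vector must contain only 0/1 after filtering")

    def as_int(self) -> np.ndarray:
        self.validate()
        return self.z.astype(int)

    def select(self, idx: np.ndarray) -> "OutcomeVector":
        return OutcomeVector(self.z[idx], self.positive_label_meaning)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_cohort_csv(path, schema: FeatureSchema, outcome_column: str):
    """Parse a delimited cohort file against *schema*.

    Returns ``(table, outcome, row_report)``.  Nothing is dropped here:
    rows containing blank, unparseable or out-of-level cells (or an unknown
    outcome) are recorded in ``row_report``, a DataFrame with columns
    ``row`` (0-based) and ``issues`` (';'-joined descriptions), and left in
    place for :func:`apply_cohort_filters` to remove.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in schema.names + [outcome_column] if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"cohort file is missing required columns: {missing_cols}")

    values = {}
    issues: dict[int, list[str]] = {}

    def flag(i: int, msg: str) -> None:
        issues.setdefault(i, []).append(msg)

    for f in schema:
        col = raw[f.name].str.strip()
        if f.kind == "continuous":
            num = pd.to_numeric(col, errors="coerce")
            for i in np.flatnonzero(~np.isfinite(num.to_numpy(dtype=float))):
                flag(int(i), f"{f.name}: unparseable or blank continuous cell")
            values[f.name] = num
        else:
            for i in np.flatnonzero(~col.isin(f.levels).to_numpy()):
                cell = col.iloc[int(i)]
                kind = "blank" if cell == "" else f"unrecognized level {cell!r}"
                flag(int(i), f"{f.name}: {kind}")
            values[f.name] = col

    zraw = raw[outcome_column].str.strip()
    z = pd.to_numeric(zraw, errors="coerce").to_numpy(dtype=float)
    bad_outcome = ~np.isin(z, (0.0, 1.0))
    z[bad_outcome] = np.nan
    for i in np.flatnonzero(bad_outcome):
        flag(int(i), f"{outcome_column}: outcome not 0/1")

    table = ClinicalFeatureTable(
        schema=schema,
        values=pd.DataFrame(values),
        subject_ids=raw.index.to_numpy(),
    )
    outcome = OutcomeVector(z)
    row_report = pd.DataFrame(
        {
            "row": sorted(issues),
            "issues": ["; ".join(issues[i]) for i in sorted(issues)],
        }
    )
    return table, outcome, row_report


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------

def apply_cohort_filters(
    table: ClinicalFeatureTable,
    outcome: OutcomeVector,
    age_months_max: float = 24.0,
    require_outcome_known: bool = True,
):
    """Apply the cohort-derivation filters in a fixed order.

    Retains rows with age strictly below ``age_months_max`` ("under age 2"
    means the 24-month boundary itself is excluded), a known 0/1 outcome,
    and no missing cells across all schema features (complete cases).
    ``filter_log`` is a DataFrame recording rows removed by each criterion
    sequentially, in the order: age, outcome known, complete case.
    """
    if table.n != outcome.n:
        raise ValueError("table and outcome lengths differ")
    age_col = table.schema.continuous_names[0]
    age = pd.to_numeric(table.values[age_col], errors="coerce").to_numpy(dtype=float)

    keep = np.ones(table.n, dtype=bool)
    log_rows = []

    age_ok = np.isfinite(age) & (age < age_months_max)
    removed = int(np.sum(keep & ~age_ok))
    keep &= age_ok
    log_rows.append(("age", removed, int(keep.sum())))

    if require_outcome_known:
        known = outcome.known_mask()
        removed = int(np.sum(keep & ~known))
        keep &= known
        log_rows.append(("outcome_known", removed, int(keep.sum())))
    else:
        log_rows.append(("outcome_known", 0, int(keep.sum())))

    complete = ~table.missing_mask().to_numpy().any(axis=1)
    removed = int(np.sum(keep & ~complete))
    keep &= complete
    log_rows.append(("complete_case", removed, int(keep.sum())))

    if not keep.any():
        raise EmptyCohortError("cohort filters removed every row")

    idx = np.flatnonzero(keep)
    out_table = table.select_rows(idx)
    # continuous columns become clean floats after filtering
    for name in out_table.schema.continuous_names:
        out_table.values[name] = pd.to_numeric(out_table.values[name])
    out_outcome = outcome.select(idx)
    out_outcome.validate()
    out_table.validate()
    filter_log = pd.DataFrame(log_rows, columns=["criterion", "removed", "remaining"])
    return out_table, out_outcome, filter_log


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------

def summarize_cohort(table: ClinicalFeatureTable, outcome: OutcomeVector) -> pd.DataFrame:
    """Baseline-characteristics summary of a filtered cohort.

    One row per categorical level (count + percent within the feature, so
    percentages sum to 100 within a feature up to rounding), one row per
    continuous feature (mean, sd), plus a final outcome-prevalence row.
    """
    table.validate()
    rows = []
    n = table.n
    for f in table.schema:
        col = table.values[f.name]
        if f.kind == "continuous":
            num = col.to_numpy(dtype=float)
            rows.append((f.name, "mean (sd)", np.nan, np.nan, float(np.mean(num)), float(np.std(num, ddof=1))))
        else:
            counts = col.value_counts()
            for level in f.levels:
                c = int(counts.get(level, 0))
                rows.append((f.name, level, c, 100.0 * c / n, np.nan, np.nan))
    z = outcome.as_int()
    rows.append(("outcome", "positive", int(z.sum()), 100.0 * z.mean(), np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["feature", "level", "count", "percent", "mean", "sd"]
    )


# ---------------------------------------------------------------------------
# Design-matrix encoding
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Numeric n-by-q design with a feature → column-block map.

    Categorical features use reference-level (m−1 dummy) coding: the first
    declared level is the reference and contributes the all-zero row within
    the block.  Continuous features are standardized with parameters stored
    on the encoder so held-out rows reuse the training-time transform.
    """

    matrix: np.ndarray
    column_blocks: dict[str, tuple[int, int]]  # name -> (start, stop)
    encoding: str
    feature_order: tuple[str, ...]
    continuous_columns: tuple[int, ...]
    encoder: "DesignEncoder | None" = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def q(self) -> int:
        return self.matrix.shape[1]

    def block_slice(self, feature: str) -> slice:
        if feature not in self.column_blocks:
            raise KeyError(
                f"unknown feature {feature!r}; valid: {sorted(self.column_blocks)}"
            )
        start, stop = self.column_blocks[feature]
        return slice(start, stop)

    def subset_features(self, features: Sequence[str]) -> "DesignMatrix":
        """Design restricted to *features* (original schema order kept)."""
        ordered = [f for f in self.feature_order if f in set(features)]
        unknown = set(features) - set(self.feature_order)
        if unknown:
            raise KeyError(f"unknown features {sorted(unknown)}")
        cols: list[int] = []
        blocks: dict[str, tuple[int, int]] = {}
        for name in ordered:
            start, stop = self.column_blocks[name]
            blocks[name] = (len(cols), len(cols) + (stop - start))
            cols.extend(range(start, stop))
        cont = tuple(
            i for i, c in enumerate(cols) if c in set(self.continuous_columns)
        )
        return DesignMatrix(
            matrix=self.matrix[:, cols].copy(),
            column_blocks=blocks,
            encoding=self.encoding,
            feature_order=tuple(ordered),
            continuous_columns=cont,
            encoder=self.encoder,
        )

    def select_rows(self, idx: np.ndarray) -> "DesignMatrix":
        return replace(self, matrix=self.matrix[idx])


@dataclass
class DesignEncoder:
    """Reference-level dummy coder + continuous standardizer, fit on training rows."""

    schema: FeatureSchema | None = None
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    def fit(self, table: ClinicalFeatureTable) -> "DesignEncoder":
        table.validate()
        self.schema = table.schema
        for name in table.schema.continuous_names:
            col = table.values[name].to_numpy(dtype=float)
            self.means[name] = float(np.mean(col))
            sd = float(np.std(col))
            self.sds[name] = sd if sd > 0 else 1.0
        return self

    def transform(self, table: ClinicalFeatureTable) -> DesignMatrix:
        if self.schema is None:
            raise RuntimeError("encoder not fitted")
        if table.schema.names != self.schema.names:
            raise SchemaError("table schema does not match encoder schema")
        cols: list[np.ndarray] = []
        blocks: dict[str, tuple[int, int]] = {}
        cont_cols: list[int] = []
        for f in self.schema:
            start = len(cols)
            col = table.values[f.name]
            if f.kind == "continuous":
                x = col.to_numpy(dtype=float)
                cols.append((x - self.means[f.name]) / self.sds[f.name])
                cont_cols.append(start)
            else:
                bad = ~col.isin(f.levels)
                if bad.any():
                    row = int(np.flatnonzero(bad.to_numpy())[0])
                    raise SchemaError(
                        f"feature {f.name!r} row {row}: value {col.iloc[row]!r} "
                        f"outside declared levels"
                    )
                for level in f.levels[1:]:  # first level = reference
                    cols.append((col == level).to_numpy(dtype=float))
            blocks[f.name] = (start, len(cols))
        matrix = np.column_stack(cols) if cols else np.empty((table.n, 0))
        return DesignMatrix(
            matrix=matrix,
            column_blocks=blocks,
            encoding="reference_dummy+standardized",
            feature_order=tuple(self.schema.names),
            continuous_columns=tuple(cont_cols),
            encoder=self,
        )

    def inverse_transform(self, design: DesignMatrix) -> ClinicalFeatureTable:
        """Decode a design back to labelled values (round-trip check)."""
        if self.schema is None:
            raise RuntimeError("encoder not fitted")
        data = {}
        for f in self.schema:
            start, stop = design.column_blocks[f.name]
            block = design.matrix[:, start:stop]
            if f.kind == "continuous":
                data[f.name] = block[:, 0] * self.sds[f.name] + self.means[f.name]
            else:
                idx = np.zeros(design.n, dtype=int)
                hit = block > 0.5
                which = np.argmax(hit, axis=1) + 1
                idx = np.where(hit.any(axis=1), which, 0)
                data[f.name] = np.asarray(f.levels)[idx]
        return ClinicalFeatureTable(
            schema=self.schema,
            values=pd.DataFrame(data),
            subject_ids=np.arange(design.n),
        )


def encode_design_matrix(table: ClinicalFeatureTable) -> DesignMatrix:
    """Fit a :class:`DesignEncoder` on *table* and encode it."""
    return DesignEncoder().fit(table).transform(table)
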