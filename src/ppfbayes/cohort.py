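"""Cohort schema, I/O, descriptive statistics and preparation steps.

The analysis table is a small patient-level cohort: pulmonary-function
measurements, bronchoalveolar-lavage (BAL) differential cell counts, and
relative-expression biomarkers (exosomal miR-21, miR-92a and KL-6 on the
2^-ddCT scale), together with two binary clinical targets — diagnosis
(progressive vs non-progressive pulmonary fibrosis, PPF/nPPF) and prognosis
(RAPID/SLOW progression).

Missing values are kept as an explicit mask (NaN in numeric columns) and are
never imputed: analyses are strictly complete-case over the feature subset
they use.  Numeric features are standardized by z-score,
``z = (x - mean(x)) / std(x)``, with the population-std convention (divisor
``n``) by default so that a standardized column has std exactly 1.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMeta",
    "FeatureStats",
    "CohortTable",
    "ZScoreTransform",
    "STUDY_SCHEMA",
    "NUMERIC_FEATURES",
    "GENETIC_FEATURES",
    "TARGET_LEVELS",
    "table1_stats",
    "load_cohort",
    "save_cohort",
    "compute_stats",
    "drop_incomplete",
    "zscore_normalize",
    "iqr_fences",
]

# Feature groups used by the selection stages.  Derived pairwise products of
# two genetic biomarkers inherit the "mirna_biomarker" group; products mixing
# groups are tagged "derived".
GROUPS = ("functional", "bal_marker", "mirna_biomarker", "derived", "covariate", "target")


@dataclass(frozen=True)
class FeatureMeta:
    """Schema entry for one cohort column."""

    name: str
    dtype: str  # "numeric" | "nominal"
    group: str

    def __post_init__(self) -> None:
        if self.dtype not in ("numeric", "nominal"):
            raise ValueError(f"unknown dtype {self.dtype!r} for feature {self.name!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for feature {self.name!r}")


# Canonical study schema: 11 numeric features, 2 nominal covariates, 2 targets.
STUDY_SCHEMA: tuple[FeatureMeta, ...] = (
    FeatureMeta("Age", "numeric", "functional"),
    FeatureMeta("FVC%", "numeric", "functional"),
    FeatureMeta("FEV1%", "numeric", "functional"),
    FeatureMeta("DLCO", "numeric", "functional"),
    FeatureMeta("DLCO/VA", "numeric", "functional"),
    FeatureMeta("Macro%", "numeric", "bal_marker"),
    FeatureMeta("Neu%", "numeric", "bal_marker"),
    FeatureMeta("Lin%", "numeric", "bal_marker"),
    FeatureMeta("miR-21", "numeric", "mirna_biomarker"),
    FeatureMeta("miR-92a", "numeric", "mirna_biomarker"),
    FeatureMeta("KL-6", "numeric", "mirna_biomarker"),
    FeatureMeta("gender", "nominal", "covariate"),
    FeatureMeta("smoking", "nominal", "covariate"),
    FeatureMeta("diagnosis", "nominal", "target"),
    FeatureMeta("prognosis", "nominal", "target"),
)

NUMERIC_FEATURES: tuple[str, ...] = tuple(m.name for m in STUDY_SCHEMA if m.dtype == "numeric")
GENETIC_FEATURES: tuple[str, ...] = ("miR-21", "miR-92a", "KL-6")
TARGET_LEVELS: dict[str, tuple[str, str]] = {
    # (positive class, negative class)
    "diagnosis": ("PPF", "nPPF"),
    "prognosis": ("RAPID", "SLOW"),
}
NOMINAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": ("M", "F"),
    "smoking": ("smoker", "non-smoker"),
    "diagnosis": TARGET_LEVELS["diagnosis"],
    "prognosis": TARGET_LEVELS["prognosis"],
}


class SchemaError(ValueError):
    """Input file does not match the declared cohort schema."""


@dataclass
class FeatureStats:
    """Per-feature min/max/mean/std and missing counts.

    ``std`` is reported with the population convention (divisor n) to match
    the normalization contract; see :func:`compute_stats`.
    """

    table: pd.DataFrame  # index: feature; columns: min, max, mean, std, missing
    n_samples: int | None = None

    def __post_init__(self) -> None:
        required = {"min", "max", "mean", "std", "missing"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"stats table must have columns {sorted(required)}")
        t = self.table
        if (t["min"] > t["mean"] + 1e-12).any() or (t["mean"] > t["max"] + 1e-12).any():
            bad = t.index[(t["min"] > t["mean"] + 1e-12) | (t["mean"] > t["max"] + 1e-12)]
            raise ValueError(f"min <= mean <= max violated for {list(bad)}")
        if (t["std"] < 0).any():
            raise ValueError("negative std")
        if (t["missing"] < 0).any():
            raise ValueError("negative missing count")
        if self.n_samples is not None and (t["missing"] > self.n_samples).any():
            raise ValueError("missing count exceeds n_samples")

    @property
    def features(self) -> list[str]:
        return list(self.table.index)

    def total_missing(self) -> int:
        return int(self.table["missing"].sum())

    def to_csv(self, path) -> None:
        self.table.rename_axis("feature").to_csv(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.rename_axis("feature").reset_index().to_dict("records"), fh, indent=1)

    @classmethod
    def from_csv(cls, path, n_samples: int | None = None) -> "FeatureStats":
        return cls(pd.read_csv(path, index_col="feature"), n_samples=n_samples)


def table1_stats() -> FeatureStats:
    """Packaged descriptive statistics of the 39-patient study cohort.

    One row per numeric feature: min, max, mean, std (feature units) and the
    number of missing values (23 in total across the 11 features).
    """
    ref = importlib.resources.files("ppfbayes").joinpath("data/feature_stats.csv")
    with importlib.resources.as_file(ref) as path:
        return FeatureStats.from_csv(path, n_samples=39)


@dataclass
class CohortTable:
    """Samples x features with an explicit missing mask.

    ``data`` holds numeric columns as floats (NaN == missing) and nominal
    columns as strings (targets never missing).  ``metas`` maps column name to
    :class:`FeatureMeta`.  ``ground_truth`` optionally carries the simulation
    truth when the table came from the synthetic generator.
    """

    data: pd.DataFrame
    metas: dict[str, FeatureMeta]
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        names = list(self.metas)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        for name in self.data.columns:
            if name not in self.metas:
                raise ValueError(f"column {name!r} has no schema entry")
        for name, meta in self.metas.items():
            if name not in self.data.columns:
                raise ValueError(f"schema feature {name!r} missing from data")
            if meta.group == "target":
                col = self.data[name]
                if col.isna().any():
                    raise ValueError(f"target {name!r} has missing values")
                levels = set(col.unique())
                if len(levels) > 2:
                    raise ValueError(f"target {name!r} is not binary: {sorted(levels)}")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [n for n, m in self.metas.items() if m.group != "target"]

    @property
    def numeric_features(self) -> list[str]:
        return [n for n, m in self.metas.items() if m.dtype == "numeric"]

    @property
    def targets(self) -> list[str]:
        return [n for n, m in self.metas.items() if m.group == "target"]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame over numeric columns; True == value absent."""
        return self.data[self.numeric_features].isna()

    def target_values(self, target: str) -> pd.Series:
        if target not in self.targets:
            raise KeyError(f"unknown target {target!r}")
        return self.data[target]

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.metas), self.ground_truth)

    def with_data(self, data: pd.DataFrame) -> "CohortTable":
        return CohortTable(data, dict(self.metas), self.ground_truth)


def load_cohort(path, schema=STUDY_SCHEMA) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row, one patient per row).

    Missing numeric entries may be empty cells or "NA".  Unparseable numeric
    cells are treated as missing.  Target columns listed in the schema are
    optional; when present they must be binary with no missing entries.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    metas = {m.name: m for m in schema}

    present: dict[str, FeatureMeta] = {}
    cols = {}
    for meta in schema:
        if meta.name not in raw.columns:
            if meta.group == "target":
                continue  # targets optional
            raise SchemaError(f"required column {meta.name!r} absent from {path}")
        col = raw[meta.name].str.strip()
        if meta.dtype == "numeric":
            cols[meta.name] = pd.to_numeric(col.replace({"": None, "NA": None}), errors="coerce")
        else:
            col = col.replace({"": None, "NA": None})
            allowed = NOMINAL_LEVELS.get(meta.name)
            observed = set(col.dropna().unique())
            if allowed is not None and not observed.issubset(allowed):
                raise SchemaError(
                    f"column {meta.name!r} has unexpected levels {sorted(observed - set(allowed))}"
                )
            cols[meta.name] = col
        present[meta.name] = meta

    data = pd.DataFrame(cols, index=raw.index) if cols else pd.DataFrame()
    if not len(raw):
        data = pd.DataFrame({n: pd.Series(dtype=float if m.dtype == "numeric" else object)
                             for n, m in present.items()})
    return CohortTable(data, present)


def save_cohort(table: CohortTable, path) -> None:
    """Write the cohort CSV dialect read back by :func:`load_cohort`."""
    table.data.to_csv(path, index=False, na_rep="")


def compute_stats(table: CohortTable, ddof: int = 0) -> FeatureStats:
    """Descriptive statistics of the numeric features over non-missing cells."""
    rows = {}
    for name in table.numeric_features:
        col = table.data[name]
        vals = col.dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"feature {name!r} has no observed values")
        rows[name] = {
            "min": vals.min(),
            "max": vals.max(),
            "mean": vals.mean(),
            "std": vals.std(ddof=ddof) if vals.size > ddof else 0.0,
            "missing": int(col.isna().sum()),
        }
    return FeatureStats(pd.DataFrame.from_dict(rows, orient="index"), n_samples=table.n_samples)


def drop_incomplete(table: CohortTable, features: list[str]) -> CohortTable:
    """Complete-case filter: keep rows with no missing cell among ``features``.

    Row order is preserved and the input table is untouched.  With an empty
    feature list this is the identity.
    """
    for name in features:
        if name not in table.data.columns:
            raise KeyError(f"unknown feature {name!r}")
    if not features:
        return table.copy()
    keep = ~table.data[list(features)].isna().any(axis=1)
    return table.with_data(table.data.loc[keep].copy())


@dataclass(frozen=True)
class ZScoreTransform:
    """Stored (mean, std) per feature for forward/inverse standardization."""

    means: dict[str, float]
    stds: dict[str, float]
    ddof: int = 0

    @property
    def features(self) -> list[str]:
        return list(self.means)

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for name in self.means:
            out[name] = (out[name] - self.means[name]) / self.stds[name]
        return out

    def invert(self, data: pd.DataFrame) -> pd.DataFrame:
        out = data.copy()
        for name in self.means:
            out[name] = out[name] * self.stds[name] + self.means[name]
        return out

    def apply_table(self, table: CohortTable) -> CohortTable:
        return table.with_data(self.apply(table.data))

    def to_dict(self) -> dict:
        return {"means": dict(self.means), "stds": dict(self.stds), "ddof": self.ddof}


def zscore_normalize(
    table: CohortTable, features: list[str] | None = None, ddof: int = 0
) -> tuple[CohortTable, ZScoreTransform]:
    """Standardize the named numeric features to mean 0 and std 1.

    Statistics are taken over non-missing cells; missing cells stay missing.
    ``ddof=0`` (population std) is the default convention; ``ddof=1`` gives
    the sample-std variant.  A zero-variance feature raises, naming it.
    """
    if features is None:
        features = table.numeric_features
    means, stds = {}, {}
    for name in features:
        if name not in table.data.columns:
            raise KeyError(f"unknown feature {name!r}")
        vals = table.data[name].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"feature {name!r} has no observed values")
        std = float(vals.std(ddof=ddof))
        if std <= 0 or not np.isfinite(std):
            raise ValueError(f"feature {name!r} has zero variance; cannot z-score")
        means[name], stds[name] = float(vals.mean()), std
    transform = ZScoreTransform(means, stds, ddof=ddof)
    return transform.apply_table(table), transform


def iqr_fences(table: CohortTable) -> pd.DataFrame:
    """Boxplot-style summaries (quartiles and 1.5*IQR fences) for inspection.

    Flagging only — no values are removed or altered; outlier confirmation is
    left to domain experts.
    """
    rows = {}
    for name in table.numeric_features:
        vals = table.data[name].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        rows[name] = {
            "q1": q1, "median": q2, "q3": q3,
            "lower_fence": lo, "upper_fence": hi,
            "n_below": int((vals < lo).sum()), "n_above": int((vals > hi).sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
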