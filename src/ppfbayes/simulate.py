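"""Synthetic cohort generation.

Generates patient tables with the statistical structure the downstream
analysis assumes: truncated-normal marginals matching the study cohort's
published per-feature min/max/mean/std, the study's missingness pattern, and
binary targets planted through the same logistic mechanism the classifier
later fits.  This makes every pipeline stage testable — including parameter
recovery against a known ground truth — without the original patient data.

Marginals are independent truncated normals by default (no correlation
matrix is published); an optional Gaussian-copula mode accepts a
user-supplied correlation matrix for stress-testing the correlation-pruning
stage.  Truncated-normal sampling uses the inverse-CDF on the truncated
interval (exact and vectorized; no rejection loops).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    CohortTable,
    FeatureMeta,
    STUDY_SCHEMA,
    NUMERIC_FEATURES,
    TARGET_LEVELS,
    table1_stats,
    zscore_normalize,
)

__all__ = [
    "MarginalSpec",
    "SimConfig",
    "GroundTruth",
    "study_sim_config",
    "simulate_features",
    "assign_labels",
    "inject_missing",
    "make_study_like_cohort",
    "STUDY_DIAGNOSIS_TRUTH",
    "STUDY_PROGNOSIS_TRUTH",
]


@dataclass(frozen=True)
class MarginalSpec:
    """Truncated-normal marginal in feature units."""

    mean: float
    std: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise ValueError(f"infeasible truncation: upper {self.upper} < lower {self.lower}")
        if self.std <= 0:
            raise ValueError("std must be positive")

    def truncated_moments(self) -> tuple[float, float]:
        """(mean, std) of the truncated distribution, from scipy's closed form."""
        a = (self.lower - self.mean) / self.std
        b = (self.upper - self.mean) / self.std
        dist = stats.truncnorm(a, b, loc=self.mean, scale=self.std)
        return float(dist.mean()), float(dist.std())


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_samples: int
    marginals: dict[str, MarginalSpec]
    missing: dict[str, int] = field(default_factory=dict)
    p_male: float = 0.7
    p_smoker: float = 0.5
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0
    correlation: np.ndarray | None = None  # optional Gaussian-copula correlation

    def __post_init__(self) -> None:
        for name, count in self.missing.items():
            if not 0 <= count <= self.n_samples:
                raise ValueError(f"missing count for {name!r} outside [0, n_samples]")
        for target, counts in self.class_counts.items():
            if sum(counts.values()) != self.n_samples:
                raise ValueError(f"class counts for {target!r} do not sum to n_samples")

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "marginals": {k: asdict(v) for k, v in self.marginals.items()},
            "missing": dict(self.missing),
            "p_male": self.p_male,
            "p_smoker": self.p_smoker,
            "class_counts": {k: dict(v) for k, v in self.class_counts.items()},
            "seed": self.seed,
        }
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        corr = d.get("correlation")
        return cls(
            n_samples=int(d["n_samples"]),
            marginals={k: MarginalSpec(**v) for k, v in d["marginals"].items()},
            missing={k: int(v) for k, v in d.get("missing", {}).items()},
            p_male=float(d.get("p_male", 0.7)),
            p_smoker=float(d.get("p_smoker", 0.5)),
            class_counts={k: {kk: int(vv) for kk, vv in v.items()}
                          for k, v in d.get("class_counts", {}).items()},
            seed=int(d.get("seed", 0)),
            correlation=None if corr is None else np.asarray(corr, dtype=float),
        )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class GroundTruth:
    """Planted logistic mechanism for one binary target.

    Coefficients are on the z-score scale.  A key of the form ``"A × B"``
    refers to the product of the standardized parent features (matching the
    derived interaction columns of the augmentation stage), so interaction
    effects can be planted even before augmentation runs.
    """

    target: str
    intercept: float
    coefficients: dict[str, float]
    mechanism: str = "bernoulli_draw"  # or "fixed_count_threshold"
    positive_count: int | None = None  # required for fixed_count_threshold

    def __post_init__(self) -> None:
        if self.mechanism not in ("bernoulli_draw", "fixed_count_threshold"):
            raise ValueError(f"unknown label mechanism {self.mechanism!r}")
        if self.mechanism == "fixed_count_threshold" and self.positive_count is None:
            raise ValueError("fixed_count_threshold requires positive_count")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def study_sim_config(n_samples: int = 39, seed: int = 0) -> SimConfig:
    """Study-like configuration: published marginals, missingness and splits.

    Class balance is 19 positive / 20 negative for both targets (the
    diagnosis split is published; the prognosis classes are described as
    balanced).  The nominal covariates default to P(male)=0.7 and
    P(smoker)=0.5 — the study reports male predominance and no smoker/
    non-smoker difference without counts.
    """
    t1 = table1_stats().table
    marginals = {
        f: MarginalSpec(mean=row["mean"], std=row["std"], lower=row["min"], upper=row["max"])
        for f, row in t1.iterrows()
    }
    missing = {f: int(row["missing"]) for f, row in t1.iterrows()} if n_samples == 39 else {}
    pos_d, neg_d = TARGET_LEVELS["diagnosis"]
    pos_p, neg_p = TARGET_LEVELS["prognosis"]
    n_pos = round(n_samples * 19 / 39)
    return SimConfig(
        n_samples=n_samples,
        marginals=marginals,
        missing=missing,
        class_counts={
            "diagnosis": {pos_d: n_pos, neg_d: n_samples - n_pos},
            "prognosis": {pos_p: n_pos, neg_p: n_samples - n_pos},
        },
        seed=seed,
    )


# Default planted effects, signs matching the reported coefficient posteriors:
# for diagnosis, higher BAL lymphocytes and higher miR-21 lower the PPF
# probability while miR-21/miR-92a co-occurrence raises it; for prognosis,
# age and DLCO lower and KL-6 raises the RAPID probability.
STUDY_DIAGNOSIS_TRUTH = GroundTruth(
    target="diagnosis",
    intercept=0.0,
    coefficients={"Lin%": -1.0, "miR-21": -0.8, "miR-21 × miR-92a": 1.2},
    mechanism="fixed_count_threshold",
    positive_count=19,
)
STUDY_PROGNOSIS_TRUTH = GroundTruth(
    target="prognosis",
    intercept=0.0,
    coefficients={"Age": -1.0, "DLCO": -1.0, "KL-6": 1.0},
    mechanism="fixed_count_threshold",
    positive_count=19,
)


def _truncnorm_draw(spec: MarginalSpec, u: np.ndarray) -> np.ndarray:
    # inverse-CDF on the truncated interval: exact for any bounds
    a = (spec.lower - spec.mean) / spec.std
    b = (spec.upper - spec.mean) / spec.std
    return stats.truncnorm.ppf(u, a, b, loc=spec.mean, scale=spec.std)


def simulate_features(config: SimConfig) -> CohortTable:
    """Draw a complete (no-missing) cohort of numeric and nominal features.

    Numeric features are i.i.d. truncated normals per their marginal spec
    (or a Gaussian copula with those marginals when ``config.correlation``
    is given).  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = list(config.marginals)
    n, p = config.n_samples, len(names)

    if config.correlation is not None:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (p, p):
            raise ValueError(f"correlation must be {p}x{p}")
        z = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")
        u = stats.norm.cdf(z)
    else:
        u = rng.uniform(size=(n, p))
    # clip away exact 0/1 so the inverse CDF stays finite
    u = np.clip(u, 1e-12, 1 - 1e-12)

    cols: dict[str, object] = {}
    for j, name in enumerate(names):
        cols[name] = _truncnorm_draw(config.marginals[name], u[:, j])
    cols["gender"] = np.where(rng.uniform(size=n) < config.p_male, "M", "F")
    cols["smoking"] = np.where(rng.uniform(size=n) < config.p_smoker, "smoker", "non-smoker")

    metas = {m.name: m for m in STUDY_SCHEMA if m.name in cols}
    for name in names:  # features outside the study schema default to functional
        metas.setdefault(name, FeatureMeta(name, "numeric", "functional"))
    data = pd.DataFrame({k: cols[k] for k in metas})
    return CohortTable(data, metas)


def _design_matrix(table: CohortTable, coefficients: dict[str, float]) -> np.ndarray:
    """Z-score the referenced base features and build the planted design.

    Product keys ("A × B") are evaluated as products of the standardized
    parents.  Raises if any referenced cell is missing: label assignment
    requires complete predictors.
    """
    base: set[str] = set()
    for key in coefficients:
        parts = [p.strip() for p in key.split("×")] if "×" in key else [key]
        for part in parts:
            if part not in table.data.columns and key not in table.data.columns:
                raise KeyError(f"ground-truth feature {part!r} not in table")
        base.update(p for p in parts if p in table.data.columns)
    base.update(k for k in coefficients if k in table.data.columns)

    sub = table.data[sorted(base)]
    if sub.isna().any().any():
        bad = sorted(sub.columns[sub.isna().any()])
        raise ValueError(f"label assignment requires complete predictors; missing in {bad}")
    z = (sub - sub.mean()) / sub.std(ddof=0)

    cols = []
    for key in coefficients:
        if key in z.columns:
            cols.append(z[key].to_numpy())
        else:
            parts = [p.strip() for p in key.split("×")]
            prod = np.ones(len(z))
            for part in parts:
                prod = prod * z[part].to_numpy()
            cols.append(prod)
    return np.column_stack(cols) if cols else np.empty((len(z), 0))


def assign_labels(table: CohortTable, truth: GroundTruth, seed: int | None = None) -> CohortTable:
    """Attach a binary target drawn from the planted logistic mechanism.

    ``p_i = logistic(intercept + coefficients · z_i)``; labels are Bernoulli
    draws, or — for fixed class counts — the ``positive_count`` samples with
    the largest ``p_i`` (ties broken by row order).  The truth (including the
    realized probabilities) is stored on the returned table for recovery
    tests.
    """
    X = _design_matrix(table, truth.coefficients)
    eta = truth.intercept + X @ np.array(list(truth.coefficients.values()))
    prob = 1.0 / (1.0 + np.exp(-eta))

    pos, neg = TARGET_LEVELS.get(truth.target, ("pos", "neg"))
    if truth.mechanism == "bernoulli_draw":
        rng = np.random.default_rng(seed if seed is not None else 0)
        positive = rng.uniform(size=len(prob)) < prob
    else:
        k = int(truth.positive_count)
        if not 0 <= k <= len(prob):
            raise ValueError("positive_count outside [0, n_samples]")
        order = np.argsort(-prob, kind="stable")
        positive = np.zeros(len(prob), dtype=bool)
        positive[order[:k]] = True

    data = table.data.copy()
    data[truth.target] = np.where(positive, pos, neg)
    metas = dict(table.metas)
    metas[truth.target] = FeatureMeta(truth.target, "nominal", "target")
    gt = dict(table.ground_truth or {})
    gt[truth.target] = {"truth": truth, "probabilities": prob}
    return CohortTable(data, metas, ground_truth=gt)


def inject_missing(table: CohortTable, counts: dict[str, int], seed: int = 0) -> CohortTable:
    """Mask exactly ``counts[f]`` cells of each feature f, rows chosen
    uniformly without replacement.  Target columns are never masked."""
    rng = np.random.default_rng(seed)
    data = table.data.copy()
    for name, count in counts.items():
        if name not in data.columns:
            raise KeyError(f"unknown feature {name!r}")
        if table.metas[name].group == "target":
            raise ValueError(f"refusing to mask target {name!r}")
        if not 0 <= count <= len(data):
            raise ValueError(f"missing count {count} for {name!r} outside [0, {len(data)}]")
        if count:
            rows = rng.choice(len(data), size=count, replace=False)
            data.iloc[rows, data.columns.get_loc(name)] = np.nan
    return CohortTable(data, dict(table.metas), table.ground_truth)


def make_study_like_cohort(seed: int = 0, n_samples: int = 39) -> CohortTable:
    """One call producing the full study-like table: 39 rows, 19 PPF / 20
    nPPF, published marginals and missingness, default planted effects."""
    config = study_sim_config(n_samples=n_samples, seed=seed)
    table = simulate_features(config)

    n_pos = config.class_counts["diagnosis"][TARGET_LEVELS["diagnosis"][0]]
    diag = GroundTruth(**{**asdict(STUDY_DIAGNOSIS_TRUTH), "positive_count": n_pos})
    prog = GroundTruth(**{**asdict(STUDY_PROGNOSIS_TRUTH), "positive_count": n_pos})
    table = assign_labels(table, diag, seed=seed)
    table = assign_labels(table, prog, seed=seed + 1)
    if config.missing:
        table = inject_missing(table, config.missing, seed=seed + 2)
    return table
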