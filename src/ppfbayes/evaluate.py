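"""Posterior-uncertainty-aware evaluation.

Because the fitted classifier is a distribution over models, every
classification metric is itself a distribution: each posterior draw induces
hard labels (p > 0.5, strict) and hence one accuracy/sensitivity/
specificity value, and the metric is summarised by its mean and standard
deviation across draws.  Per-sample class-probability summaries (the
"confusion diagram" numbers: posterior mean, std, predicted label, and an
uncertainty flag when the mean +/- std band crosses the cutoff) and
coefficient posterior reports complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, drop_incomplete
from .model import PosteriorFit, predict_probability

__all__ = [
    "MetricSummary",
    "SampleProbability",
    "expected_classification_metrics",
    "sample_probability_summaries",
    "coefficient_report",
]


@dataclass
class MetricSummary:
    """Expected classification metrics with posterior stds."""

    accuracy_mean: float
    accuracy_std: float
    specificity_mean: float
    specificity_std: float
    sensitivity_mean: float
    sensitivity_std: float
    n: int
    positive_class: str

    def __post_init__(self) -> None:
        for name in ("accuracy", "specificity", "sensitivity"):
            m = getattr(self, f"{name}_mean")
            s = getattr(self, f"{name}_std")
            if not (0.0 <= m <= 1.0 and 0.0 <= s <= 1.0):
                raise ValueError(f"{name} summary outside [0, 1]: mean={m}, std={s}")

    def to_frame(self, model: str = "") -> pd.DataFrame:
        return pd.DataFrame([{
            "model": model,
            "accuracy_mean": self.accuracy_mean, "accuracy_std": self.accuracy_std,
            "specificity_mean": self.specificity_mean, "specificity_std": self.specificity_std,
            "sensitivity_mean": self.sensitivity_mean, "sensitivity_std": self.sensitivity_std,
            "n": self.n, "positive_class": self.positive_class,
        }])


@dataclass
class SampleProbability:
    """Per-sample posterior class-probability summary."""

    sample_id: object
    observed: str
    mean: float
    std: float
    predicted: str
    uncertain: bool  # mean +/- std band crosses the 0.5 cutoff


def expected_classification_metrics(
    fit: PosteriorFit,
    table: CohortTable,
    cutoff: float = 0.5,
    positive_class: str | None = None,
) -> MetricSummary:
    """Posterior-expected accuracy, sensitivity and specificity.

    Per draw s the labels are ``p_i^s > cutoff`` (strictly greater:
    probability exactly at the cutoff predicts the negative class);
    sensitivity is the true-positive rate of the positive class,
    specificity the true-negative rate.  The summary is mean/std across
    draws, so a degenerate posterior yields std 0.
    """
    positive_class = positive_class or fit.positive_class
    complete = drop_incomplete(table, fit.feature_names)
    y = (complete.target_values(fit.target) == positive_class).to_numpy()
    if y.all() or not y.any():
        raise ValueError("both observed classes are required to compute metrics")
    probs = predict_probability(fit, complete)
    yhat = probs.draws > cutoff  # S x n
    correct = yhat == y[None, :]
    accuracy = correct.mean(axis=1)
    sensitivity = correct[:, y].mean(axis=1)
    specificity = correct[:, ~y].mean(axis=1)
    return MetricSummary(
        accuracy_mean=float(accuracy.mean()), accuracy_std=float(accuracy.std()),
        specificity_mean=float(specificity.mean()), specificity_std=float(specificity.std()),
        sensitivity_mean=float(sensitivity.mean()), sensitivity_std=float(sensitivity.std()),
        n=int(y.size), positive_class=positive_class,
    )


def sample_probability_summaries(
    fit: PosteriorFit,
    table: CohortTable,
    positive_class: str | None = None,
    cutoff: float = 0.5,
) -> list[SampleProbability]:
    """Per-sample posterior mean/std of the positive-class probability.

    Output is ordered by observed class (positive first), then by sample
    order, matching confusion-diagram plotting.  A sample whose mean +/-
    std band crosses the cutoff is flagged uncertain: no decision should be
    made on it.
    """
    positive_class = positive_class or fit.positive_class
    complete = drop_incomplete(table, fit.feature_names)
    observed = complete.target_values(fit.target)
    probs = predict_probability(fit, complete)
    negative = [lvl for lvl in observed.unique() if lvl != positive_class]
    negative_class = negative[0] if negative else "other"

    out = []
    for idx, obs, mean, std in zip(probs.sample_index, observed, probs.mean, probs.std):
        out.append(SampleProbability(
            sample_id=idx,
            observed=obs,
            mean=float(mean),
            std=float(std),
            predicted=positive_class if mean > cutoff else negative_class,
            uncertain=bool(mean - std <= cutoff <= mean + std),
        ))
    out.sort(key=lambda s: (s.observed != positive_class, s.sample_id))
    return out


def coefficient_report(
    fit: PosteriorFit,
    near_zero: tuple[float, float] = (-0.05, 0.05),
) -> pd.DataFrame:
    """Posterior summary per parameter: mean, std, 5/50/95% quantiles,
    P(beta in near-zero interval) and P(beta > 0).

    The near-zero probability implements the relevance check: a feature
    whose coefficient has appreciable mass in the interval contributes
    ambiguously and is a removal candidate.  The intercept row is included
    but flagged — it is not part of the relevance assessment.
    """
    lo, hi = near_zero
    rows = []
    for j, name in enumerate(fit.param_names):
        d = fit.draws[:, j]
        q5, q50, q95 = np.percentile(d, [5, 50, 95])
        rows.append({
            "parameter": name,
            "is_intercept": name == "intercept",
            "mean": float(d.mean()),
            "std": float(d.std()),
            "q5": float(q5), "q50": float(q50), "q95": float(q95),
            "p_near_zero": float(((d >= lo) & (d <= hi)).mean()),
            "p_positive": float((d > 0).mean()),
        })
    return pd.DataFrame(rows)
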