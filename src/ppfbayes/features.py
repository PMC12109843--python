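"""Feature augmentation, ranking, pruning, exclusion and grouped selection.

The candidate-construction half of the workflow: pairwise products of the
standardized genetic biomarkers are added as interaction features, features
are ranked by random-forest Gini importance, highly correlated features are
pruned in rank order, known problem features are excluded (gender for label
leakage, DLCO/VA for excessive missingness), and the top-k survivors of each
clinical feature group become the candidate set for Bayesian screening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import CohortTable, FeatureMeta, drop_incomplete

__all__ = [
    "RankedFeatures",
    "augment_pairwise_products",
    "rank_random_forest",
    "prune_correlated",
    "apply_exclusions",
    "select_group_top_k",
    "DEFAULT_EXCLUSIONS",
]

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSIONS = ("gender", "DLCO/VA")
PRODUCT_SEP = " × "


@dataclass
class RankedFeatures:
    """Features ordered by non-increasing importance."""

    items: list[tuple[str, float]]
    provenance: str = "rf_gini"  # or "manual"

    def __post_init__(self) -> None:
        names = [n for n, _ in self.items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate names in ranking")
        scores = [s for _, s in self.items]
        if any(s < 0 for s in scores):
            raise ValueError("importance scores must be non-negative")
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking not sorted by non-increasing importance")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.items, columns=["feature", "importance"]).assign(
            rank=lambda d: np.arange(1, len(d) + 1), provenance=self.provenance
        )


def product_name(a: str, b: str) -> str:
    return f"{a}{PRODUCT_SEP}{b}"


def augment_pairwise_products(
    table: CohortTable, features: list[str], include_self: bool = True
) -> CohortTable:
    """Add elementwise-product interaction columns for each unordered pair.

    The inputs are expected to be z-scored so the product's sign is
    interpretable: positive when the two biomarkers are concordant (both
    high or both low), negative when discordant.  With ``include_self`` the
    squares are added too — three biomarkers then yield six derived columns.
    Missingness propagates: the product is missing if either factor is.
    """
    for name in features:
        if name not in table.data.columns:
            raise KeyError(f"unknown feature {name!r}")
    pairs = (
        combinations_with_replacement(features, 2) if include_self else combinations(features, 2)
    )
    data = table.data.copy()
    metas = dict(table.metas)
    for a, b in pairs:
        name = product_name(a, b)
        if name in data.columns:
            raise ValueError(f"augmented column {name!r} already exists")
        data[name] = data[a] * data[b]
        group_a, group_b = table.metas[a].group, table.metas[b].group
        group = "mirna_biomarker" if group_a == group_b == "mirna_biomarker" else "derived"
        metas[name] = FeatureMeta(name, "numeric", group)
    return CohortTable(data, metas, table.ground_truth)


def rank_random_forest(
    table: CohortTable,
    features: list[str],
    target: str,
    n_trees: int = 500,
    seed: int = 0,
) -> RankedFeatures:
    """Rank features by mean Gini impurity decrease in a random forest.

    Trained on the complete-case subset of the named features (no
    imputation).  Deterministic given ``seed``; exact importance ties keep
    the input order.
    """
    complete = drop_incomplete(table, list(features))
    if complete.n_samples < 10:
        raise ValueError(
            f"only {complete.n_samples} complete rows for {len(features)} features; "
            "ranking would be unstable (need >= 10)"
        )
    y = complete.target_values(target)
    if y.nunique() < 2:
        raise ValueError(f"target {target!r} has a single class on the complete rows")
    X = complete.data[list(features)].to_numpy(dtype=float)
    forest = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    forest.fit(X, y.to_numpy())
    importance = forest.feature_importances_
    order = np.argsort(-importance, kind="stable")  # stable: ties keep input order
    return RankedFeatures(
        [(features[i], float(importance[i])) for i in order], provenance="rf_gini"
    )


def prune_correlated(
    ranked: RankedFeatures,
    table: CohortTable,
    threshold: float = 0.5,
) -> tuple[RankedFeatures, pd.DataFrame]:
    """Drop lower-ranked features correlated with an already-retained one.

    Scans in rank order; a feature is dropped when its absolute Pearson
    correlation (pairwise-complete observations) with any retained feature
    is >= ``threshold``.  Returns the surviving ranking and a report of the
    dropped pairs (dropped, against, r).
    """
    retained: list[tuple[str, float]] = []
    dropped: list[dict] = []
    for name, score in ranked.items:
        if name not in table.data.columns:
            raise KeyError(f"ranked feature {name!r} not in table")
        col = table.data[name]
        reason = None
        for kept, _ in retained:
            other = table.data[kept]
            both = col.notna() & other.notna()
            if both.sum() < 3:
                raise ValueError(
                    f"fewer than 3 pairwise-complete observations between "
                    f"{name!r} and {kept!r}"
                )
            r = float(np.corrcoef(col[both], other[both])[0, 1])
            if abs(r) >= threshold:
                reason = {"dropped": name, "against": kept, "r": r}
                break
        if reason is None:
            retained.append((name, score))
        else:
            dropped.append(reason)
    report = pd.DataFrame(dropped, columns=["dropped", "against", "r"])
    return RankedFeatures(retained, ranked.provenance), report


def apply_exclusions(ranked: RankedFeatures, names: list[str]) -> RankedFeatures:
    """Remove the listed features wherever present; absent names only log."""
    present = set(ranked.names)
    for name in names:
        if name not in present:
            logger.warning("exclusion %r not present in ranking; ignored", name)
    excluded = set(names)
    return RankedFeatures(
        [(n, s) for n, s in ranked.items if n not in excluded], ranked.provenance
    )


def select_group_top_k(
    ranked: RankedFeatures, groups: dict[str, str], k: int = 2
) -> list[str]:
    """Keep the k highest-ranked surviving features of each feature group.

    Output is ordered by global rank.  A group with no surviving feature
    contributes fewer than k (with a warning).
    """
    for name in ranked.names:
        if name not in groups:
            raise KeyError(f"ranked feature {name!r} has no group assignment")
    taken: dict[str, int] = {}
    selected: list[str] = []
    for name, _ in ranked.items:
        g = groups[name]
        if taken.get(g, 0) < k:
            selected.append(name)
            taken[g] = taken.get(g, 0) + 1
    for g in set(groups[n] for n in ranked.names):
        if taken.get(g, 0) < k:
            logger.warning("group %r contributes only %d of %d features", g, taken.get(g, 0), k)
    return selected
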