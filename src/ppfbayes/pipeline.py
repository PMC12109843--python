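"""End-to-end orchestration: prepare -> augment -> rank -> prune/exclude ->
group-top-k -> screen -> wrapper-select -> fit best -> evaluate.

Every stage writes its export (CSV/JSON) into the output directory and the
run closes with a JSON manifest recording seeds, parameters and stage
results, sufficient to re-run the pipeline bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortTable,
    GENETIC_FEATURES,
    NUMERIC_FEATURES,
    compute_stats,
    load_cohort,
    zscore_normalize,
)
from .evaluate import (
    coefficient_report,
    expected_classification_metrics,
    sample_probability_summaries,
)
from .features import (
    DEFAULT_EXCLUSIONS,
    apply_exclusions,
    augment_pairwise_products,
    prune_correlated,
    rank_random_forest,
    select_group_top_k,
)
from .loo import screen_features, wrapper_select
from .model import PriorSpec, SamplerConfig, StudentPrior, fit_bernoulli_glm
from .simulate import make_study_like_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of one end-to-end run, with study-default settings."""

    input_csv: str | None = None  # None -> simulate a study-like cohort
    targets: tuple[str, ...] = ("diagnosis", "prognosis")
    seed: int = 0
    out_dir: str = "ppfbayes_out"
    # feature engineering
    genetic_features: tuple[str, ...] = GENETIC_FEATURES
    include_self_products: bool = True
    n_trees: int = 500
    correlation_threshold: float = 0.5
    exclusions: tuple[str, ...] = DEFAULT_EXCLUSIONS
    group_top_k: int = 2
    # screening / selection
    near_zero: tuple[float, float] = (-0.05, 0.05)
    p_drop: float = 0.10
    loo_method: str = "exact"
    stop_after: str | None = None  # "rank" | "screen" | "select" | "fit" | None (full run)
    # model
    prior_intercept_scale: float = 5.0
    prior_coef_scale: float = 2.5
    prior_df: float = 3.0
    algorithm: str = "ensemble"
    n_chains: int = 4
    n_draws: int = 1000
    n_warmup: int = 1000
    zscore_ddof: int = 0
    extra: dict = field(default_factory=dict)

    def priors(self) -> PriorSpec:
        return PriorSpec(
            intercept=StudentPrior(scale=self.prior_intercept_scale, df=self.prior_df),
            coefficient=StudentPrior(scale=self.prior_coef_scale, df=self.prior_df),
        )

    def sampler(self, seed_offset: int = 0) -> SamplerConfig:
        return SamplerConfig(
            n_chains=self.n_chains,
            n_draws=self.n_draws,
            n_warmup=self.n_warmup,
            seed=(self.seed + seed_offset) % (2**31),
            algorithm=self.algorithm,
        )

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "extra"}
        d["targets"] = list(self.targets)
        d["genetic_features"] = list(self.genetic_features)
        d["exclusions"] = list(self.exclusions)
        d["near_zero"] = list(self.near_zero)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("targets", "genetic_features", "exclusions", "near_zero"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)


def _prepare(config: PipelineConfig) -> tuple[CohortTable, CohortTable, object]:
    if config.input_csv is not None:
        cohort = load_cohort(config.input_csv)
    else:
        cohort = make_study_like_cohort(seed=config.seed)
    numeric = [f for f in NUMERIC_FEATURES if f in cohort.data.columns]
    normalized, transform = zscore_normalize(cohort, numeric, ddof=config.zscore_ddof)
    return cohort, normalized, transform


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow for each configured target.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    Any stage failure raises :class:`PipelineError` after writing a partial
    manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "targets": {},
    }

    def fail(stage: str, message: str):
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        return PipelineError(stage, message)

    try:
        cohort, normalized, transform = _prepare(config)
    except Exception as err:
        raise fail("prepare", str(err)) from err
    compute_stats(cohort).to_csv(out / "cohort_stats.csv")
    manifest["n_samples"] = cohort.n_samples

    try:
        augmented = augment_pairwise_products(
            normalized, list(config.genetic_features), include_self=config.include_self_products
        )
    except Exception as err:
        raise fail("augment", str(err)) from err
    derived = [c for c in augmented.data.columns if c not in normalized.data.columns]
    manifest["derived_features"] = derived

    candidate_pool = [
        n for n, m in augmented.metas.items()
        if m.dtype == "numeric" and m.group in ("functional", "bal_marker", "mirna_biomarker")
    ]
    groups = {n: augmented.metas[n].group for n in candidate_pool}

    priors = config.priors()
    for t_idx, target in enumerate(config.targets):
        if target not in augmented.targets:
            logger.warning("target %r absent from cohort; skipped", target)
            continue
        tinfo: dict = {}
        stage = "rank"
        try:
            ranked = rank_random_forest(
                augmented, candidate_pool, target,
                n_trees=config.n_trees, seed=config.seed + t_idx,
            )
            ranked.to_frame().to_csv(out / f"{target}_ranking.csv", index=False)
            pruned, prune_report = prune_correlated(
                ranked, augmented, threshold=config.correlation_threshold
            )
            prune_report.to_csv(out / f"{target}_pruned.csv", index=False)
            surviving = apply_exclusions(pruned, list(config.exclusions))
            candidates = select_group_top_k(surviving, groups, k=config.group_top_k)
            tinfo["candidates"] = candidates
            if not candidates:
                raise ValueError("no candidates after ranking/pruning/exclusion")
            if config.stop_after == "rank":
                manifest["targets"][target] = tinfo
                continue

            stage = "screen"
            report = screen_features(
                augmented, candidates, target, priors,
                config.sampler(1000 + t_idx), near_zero=config.near_zero,
                p_drop=config.p_drop,
            )
            report.to_frame().to_csv(out / f"{target}_screening.csv", index=False)
            tinfo["n_screening_models"] = len(report.models)
            tinfo["retained"] = report.retained
            retained_ranked = [f for f in candidates if f in report.retained]
            if not retained_ranked:
                raise ValueError("screening dropped every candidate")
            if config.stop_after == "screen":
                manifest["targets"][target] = tinfo
                continue

            stage = "select"
            result = wrapper_select(
                augmented, retained_ranked, target, priors,
                config.sampler(2000 + t_idx), loo_method=config.loo_method,
            )
            result.to_frame().to_csv(out / f"{target}_elpd.csv", index=False)
            tinfo["best_features"] = result.best_features
            tinfo["elpd_best"] = result.scores[result.best_index].elpd
            if config.stop_after == "select":
                manifest["targets"][target] = tinfo
                continue

            stage = "fit"
            fit = fit_bernoulli_glm(
                augmented, result.best_features, target, priors,
                config.sampler(3000 + t_idx), transform=transform,
            )
            fit.save(out / f"{target}_draws.csv", out / f"{target}_fit.json")
            tinfo["converged"] = bool(fit.converged)
            if config.stop_after == "fit":
                manifest["targets"][target] = tinfo
                continue

            stage = "evaluate"
            metrics = expected_classification_metrics(fit, augmented)
            metrics.to_frame(" + ".join(result.best_features)).to_csv(
                out / f"{target}_metrics.csv", index=False
            )
            tinfo["metrics"] = metrics.to_frame().iloc[0].drop("model").to_dict()
            samples = sample_probability_summaries(fit, augmented)
            pd.DataFrame([vars(s) for s in samples]).to_csv(
                out / f"{target}_sample_probabilities.csv", index=False
            )
            coefficient_report(fit, near_zero=config.near_zero).to_csv(
                out / f"{target}_coefficients.csv", index=False
            )
        except PipelineError:
            raise
        except Exception as err:
            raise fail(stage, f"target {target!r}: {err}") from err
        manifest["targets"][target] = tinfo

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
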