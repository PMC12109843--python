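"""Bayesian Bernoulli GLM: link, priors, sampling, prediction."""

import numpy as np
import pandas as pd
import pytest

from ppfbayes import (
    GroundTruth,
    PosteriorFit,
    PriorSpec,
    SamplerConfig,
    StudentPrior,
    assign_labels,
    fit_bernoulli_glm,
    logistic,
    predict_probability,
    simulate_features,
    study_sim_config,
    zscore_normalize,
)
from ppfbayes.cohort import CohortTable, FeatureMeta, NUMERIC_FEATURES


def _planted_cohort(n, coefficients, seed, intercept=0.0):
    table = simulate_features(study_sim_config(n_samples=n, seed=seed))
    truth = GroundTruth("diagnosis", intercept, coefficients)
    table = assign_labels(table, truth, seed=seed + 1)
    normalized, _ = zscore_normalize(table, list(NUMERIC_FEATURES))
    return normalized


def _manual_fit(feature_names, draws, target="diagnosis", positive="PPF"):
    return PosteriorFit(
        target=target,
        positive_class=positive,
        feature_names=feature_names,
        draws=np.asarray(draws, dtype=float),
        rhat=np.ones(1 + len(feature_names)),
        ess=np.full(1 + len(feature_names), 1e4),
        converged=True,
        n_obs=0,
        priors=PriorSpec(),
        sampler=SamplerConfig(seed=0, algorithm="laplace"),
    )


class TestLogistic:
    def test_symmetry_limits_and_closed_form(self):
        assert logistic(0.0) == 0.5
        assert logistic(800.0) == 1.0 and logistic(-800.0) == 0.0
        assert logistic(np.log(3.0)) == pytest.approx(0.75, abs=1e-12)
        eta = np.linspace(-5, 5, 101)
        assert (np.diff(logistic(eta)) > 0).all()

    def test_positive_coefficient_raises_probability(self):
        # the adopted sign convention: higher feature value with positive
        # coefficient means higher positive-class probability
        fit = _manual_fit(["x"], [[0.0, 2.0]] * 1000)
        table = CohortTable(
            pd.DataFrame({"x": [-1.0, 0.0, 1.0]}),
            {"x": FeatureMeta("x", "numeric", "functional")},
        )
        probs = predict_probability(fit, table)
        assert probs.mean[0] < probs.mean[1] < probs.mean[2]


class TestPriorSpec:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            StudentPrior(scale=0.0)
        with pytest.raises(ValueError):
            StudentPrior(df=-1.0)

    def test_per_feature_override(self):
        spec = PriorSpec(per_feature={"x": StudentPrior(scale=0.1)})
        loc, scale, df = spec.arrays(["x", "y"])
        assert scale[1] == pytest.approx(0.1)
        assert scale[2] == pytest.approx(2.5)


class TestFit:
    def test_intercept_only_balanced_labels(self, mcmc_sampler):
        data = pd.DataFrame({
            "x": np.r_[np.zeros(40)] + np.linspace(-1, 1, 40),
            "diagnosis": ["PPF"] * 20 + ["nPPF"] * 20,
        })
        metas = {
            "x": FeatureMeta("x", "numeric", "functional"),
            "diagnosis": FeatureMeta("diagnosis", "nominal", "target"),
        }
        table = CohortTable(data, metas)
        fit = fit_bernoulli_glm(table, [], "diagnosis", sampler=mcmc_sampler)
        p = logistic(fit.intercept_draws).mean()
        assert 0.4 < p < 0.6

    @pytest.mark.parametrize("algorithm", ["mcmc", "laplace", "ensemble"])
    def test_planted_coefficients_recovered(self, algorithm):
        normalized = _planted_cohort(400, {"Lin%": 1.5, "KL-6": -1.0}, seed=3)
        sampler = SamplerConfig(seed=5, algorithm=algorithm, n_warmup=500)
        fit = fit_bernoulli_glm(normalized, ["Lin%", "KL-6"], "diagnosis", sampler=sampler)
        means = fit.draws.mean(axis=0)
        assert means[1] == pytest.approx(1.5, abs=0.25)
        assert means[2] == pytest.approx(-1.0, abs=0.25)
        lo, hi = np.percentile(fit.coef_draws("Lin%"), [5, 95])
        assert lo < 1.5 < hi

    def test_null_coefficient_mass_near_zero(self, mcmc_sampler):
        # averaged over replicates, a truly null coefficient places far more
        # than the 5% retention floor inside [-0.05, 0.05]
        p_near = []
        for seed in range(8):
            normalized = _planted_cohort(400, {"Lin%": 1.0, "Age": 0.0}, seed=200 + seed)
            fit = fit_bernoulli_glm(
                normalized, ["Lin%", "Age"], "diagnosis", sampler=mcmc_sampler
            )
            d = fit.coef_draws("Age")
            p_near.append(((d >= -0.05) & (d <= 0.05)).mean())
        assert np.mean(p_near) > 0.15

    def test_single_class_target_rejected(self):
        data = pd.DataFrame({"x": [0.1, 0.2, -0.1, 0.4], "diagnosis": ["PPF"] * 4})
        table = CohortTable(data, {
            "x": FeatureMeta("x", "numeric", "functional"),
            "diagnosis": FeatureMeta("diagnosis", "nominal", "target"),
        })
        with pytest.raises(ValueError, match="single class"):
            fit_bernoulli_glm(table, ["x"], "diagnosis")

    def test_wide_priors_match_irls_oracle(self):
        import statsmodels.api as sm

        normalized = _planted_cohort(300, {"Lin%": 0.8, "DLCO": -0.6}, seed=17)
        wide = PriorSpec(
            intercept=StudentPrior(scale=500.0), coefficient=StudentPrior(scale=500.0)
        )
        fit = fit_bernoulli_glm(
            normalized, ["Lin%", "DLCO"], "diagnosis", priors=wide,
            sampler=SamplerConfig(seed=1, algorithm="laplace"),
        )
        y = (normalized.data["diagnosis"] == "PPF").astype(float)
        X = sm.add_constant(normalized.data[["Lin%", "DLCO"]].to_numpy())
        ml = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.map_estimate, ml.params, atol=0.05)

    def test_posterior_contraction_with_sample_size(self):
        # doubling n should not increase average posterior coefficient std
        violations = 0
        for seed in range(10):
            stds = []
            for n in (200, 400):
                normalized = _planted_cohort(n, {"Lin%": 1.0}, seed=100 * seed + n)
                fit = fit_bernoulli_glm(
                    normalized, ["Lin%"], "diagnosis",
                    sampler=SamplerConfig(seed=seed, algorithm="laplace"),
                )
                stds.append(fit.coef_draws("Lin%").std())
            violations += stds[1] > stds[0]
        assert violations <= 1

    def test_credible_interval_calibration(self):
        # 90% intervals should cover the truth in most replicates
        covered = 0
        n_rep = 50
        for seed in range(n_rep):
            normalized = _planted_cohort(200, {"Lin%": 1.0}, seed=1000 + seed)
            fit = fit_bernoulli_glm(
                normalized, ["Lin%"], "diagnosis",
                sampler=SamplerConfig(seed=seed, algorithm="laplace"),
            )
            lo, hi = np.percentile(fit.coef_draws("Lin%"), [5, 95])
            covered += lo <= 1.0 <= hi
        assert covered >= 0.8 * n_rep


class TestPredict:
    def test_degenerate_posterior_at_zero_gives_half(self):
        fit = _manual_fit(["x"], np.zeros((100, 2)))
        table = CohortTable(
            pd.DataFrame({"x": [0.0, 1.3, -2.1]}),
            {"x": FeatureMeta("x", "numeric", "functional")},
        )
        probs = predict_probability(fit, table)
        assert (probs.draws == 0.5).all()
        assert ((probs.draws > 0) & (probs.draws < 1)).all()

    def test_monotone_in_feature_under_positive_draws(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([rng.standard_normal(500), rng.uniform(0.5, 2.0, 500)])
        fit = _manual_fit(["x"], draws)
        table = CohortTable(
            pd.DataFrame({"x": np.linspace(-2, 2, 9)}),
            {"x": FeatureMeta("x", "numeric", "functional")},
        )
        probs = predict_probability(fit, table)
        assert (np.diff(probs.draws, axis=1) >= 0).all()

    def test_missing_predictor_cells_error_lists_samples(self):
        fit = _manual_fit(["x"], np.zeros((10, 2)))
        table = CohortTable(
            pd.DataFrame({"x": [0.5, np.nan, 1.0]}),
            {"x": FeatureMeta("x", "numeric", "functional")},
        )
        with pytest.raises(ValueError, match="\\[1\\]"):
            predict_probability(fit, table)

    def test_raw_data_goes_through_stored_transform(self):
        from ppfbayes.cohort import ZScoreTransform

        tr = ZScoreTransform({"x": 10.0}, {"x": 2.0})
        fit = _manual_fit(["x"], np.tile([0.0, 1.0], (100, 1)))
        fit.transform = tr
        table = CohortTable(
            pd.DataFrame({"x": [10.0, 12.0]}),
            {"x": FeatureMeta("x", "numeric", "functional")},
        )
        probs = predict_probability(fit, table, raw=True)
        assert probs.mean[0] == pytest.approx(0.5)
        assert probs.mean[1] == pytest.approx(logistic(1.0))
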