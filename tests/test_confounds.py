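"""Box-Cox transform, mixed-effects confound model, quality gating, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metricselect.confounds import (
    BoxCoxTransform,
    ConfoundModel,
    DegenerateMetricError,
    abnormality_cutoff,
    fit_boxcox,
    fit_random_intercept_ml,
    model_quality,
    normalization_params,
    normalize,
    step1_filter,
    ModelQuality,
)
from metricselect.data import MetricDescriptor, aggregate_trials
from metricselect.simulate import CohortConfig, MetricSpec, gen_cohort


def _desc(direction="higher_is_worse"):
    return MetricDescriptor("m", "speed", "transport", direction)


class TestBoxCox:
    def test_transform_of_one_is_zero_for_any_lambda(self):
        for lam in (-2.0, -0.5, 0.0, 0.7, 2.0):
            assert BoxCoxTransform(lam).transform([1.0])[0] == pytest.approx(0.0)

    def test_lambda_zero_limit_is_natural_log(self):
        t = BoxCoxTransform(0.0)
        assert t.transform([np.e])[0] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.one_of(st.just(0.0), st.floats(-2.5, -1e-3), st.floats(1e-3, 2.5)),
        st.lists(st.floats(0.01, 1e3), min_size=1, max_size=50),
    )
    def test_round_trip(self, lam, values):
        t = BoxCoxTransform(lam, scale=3.7)
        y = np.asarray(values)
        if lam < 0 and np.any(lam * t.transform(y) / t.scale + 1 <= 0):
            return  # outside invertible branch
        back = t.inverse(t.transform(y))
        np.testing.assert_allclose(back, y, rtol=1e-9)

    def test_lognormal_data_recovers_lambda_near_zero(self, rng):
        y = np.exp(rng.normal(size=500))
        t = fit_boxcox(y)
        assert -0.3 <= t.lmbda <= 0.3

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            fit_boxcox(np.ones(20))

    def test_nonpositive_values_shifted(self, rng):
        y = rng.normal(size=100) - 5.0
        t = fit_boxcox(y)
        assert t.shift > 0
        np.testing.assert_allclose(t.inverse(t.transform(y)), y, rtol=1e-9,
                                   atol=1e-9)


class TestRandomInterceptML:
    def test_matches_statsmodels_mixedlm(self, rng):
        import statsmodels.api as sm

        n_subj = 60
        g = np.repeat(np.arange(n_subj), 2)
        X = np.column_stack([np.ones(2 * n_subj), rng.normal(size=2 * n_subj)])
        y = X @ [1.0, 0.5] + rng.normal(scale=0.7, size=n_subj)[g] \
            + rng.normal(scale=0.9, size=2 * n_subj)
        mine = fit_random_intercept_ml(y, X, g)
        ref = sm.MixedLM(y, X, groups=g).fit(reml=False)
        np.testing.assert_allclose(mine.beta, np.asarray(ref.params)[:2],
                                   rtol=1e-6, atol=1e-8)
        assert mine.llf == pytest.approx(ref.llf, abs=1e-6)
        assert mine.tau2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]),
                                          abs=1e-4)

    def test_singleton_groups_fall_back_to_ols(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [1.0, 2.0] + rng.normal(size=30)
        fit = fit_random_intercept_ml(y, X, np.arange(30))
        assert fit.no_random_effect
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, ols, rtol=1e-8)


class TestConfoundModel:
    def _fit(self, seed=0, betas=(0.05, 0, 0, 0, 0), link=1.0):
        cfg = CohortConfig(
            seed=seed, n_affected={}, n_retest=0, include_noise_metric=False,
            metrics=[MetricSpec("m", betas=betas, link_lambda=link,
                                intercept=10.0)],
            n_repetitions=2, n_pegs=3,
        )
        subjects, obs, _ = gen_cohort(cfg)
        table = aggregate_trials(obs)
        return ConfoundModel.from_table(table, subjects, "m")

    def test_planted_age_effect_recovered(self):
        model = self._fit()
        fit = model.fit()
        assert fit.betas[1] == pytest.approx(0.05, abs=2.5 * fit.bse[1])

    def test_single_side_data_flags_no_random_effect(self, rng):
        idx = pd.MultiIndex.from_tuples(
            [(f"s{i}", "left", "test") for i in range(40)],
            names=["subject_id", "side", "session"],
        )
        values = pd.Series(rng.normal(10, 1, size=40), index=idx)
        cov = pd.DataFrame(
            rng.integers(0, 2, size=(40, 5)).astype(float), index=idx,
            columns=["age", "sex", "tested_side", "handedness",
                     "stereo_deficit"],
        )
        cov["age"] = rng.uniform(20, 80, size=40)
        fit = ConfoundModel(values, cov, "m").fit()
        assert "no_random_effect" in fit.flags

    def test_constant_covariate_dropped_with_flag(self, rng):
        idx = pd.MultiIndex.from_tuples(
            [(f"s{i}", s, "test") for i in range(30) for s in ("left", "right")],
            names=["subject_id", "side", "session"],
        )
        cov = pd.DataFrame(0.0, index=idx,
                           columns=["age", "sex", "tested_side",
                                    "handedness", "stereo_deficit"])
        cov["age"] = rng.uniform(20, 80, size=len(idx))
        cov["tested_side"] = [1.0 if k[1] == "right" else 0.0 for k in idx]
        values = pd.Series(10 + 0.02 * cov["age"] + rng.normal(0, 0.5,
                                                               len(idx)),
                           index=idx)
        fit = ConfoundModel(values, cov, "m").fit()
        assert "dropped_covariate:sex" in fit.flags
        assert fit.betas[2] == 0.0

    def test_bootstrap_lrt_deterministic_under_seed(self):
        model = self._fit()
        model.fit()
        p1 = model.bootstrap_lrt("age", iterations=30, seed=5)
        p2 = model.bootstrap_lrt("age", iterations=30, seed=5)
        assert p1 == p2

    def test_bootstrap_lrt_detects_planted_effect(self):
        model = self._fit(betas=(0.0, 0.0, 0.0, 0.0, 2.0))
        model.fit()
        p = model.bootstrap_lrt("stereo_deficit", iterations=99, seed=3)
        assert p <= 0.01

    def test_bootstrap_lrt_rejects_zero_iterations(self):
        model = self._fit()
        model.fit()
        with pytest.raises(ValueError):
            model.bootstrap_lrt("age", iterations=0)

    def test_remove_confounds_subtracts_only_covariate_terms(self):
        model = self._fit()
        fit = model.fit()
        z = fit.boxcox.transform([12.0])[0]
        zero_cov = fit.remove_confounds([12.0], np.zeros(5))
        assert zero_cov[0] == pytest.approx(z)  # intercept untouched
        once = fit.remove_confounds([12.0], np.r_[50.0, np.zeros(4)])[0]
        assert once == pytest.approx(z - 50.0 * fit.betas[1])

    def test_planted_age_effect_removed_in_groups(self):
        model = self._fit(seed=4)
        fit = model.fit()
        vals = model.values
        ages = model.covariates["age"]
        corrected = fit.remove_confounds(
            vals.to_numpy(), model.covariates.to_numpy(float)
        )
        old = corrected[(ages >= ages.median()).to_numpy()]
        young = corrected[(ages < ages.median()).to_numpy()]
        pooled_sd = np.std(corrected, ddof=1)
        assert abs(old.mean() - young.mean()) < 0.25 * pooled_sd


class TestModelQuality:
    def test_perfect_predictions(self, rng):
        y = rng.normal(10, 2, size=50)
        q = model_quality(y, y)
        assert (q.mae, q.c1, q.c2) == (0.0, 0.0, 0.0) and q.passed

    def test_c_criteria_arithmetic(self):
        # MAE 2, sigma 2, range 20 -> C1 = 10, C2 = (2 + 6)/20*100 = 40
        q = ModelQuality(mae=2.0, sigma=2.0, c1=10.0, c2=40.0, passed=False)
        assert q.c2 == pytest.approx(100 * (q.mae + 3 * q.sigma) / 20.0)

    def test_boundary_pass(self):
        # MAE 3, sigma 0, range 20 -> C1 = 15 (boundary), C2 = 15 -> pass
        keep, reason = step1_filter(
            ModelQuality(3.0, 0.0, 15.0, 15.0, True), stereo_p=0.5)
        assert keep and reason is None

    def test_zero_range_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            model_quality(np.ones(30), np.ones(30))

    def test_step1_filter_reasons(self):
        bad_quality = ModelQuality(4.0, 1.0, 16.0, 24.0, False)
        keep, reason = step1_filter(bad_quality, stereo_p=0.5)
        assert not keep and "C1" in reason
        keep, reason = step1_filter(
            ModelQuality(1.0, 1.0, 5.0, 20.0, True), stereo_p=0.03)
        assert not keep and "stereo" in reason
        keep, _ = step1_filter(
            ModelQuality(2.0, 1.0, 10.0, 20.0, True), stereo_p=0.2)
        assert keep


class TestNormalization:
    def test_mad_example_by_hand(self):
        # intact {1,2,3,4,100}: median 3, MAD 1; value 5 -> yhat = 2
        params = normalization_params([1, 2, 3, 4, 100], _desc(), [5.0, 8.0])
        assert params.intact_median == 3.0 and params.mad == 1.0
        yhat_5 = (5.0 - 3.0) / 1.0
        assert normalize([5.0], params)[0] == pytest.approx(
            100.0 * yhat_5 / params.worst_scale)

    def test_worst_affected_scores_100(self, rng):
        intact = rng.normal(size=100)
        affected = rng.normal(loc=2.0, size=50)
        params = normalization_params(intact, _desc(), affected)
        assert normalize(affected, params).max() == pytest.approx(100.0)

    def test_intact_median_maps_to_zero(self, rng):
        intact = rng.normal(size=101)
        params = normalization_params(intact, _desc(), intact + 3.0)
        assert normalize([params.intact_median], params)[0] == pytest.approx(0.0)

    def test_normalized_intact_median0_mad1_before_worst_scaling(self, rng):
        intact = rng.normal(size=201)
        params = normalization_params(intact, _desc(), intact + 2.0)
        yhat = normalize(intact, params) * params.worst_scale / 100.0
        assert np.median(yhat) == pytest.approx(0.0, abs=1e-12)
        assert np.median(np.abs(yhat - np.median(yhat))) == pytest.approx(1.0)

    def test_lower_is_worse_flips_sign(self, rng):
        intact = rng.normal(size=100)
        affected = intact - 2.0  # lower values, i.e. worse here
        params = normalization_params(intact, _desc("lower_is_worse"), affected)
        assert np.median(normalize(affected, params)) > 0

    def test_zero_mad_degenerate(self):
        with pytest.raises(DegenerateMetricError):
            normalization_params(np.ones(30), _desc(), np.ones(3) + 1)


class TestAbnormalityCutoff:
    def test_at_most_5pct_above(self):
        v = np.arange(1.0, 101.0)
        cut = abnormality_cutoff(v)
        assert np.mean(v > cut) <= 0.05

    def test_constant_vector(self):
        assert abnormality_cutoff(np.full(25, 7.0)) == 7.0

    def test_standard_normal_quantile(self, rng):
        cut = abnormality_cutoff(rng.standard_normal(10_000))
        assert 1.55 <= cut <= 1.75
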