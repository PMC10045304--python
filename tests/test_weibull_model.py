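"""Censored Weibull AFT regression: likelihood, fit, residuals, influence."""

import numpy as np
import pandas as pd
import pytest

import survcompare as sc
from survcompare.weibull import censored_loglik, build_design_matrix, encode_pattern
from conftest import FINAL_MODEL, FINAL_SIGMA, make_cohort


@pytest.fixture(scope="module")
def two_cov_cohort():
    """Simulated cohort from the AFT model with two binary covariates."""
    config = sc.SimulationConfig(
        n=500,
        coefficients={"intercept": 1.6, "a[yes]": -0.3, "b[yes]": 0.5},
        sigma=0.25,
        covariate_spec={
            "a": sc.CategoricalCovariate(("no", "yes"), (0.5, 0.5)),
            "b": sc.CategoricalCovariate(("no", "yes"), (0.5, 0.5)),
        },
        censoring=0.25,
        seed=11,
    )
    return sc.simulate_cohort(config)


class TestDesignMatrix:
    def test_numeric_plus_binary_gives_three_columns(self, rng):
        schema = sc.CovariateSchema({"age": "numeric", "grp": ("x", "y")})
        data = sc.CohortDataset(
            [1, 2, 3], [1, 1, 0],
            pd.DataFrame({"age": [1.0, 2.0, 3.0], "grp": ["x", "y", "x"]}), schema,
        )
        design = sc.build_design_matrix(data)
        assert design.column_names == ["intercept", "age", "grp[y]"]
        np.testing.assert_array_equal(design.matrix[:, 0], 1.0)

    def test_cardiac_schema_gives_seven_columns(self):
        schema = sc.CovariateSchema(
            {
                "age": "numeric",
                "protocol": ("conventional", "fast-track"),
                "race": ("white", "black", "asian"),
                "sex": ("female", "male"),
                "patient": ("congenital", "coronary"),
            }
        )
        frame = pd.DataFrame(
            {
                "age": [30.0],
                "protocol": ["fast-track"],
                "race": ["black"],
                "sex": ["male"],
                "patient": ["coronary"],
            }
        )
        data = sc.CohortDataset([5.0], [1], frame, schema)
        design = sc.build_design_matrix(data)
        assert design.n_columns == 7  # intercept + age + 1 + 2 + 1 + 1

    def test_intercept_only(self):
        data = make_cohort([1, 2], [1, 1])
        design = sc.build_design_matrix(data, covariates=[])
        assert design.column_names == ["intercept"]

    def test_unseen_level_rejected(self, cardiac_schema, final_model_fit):
        with pytest.raises(sc.CohortError, match="exotic"):
            sc.predict_time(final_model_fit, {"protocol": "exotic", "patient": "coronary"})


class TestCensoredLoglik:
    def test_single_death_at_its_location_contributes_minus_one(self):
        data = make_cohort([np.e], [1])
        design = sc.build_design_matrix(data, covariates=[])
        # mu = log(t) = 1, sigma = 1 => z = 0 => -log(sigma) + z - e^z = -1
        assert censored_loglik(np.array([1.0]), 0.0, design, data.times, data.events) == pytest.approx(-1.0)

    def test_censored_record_contributes_negative_survival_term(self):
        data = make_cohort([2.0], [0])
        design = sc.build_design_matrix(data, covariates=[])
        value = censored_loglik(np.array([0.5]), 0.2, design, data.times, data.events)
        z = (np.log(2.0) - 0.5) / np.exp(0.2)
        assert value == pytest.approx(-np.exp(z))
        assert value <= 0

    def test_two_records_sum_of_closed_forms(self):
        data = make_cohort([1.5, 4.0], [1, 0])
        design = sc.build_design_matrix(data, covariates=[])
        beta, tau = np.array([0.3]), -0.2
        sigma = np.exp(tau)
        z1 = (np.log(1.5) - 0.3) / sigma
        z2 = (np.log(4.0) - 0.3) / sigma
        expected = (-tau + z1 - np.exp(z1)) + (-np.exp(z2))
        assert censored_loglik(beta, tau, design, data.times, data.events) == pytest.approx(expected)


class TestFit:
    def test_censored_exponential_closed_form(self, rng):
        times = rng.exponential(3.0, size=80)
        events = (rng.random(80) < 0.7).astype(int)
        events[0] = 1
        data = make_cohort(times, events)
        fit = sc.fit_weibull_aft(data, covariates=[], fix_scale=1.0)
        closed = np.log(times.sum() / events.sum())
        assert fit.beta["intercept"] == pytest.approx(closed, abs=1e-6)
        # the maximized likelihood matches the closed-form optimum
        design = sc.build_design_matrix(data, covariates=[])
        assert fit.loglik == pytest.approx(
            censored_loglik(np.array([closed]), 0.0, design, times, events), abs=1e-6
        )

    def test_degenerate_equal_times_flags_boundary(self):
        data = make_cohort([3.0] * 25, [1] * 25)
        fit = sc.fit_weibull_aft(data, covariates=[])
        assert fit.boundary
        assert fit.beta["intercept"] == pytest.approx(np.log(3.0), abs=1e-3)

    def test_recovers_simulated_coefficients(self, two_cov_cohort):
        fit = sc.fit_weibull_aft(two_cov_cohort)
        truth = {"intercept": 1.6, "a[yes]": -0.3, "b[yes]": 0.5}
        for name, value in truth.items():
            assert abs(fit.beta[name] - value) < 3 * fit.standard_errors[name]
        assert fit.sigma == pytest.approx(0.25, abs=0.05)

    def test_matches_lifelines_weibull_aft(self, two_cov_cohort):
        lifelines = pytest.importorskip("lifelines")
        fit = sc.fit_weibull_aft(two_cov_cohort)
        frame = two_cov_cohort.to_frame()
        frame["a"] = (frame["a"] == "yes").astype(float)
        frame["b"] = (frame["b"] == "yes").astype(float)
        ll = lifelines.WeibullAFTFitter().fit(frame, "time", "event")
        theirs = ll.params_["lambda_"]
        assert fit.beta["intercept"] == pytest.approx(theirs["Intercept"], abs=1e-4)
        assert fit.beta["a[yes]"] == pytest.approx(theirs["a"], abs=1e-4)
        assert fit.beta["b[yes]"] == pytest.approx(theirs["b"], abs=1e-4)
        # lifelines stores log(rho); rho = 1/sigma
        assert fit.sigma == pytest.approx(np.exp(-ll.params_["rho_"]["Intercept"]), abs=1e-4)
        # lifelines' log-likelihood is on the time scale; ours is on log-time.
        # They differ by the Jacobian sum(delta * log t), constant in theta.
        jacobian = float(np.sum(two_cov_cohort.events * np.log(two_cov_cohort.times)))
        assert fit.loglik - jacobian == pytest.approx(ll.log_likelihood_, abs=1e-4)

    def test_loglik_is_local_optimum(self, two_cov_cohort, rng):
        fit = sc.fit_weibull_aft(two_cov_cohort)
        design = build_design_matrix(two_cov_cohort)
        theta = np.concatenate([fit.beta.to_numpy(), [fit.tau]])
        for _ in range(100):
            perturbed = theta + rng.normal(scale=0.05, size=theta.size)
            ll = censored_loglik(
                perturbed[:-1], perturbed[-1], design,
                two_cov_cohort.times, two_cov_cohort.events,
            )
            assert ll <= fit.loglik + 1e-9

    def test_collinear_design_rejected(self):
        schema = sc.CovariateSchema({"a": ("n", "y"), "b": ("n", "y")})
        frame = pd.DataFrame({"a": ["n", "y"] * 10, "b": ["n", "y"] * 10})
        data = sc.CohortDataset(np.arange(1, 21), [1] * 20, frame, schema)
        with pytest.raises(sc.CohortError, match="rank deficient"):
            sc.fit_weibull_aft(data)


class TestLikelihoodRatio:
    def test_identical_models_give_zero(self, two_cov_cohort):
        fit = sc.fit_weibull_aft(two_cov_cohort)
        result = sc.likelihood_ratio_test(fit, fit)
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_null_noise_covariate_statistic_mean_near_one(self):
        # Under H0 the LR statistic is ~ chi-square(1): mean about 1
        stats = []
        for rep in range(200):
            config = sc.SimulationConfig(
                n=120,
                coefficients={"intercept": 1.5, "g[b]": 0.4},
                sigma=0.3,
                covariate_spec={
                    "g": sc.CategoricalCovariate(("a", "b"), (0.5, 0.5)),
                    "noise": sc.NumericCovariate("uniform", 0.0, 1.0),
                },
                censoring=0.2,
                seed=1000 + rep,
            )
            data = sc.simulate_cohort(config)
            full = sc.fit_weibull_aft(data)
            nested = sc.fit_weibull_aft(data, covariates=["g"])
            stats.append(sc.likelihood_ratio_test(full, nested).statistic)
        assert np.mean(stats) == pytest.approx(1.0, abs=0.35)

    def test_exponential_rejected_when_shape_is_large(self):
        # data simulated with gamma = 4.5 (sigma = 1/4.5): Weibull beats exponential
        rejections = 0
        for rep in range(40):
            config = sc.SimulationConfig(
                n=145,
                coefficients={"intercept": 1.6},
                sigma=1 / 4.5,
                censoring=0.25,
                seed=2000 + rep,
            )
            data = sc.simulate_cohort(config)
            weibull = sc.fit_weibull_aft(data, covariates=[])
            exponential = sc.fit_weibull_aft(data, covariates=[], fix_scale=1.0)
            if sc.likelihood_ratio_test(weibull, exponential).p_value < 0.05:
                rejections += 1
        assert rejections >= 38  # >= 95% power


class TestPredictionAndEffects:
    def test_reference_pattern_prediction(self, final_model_fit):
        value = sc.predict_time(final_model_fit, {"protocol": "conventional", "patient": "congenital"})
        assert value == pytest.approx(4.92, abs=0.01)

    def test_coronary_fast_track_prediction(self, final_model_fit):
        value = sc.predict_time(final_model_fit, {"protocol": "fast-track", "patient": "coronary"})
        assert value == pytest.approx(6.63, abs=0.01)

    def test_coronary_conventional_prediction(self, final_model_fit):
        value = sc.predict_time(final_model_fit, {"protocol": "conventional", "patient": "coronary"})
        assert value == pytest.approx(8.57, abs=0.01)

    def test_median_time_ratio_values(self, final_model_fit):
        assert sc.median_time_ratio(final_model_fit, "protocol[fast-track]") == pytest.approx(0.774, abs=5e-4)
        assert sc.median_time_ratio(final_model_fit, "patient[coronary]") == pytest.approx(1.74, abs=5e-3)
        zero_fit = sc.WeibullAFTFit.from_parameters(
            {"intercept": 1.0}, 0.5, final_model_fit.design.schema, covariates=()
        )
        assert sc.median_time_ratio(zero_fit, "intercept") == pytest.approx(np.e)

    def test_quantile_ratio_matches_exp_beta_for_any_quantile(self, final_model_fit):
        for q in (0.1, 0.5, 0.9):
            ref = sc.predict_time(
                final_model_fit, {"protocol": "conventional", "patient": "congenital"}, quantile=q
            )
            fast = sc.predict_time(
                final_model_fit, {"protocol": "fast-track", "patient": "congenital"}, quantile=q
            )
            assert fast / ref == pytest.approx(
                sc.median_time_ratio(final_model_fit, "protocol[fast-track]")
            )

    def test_unknown_coefficient_rejected(self, final_model_fit):
        with pytest.raises(sc.CohortError, match="unknown coefficient"):
            sc.median_time_ratio(final_model_fit, "nope")


class TestResiduals:
    @pytest.fixture()
    def influential_records(self, cardiac_schema):
        return sc.CohortDataset(
            [6.67, 9.92, 14.17],
            [0, 1, 1],
            pd.DataFrame(
                {
                    "protocol": ["conventional", "fast-track", "conventional"],
                    "patient": ["congenital", "coronary", "coronary"],
                }
            ),
            cardiac_schema,
        )

    def test_published_residual_values(self, final_model_fit, influential_records):
        res = sc.residuals(final_model_fit, influential_records)
        np.testing.assert_allclose(res.martingale, [-4.93, -5.08, -8.57], atol=0.05)
        np.testing.assert_allclose(res.deviance, [-3.14, -2.56, -3.55], atol=0.05)

    def test_death_at_predicted_time_has_zero_residuals(self, final_model_fit, cardiac_schema):
        t = sc.predict_time(final_model_fit, {"protocol": "conventional", "patient": "congenital"})
        data = sc.CohortDataset(
            [t], [1],
            pd.DataFrame({"protocol": ["conventional"], "patient": ["congenital"]}),
            cardiac_schema,
        )
        res = sc.residuals(final_model_fit, data)
        assert res.cox_snell[0] == pytest.approx(1.0)
        assert res.martingale[0] == pytest.approx(0.0, abs=1e-12)
        assert res.deviance[0] == pytest.approx(0.0, abs=1e-6)

    def test_residual_identities(self, final_model_fit, influential_records):
        res = sc.residuals(final_model_fit, influential_records)
        delta = influential_records.events.astype(float)
        np.testing.assert_allclose(res.martingale, delta - res.cox_snell, rtol=0, atol=0)
        log_term = np.where(delta == 1, np.log(delta - res.martingale), 0.0)
        np.testing.assert_allclose(
            res.deviance**2, -2 * (res.martingale + delta * log_term), atol=1e-12
        )
        assert np.all(np.sign(res.deviance) == np.sign(res.martingale))
        assert np.all(res.martingale <= 1.0)
        assert np.all(res.martingale[delta == 0] <= -1.0)

    def test_gof_curve_tracks_exponential_for_true_residuals(self, rng):
        draws = rng.exponential(1.0, size=500)
        res = sc.ResidualSet(draws, 1 - draws, np.zeros(500), np.ones(500, dtype=np.int8))
        curve = sc.cox_snell_gof(res)
        assert curve.max_discrepancy() < 0.08

    def test_gof_degenerate_inputs(self):
        single = sc.ResidualSet(np.array([0.7]), np.array([0.3]), np.array([0.8]),
                                np.array([1], dtype=np.int8))
        curve = sc.cox_snell_gof(single)
        assert curve.km.times.tolist() == [0.7]
        censored = sc.ResidualSet(np.array([1.2, 2.0]), np.array([-1.2, -2.0]),
                                  np.array([-1.0, -1.5]), np.array([0, 0], dtype=np.int8))
        assert sc.cox_snell_gof(censored).km.times.size == 0


class TestCaseDeletion:
    def test_empty_deletion_reproduces_full_fit(self, two_cov_cohort):
        fit = sc.fit_weibull_aft(two_cov_cohort)
        table = sc.case_deletion_refit(two_cov_cohort, [[]])
        for name in fit.parameter_names:
            est = fit.beta[name] if name in fit.beta.index else fit.tau
            assert table.iloc[0][name] == pytest.approx(est)
        assert not table.iloc[0]["significance_changed"]

    def test_dropping_gross_outlier_reduces_bias(self):
        config = sc.SimulationConfig(
            n=150,
            coefficients={"intercept": 1.6, "g[b]": -0.4},
            sigma=0.2,
            covariate_spec={"g": sc.CategoricalCovariate(("a", "b"), (0.5, 0.5))},
            censoring=0.0,
            seed=77,
        )
        data = sc.simulate_cohort(config)
        # corrupt one group-b record by a factor of 10
        victim = int(np.flatnonzero(data.covariates["g"] == "b")[0])
        times = data.times.copy()
        times[victim] *= 10
        corrupted = sc.CohortDataset(times, data.events, data.covariates, data.schema)
        table = sc.case_deletion_refit(corrupted, [[], [victim]])
        bias_with = abs(table.iloc[0]["g[b]"] - (-0.4))
        bias_without = abs(table.iloc[1]["g[b]"] - (-0.4))
        assert bias_without < bias_with

    def test_deletion_breaking_preconditions_is_named(self, cardiac_schema):
        data = sc.CohortDataset(
            [1.0, 2.0, 3.0], [1, 0, 0],
            pd.DataFrame(
                {
                    "protocol": ["conventional", "fast-track", "conventional"],
                    "patient": ["congenital", "coronary", "coronary"],
                }
            ),
            cardiac_schema,
        )
        with pytest.raises(sc.CohortError, match=r"\{#0\}"):
            sc.case_deletion_refit(data, [[0]], covariates=[])
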