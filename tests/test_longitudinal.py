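"""Mixed-model fitting, Wald/LR tests and the change-in-estimate screen."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import small_config
from lipidecay.cohort import generate_cohort
from lipidecay.longitudinal import (
    DesignSpec,
    ModelFit,
    fit_random_intercept,
    lr_test,
    period_effect_test,
    screen_confounders,
    wald_test,
)


def _one_way_layout(m=30, k=5, sigma_b=0.7, sigma_e=0.4, seed=42, center=False):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, sigma_b, m) if sigma_b > 0 else np.zeros(m)
    e = rng.normal(0, sigma_e, (m, k))
    if center:  # remove all between-patient variation -> boundary fit
        y = 2.0 + (e - e.mean(axis=1, keepdims=True)).ravel()
    else:
        y = 2.0 + np.repeat(b, k) + e.ravel()
    pid = np.repeat([f"P{i}" for i in range(m)], k)
    samples = pd.DataFrame(
        {
            "patient_id": pid,
            "tc_obs": y,
            "storage_time": np.tile(np.arange(k, dtype=float), m),
            # a second regressor, not collinear with storage or the intercept
            "followup_time": np.tile((np.arange(k, dtype=float)[::-1]) ** 2, m),
            "sample_date": 2000.0,
            "subcohort": 1,
        }
    )
    patients = pd.DataFrame({"patient_id": [f"P{i}" for i in range(m)]})
    return patients, samples, y.reshape(m, k)


def _make_fit(coefs: dict, ses: dict) -> ModelFit:
    names = list(coefs)
    cov = pd.DataFrame(np.diag([ses[n] ** 2 for n in names]), index=names,
                       columns=names)
    return ModelFit(
        response="tc",
        coefficients=pd.Series(coefs),
        standard_errors=pd.Series(ses),
        cov_fixed=cov,
        var_random_intercept=0.1,
        var_residual=0.1,
        log_likelihood=0.0,
        n_obs=10,
        n_patients=5,
        fitting_method="REML",
        term_columns={n: [n] for n in names},
    )


class TestVarianceComponents:
    def test_balanced_reml_matches_anova_closed_form(self):
        """Balanced one-way layout: REML variance components equal the
        MSB/MSW moment estimators exactly."""
        patients, samples, ymat = _one_way_layout()
        m, k = ymat.shape
        fit = fit_random_intercept(
            patients, samples, DesignSpec("tc", ("intercept",)), "REML"
        )
        ybar_i = ymat.mean(axis=1)
        msb = k * ((ybar_i - ymat.mean()) ** 2).sum() / (m - 1)
        msw = ((ymat - ybar_i[:, None]) ** 2).sum() / (m * (k - 1))
        assert fit.var_residual == pytest.approx(msw, abs=1e-8)
        assert fit.var_random_intercept == pytest.approx((msb - msw) / k, abs=1e-8)
        assert fit.n_obs == m * k and fit.n_patients == m

    def test_zero_between_variance_degenerates_to_ols(self):
        """With no between-patient variation the model collapses to OLS."""
        patients, samples, _ = _one_way_layout(center=True)
        spec = DesignSpec("tc", ("intercept", "storage_time"))
        fit = fit_random_intercept(patients, samples, spec, "REML")
        X = np.column_stack([np.ones(len(samples)), samples["storage_time"]])
        beta_ols = np.linalg.lstsq(X, samples["tc_obs"], rcond=None)[0]
        assert fit.var_random_intercept == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(fit.coefficients.to_numpy(), beta_ols, atol=1e-8)

    def test_ml_and_reml_agree_on_balanced_fixed_effects(self):
        patients, samples, _ = _one_way_layout()
        spec = DesignSpec("tc", ("intercept", "storage_time"))
        f_ml = fit_random_intercept(patients, samples, spec, "ML")
        f_reml = fit_random_intercept(patients, samples, spec, "REML")
        assert np.allclose(
            f_ml.coefficients.to_numpy(), f_reml.coefficients.to_numpy(), atol=1e-6
        )
        assert f_ml.var_random_intercept >= 0 and f_reml.var_random_intercept >= 0

    def test_beta_equals_gls_at_fitted_variance_components(self, default_cohort):
        """At the fitted (sb^2, se^2) the coefficients equal the closed-form
        GLS solution under the compound-symmetric block covariance."""
        from lipidecay.longitudinal import _merged, build_design
        from lipidecay.pipeline import TC_DECAY_SPEC

        patients, samples = default_cohort
        fit = fit_random_intercept(patients, samples, TC_DECAY_SPEC, "REML")
        data = _merged(patients, samples)
        y, X, _ = build_design(data, TC_DECAY_SPEC)
        groups = data.loc[y.index, "patient_id"]
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        for _, idx in y.groupby(groups).groups.items():
            Xi = X.loc[idx].to_numpy()
            yi = y.loc[idx].to_numpy()
            Vi = fit.var_residual * np.eye(len(yi)) + fit.var_random_intercept
            Wi = np.linalg.inv(Vi)
            XtVX += Xi.T @ Wi @ Xi
            XtVy += Xi.T @ Wi @ yi
        beta = np.linalg.solve(XtVX, XtVy)
        assert np.max(np.abs(beta - fit.coefficients.to_numpy())) < 1e-8


class TestDesignSpec:
    def test_quadratic_requires_linear_term(self):
        with pytest.raises(ValueError, match="followup_time"):
            DesignSpec("tc", ("intercept", "followup_time_sq"))

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="subcohort_x_followup"):
            DesignSpec("tc", ("intercept", "followup_time", "subcohort_x_followup"))

    def test_intercept_required(self):
        with pytest.raises(ValueError, match="intercept"):
            DesignSpec("tc", ("storage_time",))

    def test_rank_deficient_design_names_collinear_terms(self, default_cohort):
        patients, samples = default_cohort
        samples = samples.copy()
        samples["storage_time"] = 2.0 * samples["followup_time"]  # exact collinearity
        spec = DesignSpec("tc", ("intercept", "storage_time", "followup_time"))
        with pytest.raises(ValueError, match="collinear"):
            fit_random_intercept(patients, samples, spec)


class TestWaldAndLRT:
    def test_zero_estimate_gives_zero_statistic(self):
        fit = _make_fit({"intercept": 1.0, "x": 0.0}, {"intercept": 0.1, "x": 0.2})
        res = wald_test(fit, ["x"])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_single_term_equals_z_squared(self, default_cohort):
        from lipidecay.pipeline import TC_DECAY_SPEC

        patients, samples = default_cohort
        fit = fit_random_intercept(patients, samples, TC_DECAY_SPEC)
        res = wald_test(fit, ["storage_time"])
        z2 = (
            fit.coefficients["storage_time"] / fit.standard_errors["storage_time"]
        ) ** 2
        assert res.statistic == pytest.approx(z2, abs=1e-10)
        assert res.df == 1

    def test_empty_term_set_rejected(self):
        fit = _make_fit({"intercept": 1.0}, {"intercept": 0.1})
        with pytest.raises(ValueError):
            wald_test(fit, [])

    def test_lrt_identical_models_is_null(self):
        patients, samples, _ = _one_way_layout()
        spec = DesignSpec("tc", ("intercept", "storage_time"))
        fit = fit_random_intercept(patients, samples, spec, "ML")
        res = lr_test(fit, fit)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_lrt_nested_nonnegative_and_agrees_with_wald(self):
        """1-df LRT and Wald p-values agree closely at moderate n."""
        patients, samples, _ = _one_way_layout(m=200, k=5, seed=7)
        full = DesignSpec("tc", ("intercept", "storage_time"))
        red = DesignSpec("tc", ("intercept",))
        f_full = fit_random_intercept(patients, samples, full, "ML")
        f_red = fit_random_intercept(patients, samples, red, "ML")
        res = lr_test(f_full, f_red)
        assert res.statistic >= 0.0 and res.df == 1
        wald = wald_test(f_full, ["storage_time"])
        assert abs(res.p_value - wald.p_value) < 0.01

    def test_lrt_refuses_reml_fits(self):
        patients, samples, _ = _one_way_layout()
        spec = DesignSpec("tc", ("intercept", "storage_time"))
        f1 = fit_random_intercept(patients, samples, spec, "REML")
        f2 = fit_random_intercept(
            patients, samples, DesignSpec("tc", ("intercept",)), "REML"
        )
        with pytest.raises(ValueError, match="REML"):
            lr_test(f1, f2)

    def test_lrt_requires_nesting(self):
        patients, samples, _ = _one_way_layout()
        f1 = fit_random_intercept(
            patients, samples, DesignSpec("tc", ("intercept", "storage_time")), "ML"
        )
        f2 = fit_random_intercept(
            patients, samples, DesignSpec("tc", ("intercept", "followup_time")), "ML"
        )
        with pytest.raises(ValueError, match="subset"):
            lr_test(f1, f2)


class TestConfounderScreen:
    BASE = DesignSpec(
        "tc", ("intercept", "storage_time", "followup_time", "followup_time_sq")
    )

    def test_planted_confounder_is_selected(self):
        """Statin use is generated with a large TC effect and a strong
        calendar trend (hence storage-time correlation): a textbook
        confounder of the decay estimate."""
        cfg = small_config(seed=21, n_patients_per_subcohort=40)
        cfg.beta_tc["statin"] = 2.5
        cfg.covariate_params = dict(cfg.covariate_params, statin_p=(0.0, 0.3, 0.8))
        patients, samples = generate_cohort(cfg)
        selected = screen_confounders(
            patients, samples, self.BASE, ["statin"], monitored=["storage_time"]
        )
        assert selected == ["statin"]

    def test_pure_noise_candidate_not_selected(self):
        cfg = small_config(seed=22, n_patients_per_subcohort=60)
        patients, samples = generate_cohort(cfg)
        rng = np.random.default_rng(99)
        patients = patients.copy()
        patients["das28"] = rng.normal(5.0, 1.2, len(patients))  # independent noise
        selected, details = screen_confounders(
            patients,
            samples,
            self.BASE,
            ["das28"],
            monitored=["storage_time"],
            return_details=True,
        )
        assert selected == []
        assert details["das28"] < 0.10

    def test_screen_is_deterministic(self, default_cohort):
        patients, samples = default_cohort
        cands = ["age", "statin", "smoker"]
        r1 = screen_confounders(patients, samples, self.BASE, cands,
                                return_details=True)
        r2 = screen_confounders(patients, samples, self.BASE, cands,
                                return_details=True)
        assert r1[0] == r2[0]
        assert r1[1] == r2[1]

    def test_candidate_overlapping_base_rejected(self, default_cohort):
        patients, samples = default_cohort
        with pytest.raises(ValueError, match="storage_time"):
            screen_confounders(patients, samples, self.BASE, ["storage_time"])


class TestPeriodEffect:
    def test_single_subcohort_errors(self):
        cfg = small_config(seed=3)
        patients, samples = generate_cohort(cfg)
        one = patients["subcohort"] == 1
        with pytest.raises(ValueError, match="two subcohorts"):
            period_effect_test(
                patients[one], samples[samples["subcohort"] == 1], "tc"
            )

    def test_subcohort_with_single_followup_named(self):
        cfg = small_config(seed=4)
        patients, samples = generate_cohort(cfg)
        keep = (samples["subcohort"] != 3) | (samples["followup_time"] == 0.0)
        with pytest.raises(ValueError, match="subcohort 3"):
            period_effect_test(patients, samples[keep], "tc")

    def test_planted_period_effect_detected(self):
        """A strong extra follow-up slope in one subcohort is detected."""
        cfg = small_config(seed=31, n_patients_per_subcohort=40)
        patients, samples = generate_cohort(cfg)
        samples = samples.copy()
        bump = (samples["subcohort"] == 3) * 0.25 * samples["followup_time"]
        samples["tc_obs"] = samples["tc_obs"] + bump
        test, _ = period_effect_test(patients, samples, "tc")
        assert test.p_value < 0.01
        assert test.df == 2  # three subcohorts -> two interaction columns


def test_storage_coefficient_recovery_single_seed(default_cohort, default_config):
    """Single-cohort sanity bound: the fitted TC storage slope is negative
    and within 3 SE of the generator's truth."""
    from lipidecay.pipeline import TC_DECAY_SPEC

    patients, samples = default_cohort
    fit = fit_random_intercept(patients, samples, TC_DECAY_SPEC, "ML")
    est = fit.coefficients["storage_time"]
    se = fit.standard_errors["storage_time"]
    assert est < 0
    assert abs(est - (-default_config.true_decay_tc)) < 3 * se
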