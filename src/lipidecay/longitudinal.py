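"""Random-intercept longitudinal models for lipid decay and period effects.

The working model is

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sb^2),  e_ij ~ N(0, se^2)

for lipid level y of patient i at occasion j.  Storage time is the primary
regressor in the decay analysis; the period analysis replaces it with
subcohort indicators and subcohort x follow-up interactions.  Fitting is by
ML or REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`.

Confounders are screened by the change-in-estimate rule: a candidate is a
confounder when adding it moves a monitored coefficient by more than 10 %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "DesignSpec",
    "ModelFit",
    "TestResult",
    "fit_random_intercept",
    "wald_test",
    "lr_test",
    "screen_confounders",
    "period_effect_test",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = {"tc": "tc_obs", "hdl": "hdl_obs", "ldl": "ldl_obs"}

#: simple terms that map one-to-one onto a data column
_COVARIATE_TERMS = (
    "age",
    "female",
    "bmi",
    "smoker",
    "statin",
    "glucocorticoid",
    "das28",
    "rf_positive",
    "sbp",
)


@dataclass
class DesignSpec:
    """Fixed-effect design for one lipid response.

    ``fixed_terms`` is an ordered list of term names; compound terms
    ``subcohort`` and ``subcohort_x_followup`` expand to indicator columns
    (subcohort 1 is the reference level).
    """

    response: str = "tc"
    fixed_terms: tuple[str, ...] = ("intercept", "storage_time")
    grouping: str = "patient_id"

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_COLUMNS:
            raise ValueError(f"unknown response {self.response!r}")
        terms = list(self.fixed_terms)
        if "intercept" not in terms:
            raise ValueError("design must contain an intercept")
        if "followup_time_sq" in terms and "followup_time" not in terms:
            raise ValueError("followup_time_sq requires followup_time")
        if "subcohort_x_followup" in terms and not (
            "subcohort" in terms and "followup_time" in terms
        ):
            raise ValueError(
                "subcohort_x_followup requires both subcohort and followup_time"
            )

    def with_terms(self, *extra: str) -> "DesignSpec":
        return DesignSpec(
            self.response, tuple(self.fixed_terms) + tuple(extra), self.grouping
        )


@dataclass
class ModelFit:
    """A fitted random-intercept model.

    Coefficients and SEs are keyed by design-matrix column name; compound
    terms own several columns (``term_columns``).  Variance components are on
    the response scale squared (mmol^2/L^2).
    """

    response: str
    coefficients: pd.Series
    standard_errors: pd.Series
    cov_fixed: pd.DataFrame
    var_random_intercept: float
    var_residual: float
    log_likelihood: float
    n_obs: int
    n_patients: int
    fitting_method: str
    term_columns: dict[str, list[str]] = field(default_factory=dict)
    converged: bool = True

    def columns_for(self, terms) -> list[str]:
        cols: list[str] = []
        for t in terms:
            if t in self.term_columns:
                cols.extend(self.term_columns[t])
            elif t in self.coefficients.index:
                cols.append(t)
            else:
                raise KeyError(f"term {t!r} not in fitted model")
        return cols

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        lo = self.coefficients - z * self.standard_errors
        hi = self.coefficients + z * self.standard_errors
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def coefficient_table(self) -> pd.DataFrame:
        """Estimate / SE / 95% CI / Wald p per fixed-effect column."""
        z = self.coefficients / self.standard_errors
        p = 2 * stats.norm.sf(np.abs(z))
        out = pd.DataFrame(
            {
                "term": self.coefficients.index,
                "estimate": self.coefficients.to_numpy(),
                "se": self.standard_errors.to_numpy(),
            }
        )
        ci = self.conf_int()
        out["ci_low"] = ci["ci_low"].to_numpy()
        out["ci_high"] = ci["ci_high"].to_numpy()
        out["p_value"] = p
        return out


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    kind: str  # "Wald" or "LRT"


def _merged(patients: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    pat_cols = [c for c in patients.columns if c not in samples.columns
                or c == "patient_id"]
    return samples.merge(patients[pat_cols], on="patient_id", how="left",
                         validate="many_to_one")


def build_design(
    data: pd.DataFrame, spec: DesignSpec
) -> tuple[pd.Series, pd.DataFrame, dict[str, list[str]]]:
    """Response vector, design matrix and term->columns map for ``spec``."""
    ycol = RESPONSE_COLUMNS[spec.response]
    if ycol == "ldl_obs" and "ldl_obs" not in data.columns:
        from .decay import friedewald_ldl

        data = data.copy()
        data["ldl_obs"] = friedewald_ldl(
            data["tc_obs"].to_numpy(),
            data["hdl_obs"].to_numpy(),
            data["tg_obs"].to_numpy(),
            strict=False,
        )
    if ycol not in data.columns:
        raise KeyError(f"response column {ycol!r} missing from data")

    cols: dict[str, np.ndarray] = {}
    term_columns: dict[str, list[str]] = {}
    sc_levels = sorted(data["subcohort"].unique()) if "subcohort" in data else []
    for term in spec.fixed_terms:
        if term == "intercept":
            cols["intercept"] = np.ones(len(data))
            term_columns["intercept"] = ["intercept"]
        elif term in ("storage_time", "followup_time"):
            cols[term] = data[term].to_numpy(float)
            term_columns[term] = [term]
        elif term == "followup_time_sq":
            cols[term] = data["followup_time"].to_numpy(float) ** 2
            term_columns[term] = [term]
        elif term == "subcohort":
            names = []
            for lev in sc_levels[1:]:
                name = f"subcohort_{lev}"
                cols[name] = (data["subcohort"] == lev).to_numpy(float)
                names.append(name)
            term_columns["subcohort"] = names
        elif term == "subcohort_x_followup":
            names = []
            fu = data["followup_time"].to_numpy(float)
            for lev in sc_levels[1:]:
                name = f"subcohort_{lev}_x_followup"
                cols[name] = (data["subcohort"] == lev).to_numpy(float) * fu
                names.append(name)
            term_columns["subcohort_x_followup"] = names
        elif term in _COVARIATE_TERMS:
            cols[term] = data[term].to_numpy(float)
            term_columns[term] = [term]
        else:
            raise KeyError(f"unknown design term {term!r}")
    X = pd.DataFrame(cols, index=data.index)
    y = data[ycol].astype(float)
    ok = y.notna() & np.isfinite(X).all(axis=1)
    return y[ok], X[ok], term_columns


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # pivoted QR localises the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(arr, pivoting=True, mode="economic")
        bad = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"design matrix rank-deficient; collinear terms: {bad}")


def fit_random_intercept(
    patients: pd.DataFrame,
    samples: pd.DataFrame,
    spec: DesignSpec,
    method: str = "REML",
) -> ModelFit:
    """Fit the random-intercept model for ``spec`` by ML or REML.

    Standard errors are model-based (inverse expected information at the
    optimum).  Deterministic given the input data.
    """
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    data = _merged(patients, samples)
    if data[spec.grouping].nunique() < 2:
        raise ValueError("need at least two patients to fit a random intercept")
    y, X, term_columns = build_design(data, spec)
    groups = data.loc[y.index, spec.grouping]
    _check_rank(X)

    model = MixedLM(y, X, groups=groups)
    reml = method == "REML"
    with warnings.catch_warnings():
        # boundary (sb^2 -> 0) fits are legitimate; silence the chatter
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        except np.linalg.LinAlgError:
            # gradient methods can fail at the sb^2 = 0 boundary
            res = model.fit(reml=reml, method="powell", xtol=1e-12, ftol=1e-14)
        try:
            # polish the variance components to near machine precision
            polished = model.fit(
                reml=reml, method="bfgs", gtol=1e-12, start_params=res.params_object
            )
            if (
                polished.converged
                and np.isfinite(polished.llf)
                and polished.llf >= res.llf - 1e-8
            ):
                res = polished
        except (np.linalg.LinAlgError, ValueError):
            pass
    if not res.converged:
        raise RuntimeError(
            f"mixed-model fit did not converge (last loglike {res.llf:.6g})"
        )
    k = X.shape[1]
    cov_fe = pd.DataFrame(
        np.asarray(res.cov_params())[:k, :k], index=X.columns, columns=X.columns
    )
    return ModelFit(
        response=spec.response,
        coefficients=res.fe_params.copy(),
        standard_errors=res.bse_fe.copy(),
        cov_fixed=cov_fe,
        var_random_intercept=float(np.asarray(res.cov_re)[0, 0]),
        var_residual=float(res.scale),
        log_likelihood=float(res.llf),
        n_obs=int(len(y)),
        n_patients=int(groups.nunique()),
        fitting_method=method,
        term_columns=term_columns,
        converged=bool(res.converged),
    )


def wald_test(fit: ModelFit, terms) -> TestResult:
    """Joint Wald chi-square test that the named coefficients are all zero."""
    terms = list(terms)
    if not terms:
        raise ValueError("empty term set")
    cols = fit.columns_for(terms)
    b = fit.coefficients[cols].to_numpy()
    V = fit.cov_fixed.loc[cols, cols].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    stat = max(stat, 0.0)
    df = len(cols)
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)), "Wald")


def lr_test(fit_full: ModelFit, fit_reduced: ModelFit) -> TestResult:
    """Likelihood-ratio test of nested fixed-effect structures (ML fits)."""
    if fit_full.fitting_method != "ML" or fit_reduced.fitting_method != "ML":
        raise ValueError(
            "likelihood-ratio tests of fixed effects require ML fits "
            "(REML likelihoods are not comparable across fixed-effect sets)"
        )
    full_cols = set(fit_full.coefficients.index)
    red_cols = set(fit_reduced.coefficients.index)
    if not red_cols <= full_cols:
        raise ValueError("reduced-model terms are not a subset of the full model")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits use different observation sets")
    stat = max(0.0, 2.0 * (fit_full.log_likelihood - fit_reduced.log_likelihood))
    df = len(full_cols) - len(red_cols)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return TestResult(stat, df, p, "LRT")


def screen_confounders(
    patients: pd.DataFrame,
    samples: pd.DataFrame,
    spec: DesignSpec,
    candidates,
    threshold: float = 0.10,
    monitored=None,
    method: str = "REML",
    zero_scale: float = 1e-6,
    return_details: bool = False,
):
    """Change-in-estimate confounder screen.

    Each candidate is added alone to the base model; it is selected when the
    largest relative change |b_new - b_base| / |b_base| over the monitored
    coefficients exceeds ``threshold``.  ``monitored`` defaults to the
    subcohort x follow-up interaction columns when present (period analysis)
    and otherwise to storage time (decay analysis).  A monitored base
    coefficient of exactly zero is judged on absolute change against
    ``zero_scale``.
    """
    candidates = list(candidates)
    overlap = set(candidates) & set(spec.fixed_terms)
    if overlap:
        raise ValueError(f"candidates already in the base model: {sorted(overlap)}")
    base = fit_random_intercept(patients, samples, spec, method=method)
    if monitored is None:
        if "subcohort_x_followup" in spec.fixed_terms:
            monitored = ["subcohort_x_followup"]
        else:
            monitored = ["storage_time"]
    mon_cols = base.columns_for(monitored)

    selected, details = [], {}
    for cand in candidates:
        fit_c = fit_random_intercept(
            patients, samples, spec.with_terms(cand), method=method
        )
        changes = []
        for col in mon_cols:
            b0 = base.coefficients[col]
            b1 = fit_c.coefficients[col]
            if b0 == 0.0:
                changes.append(abs(b1 - b0) / zero_scale)
            else:
                changes.append(abs(b1 - b0) / abs(b0))
        details[cand] = max(changes)
        if details[cand] > threshold:
            selected.append(cand)
    if return_details:
        return selected, details
    return selected


def period_effect_test(
    patients: pd.DataFrame,
    samples: pd.DataFrame,
    response: str = "tc",
    confounders: tuple[str, ...] = ("age", "female", "bmi"),
    method: str = "REML",
) -> tuple[TestResult, ModelFit]:
    """Joint test of all subcohort x follow-up interaction coefficients.

    Fits lipid ~ follow-up + follow-up^2 + subcohort + subcohort:follow-up
    (+ confounders) with a patient random intercept and returns the joint
    Wald test of the interaction block together with the fit.
    """
    data = _merged(patients, samples)
    levels = sorted(data["subcohort"].unique())
    if len(levels) < 2:
        raise ValueError("period-effect test needs at least two subcohorts")
    for lev in levels:
        n_fu = data.loc[data["subcohort"] == lev, "followup_time"].nunique()
        if n_fu < 2:
            raise ValueError(
                f"subcohort {lev} has a single follow-up time; "
                "its interaction slope is not estimable"
            )
    spec = DesignSpec(
        response=response,
        fixed_terms=(
            "intercept",
            "followup_time",
            "followup_time_sq",
            "subcohort",
            "subcohort_x_followup",
        )
        + tuple(confounders),
    )
    fit = fit_random_intercept(patients, samples, spec, method=method)
    return wald_test(fit, ["subcohort_x_followup"]), fit
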