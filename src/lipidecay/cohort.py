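"""Synthetic inception-cohort generator for serum-storage decay studies.

Emulates a rheumatoid-arthritis inception cohort enrolled in five calendar
subcohorts (1985-1989 ... 2005-2009), with serum sampled at fixed follow-up
years and all samples assayed on a single analysis date, so that storage time
equals analysis date minus sampling date.  Observed lipid levels follow the
additive model

    obs = mu + covariate effects + g1*t_f + g2*t_f^2 + b_i - decay*t_s + eps

with patient random intercept ``b_i``, quadratic follow-up trend in ``t_f``
(years since inclusion), linear storage decay in ``t_s`` (years frozen) and
Gaussian residual ``eps``.  Calendar trends in statin use, smoking,
glucocorticoid use and age across subcohorts are built in so that period
effects and confounding are representable downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "PatientRecord",
    "SampleRecord",
    "generate_cohort",
    "storage_years",
    "DEFAULT_SUBCOHORT_PERIODS",
    "DEFAULT_COVARIATE_PARAMS",
]

DEFAULT_SUBCOHORT_PERIODS: tuple[tuple[float, float], ...] = (
    (1985, 1989),
    (1990, 1994),
    (1995, 1999),
    (2000, 2004),
    (2005, 2009),
)

# Per-subcohort covariate distributions (means/SDs for continuous, proportions
# for binary), one entry per subcohort, oldest first.  The calendar trends
# matter: statin use rises and smoking falls in later subcohorts.
DEFAULT_COVARIATE_PARAMS: dict[str, tuple[float, ...]] = {
    "age_mean": (51.0, 50.0, 52.0, 58.0, 59.0),
    "age_sd": (14.4, 13.5, 14.5, 12.1, 12.6),
    "female_p": (0.533, 0.613, 0.567, 0.833, 0.677),
    "rf_p": (0.867, 0.742, 0.833, 0.767, 0.806),
    "das28_mean": (5.6, 5.3, 4.8, 4.9, 5.0),
    "das28_sd": (1.2, 1.4, 1.6, 1.0, 1.2),
    "bmi_mean": (26.0, 27.1, 25.6, 26.2, 26.6),
    "bmi_sd": (3.8, 4.6, 3.3, 3.0, 6.8),
    "smoker_p": (0.467, 0.194, 0.333, 0.300, 0.290),
    "statin_p": (0.0, 0.0, 0.067, 0.067, 0.290),
    "glucocorticoid_p": (0.100, 0.097, 0.167, 0.567, 0.548),
}


class ConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


@dataclass
class CohortConfig:
    """Configuration of the synthetic cohort generator.

    Parameters mirror the study design: five inclusion-period subcohorts,
    sampling at follow-up years {0,1,2,3,5,7,10}, a single analysis date
    (January 2012 -> 2012.0), and per-year linear storage decay on total and
    HDL cholesterol.  Lipid units are mmol/L throughout.
    """

    n_patients_per_subcohort: int = 30
    subcohort_periods: tuple[tuple[float, float], ...] = DEFAULT_SUBCOHORT_PERIODS
    followup_years: tuple[float, ...] = (0, 1, 2, 3, 5, 7, 10)
    analysis_date: float = 2012.0

    # storage decay, mmol/L per storage-year (positive = loss)
    true_decay_tc: float = 0.030
    true_decay_hdl: float = 0.024

    # quadratic within-patient follow-up trend (g1, g2) per lipid
    followup_trend_tc: tuple[float, float] = (0.012, -0.0001)
    followup_trend_hdl: tuple[float, float] = (0.003, -0.00003)

    # lipid level at reference covariates (age 54, male, BMI 26, no treatment)
    tc_intercept: float = 5.0
    hdl_intercept: float = 1.25

    # covariate effects on the true lipid level, mmol/L per unit
    beta_tc: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.016,
            "female": 0.023,
            "bmi": 0.011,
            "statin": 0.888,
            "glucocorticoid": 0.239,
        }
    )
    beta_hdl: dict[str, float] = field(
        default_factory=lambda: {"age": 0.003, "female": 0.074}
    )

    covariate_params: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )

    random_intercept_sd: float = 0.8
    residual_sd: float = 0.5
    # HDL varies on a much narrower scale than TC; both HDL variance
    # components are scaled by this factor.
    hdl_sd_scale: float = 0.25

    lipid_floor: float = 0.1
    sbp_mean: float = 135.0
    sbp_sd: float = 15.0
    tg_log_mean: float = 0.336  # log(1.4 mmol/L)
    tg_log_sd: float = 0.4

    seed: int = 0

    # reference covariate values subtracted before applying betas
    age_ref: float = 54.0
    bmi_ref: float = 26.0

    def validate(self) -> None:
        periods = list(self.subcohort_periods)
        if not periods:
            raise ConfigError("subcohort_periods: at least one period required")
        for (s, e) in periods:
            if e < s:
                raise ConfigError(f"subcohort_periods: period ({s}, {e}) reversed")
        for (a, b) in zip(periods, periods[1:]):
            if b[0] <= a[1]:
                raise ConfigError(
                    f"subcohort_periods: periods {a} and {b} overlap or are unordered"
                )
        if self.n_patients_per_subcohort <= 0:
            raise ConfigError("n_patients_per_subcohort: must be positive")
        fu = list(self.followup_years)
        if any(t < 0 for t in fu):
            raise ConfigError("followup_years: must be non-negative")
        if fu != sorted(fu):
            raise ConfigError("followup_years: must be sorted ascending")
        for name in ("random_intercept_sd", "residual_sd", "hdl_sd_scale",
                     "sbp_sd", "tg_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative")
        # all inclusion dates must precede the analysis date
        last_inclusion = periods[-1][1] + 1.0
        if self.analysis_date < periods[0][0]:
            raise ConfigError("analysis_date: precedes the first inclusion period")
        if self.analysis_date < last_inclusion - 1.0:
            raise ConfigError("analysis_date: earlier than the last inclusion year")
        n_sc = len(periods)
        for key, vals in self.covariate_params.items():
            if len(vals) != n_sc:
                raise ConfigError(
                    f"covariate_params[{key}]: expected {n_sc} per-subcohort values"
                )

    def config_hash(self) -> str:
        """Stable hash of the full configuration (used in run manifests)."""
        canon = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


@dataclass
class PatientRecord:
    """Row schema of the patients table."""

    patient_id: str
    inclusion_date: float
    subcohort: int
    age: float
    female: bool
    bmi: float
    smoker: bool
    statin: bool
    glucocorticoid: bool
    das28: float
    rf_positive: bool
    sbp: float
    random_intercept_tc: float
    random_intercept_hdl: float


@dataclass
class SampleRecord:
    """Row schema of the samples table (one serum measurement occasion)."""

    patient_id: str
    subcohort: int
    followup_time: float
    sample_date: float
    storage_time: float
    tc_true: float
    hdl_true: float
    tc_obs: float
    hdl_obs: float
    tg_obs: float
    sbp: float


def storage_years(sample_date: float, analysis_date: float) -> float:
    """Years a sample spent frozen: analysis date minus sampling date.

    Both dates are decimal years.  Raises ``ValueError`` if the sample would
    have been analysed before it was taken.
    """
    delta = analysis_date - sample_date
    if np.any(np.asarray(delta) < 0):
        raise ValueError(
            f"sample_date {sample_date!r} is after analysis_date {analysis_date!r}"
        )
    return delta


def _resample_floor(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: float,
    floor: float,
    max_tries: int = 100,
) -> np.ndarray:
    """Draw mean + N(0, sd) redrawing the noise while below ``floor``."""
    if sd == 0:
        return np.maximum(mean, floor)
    out = mean + rng.normal(0.0, sd, size=mean.shape)
    for _ in range(max_tries):
        mask = out < floor
        if not mask.any():
            break
        out[mask] = mean[mask] + rng.normal(0.0, sd, size=int(mask.sum()))
    return np.maximum(out, floor)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic cohort; returns (patients, samples) DataFrames.

    Deterministic given ``config.seed``.  Samples whose date would exceed the
    analysis date are dropped, reproducing the staircase design in which
    recent subcohorts contribute short follow-up only.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = config.covariate_params
    sd_hdl_b = config.random_intercept_sd * config.hdl_sd_scale
    sd_hdl_e = config.residual_sd * config.hdl_sd_scale

    patients = []
    for isc, (start, end) in enumerate(config.subcohort_periods, start=1):
        n = config.n_patients_per_subcohort
        j = isc - 1
        incl = rng.uniform(start, end + 1.0, size=n)
        age = np.clip(rng.normal(cov["age_mean"][j], cov["age_sd"][j], n), 18, 95)
        female = rng.random(n) < cov["female_p"][j]
        bmi = np.clip(rng.normal(cov["bmi_mean"][j], cov["bmi_sd"][j], n), 15, 55)
        smoker = rng.random(n) < cov["smoker_p"][j]
        statin = rng.random(n) < cov["statin_p"][j]
        gluco = rng.random(n) < cov["glucocorticoid_p"][j]
        das28 = np.clip(rng.normal(cov["das28_mean"][j], cov["das28_sd"][j], n), 0, 10)
        rf = rng.random(n) < cov["rf_p"][j]
        sbp = np.clip(rng.normal(config.sbp_mean, config.sbp_sd, n), 90, 210)
        b_tc = rng.normal(0.0, config.random_intercept_sd, n) \
            if config.random_intercept_sd > 0 else np.zeros(n)
        b_hdl = rng.normal(0.0, sd_hdl_b, n) if sd_hdl_b > 0 else np.zeros(n)
        patients.append(
            pd.DataFrame(
                {
                    "patient_id": [f"S{isc}P{k:03d}" for k in range(n)],
                    "subcohort": isc,
                    "inclusion_date": incl,
                    "age": age,
                    "female": female,
                    "bmi": bmi,
                    "smoker": smoker,
                    "statin": statin,
                    "glucocorticoid": gluco,
                    "das28": das28,
                    "rf_positive": rf,
                    "sbp": sbp,
                    "random_intercept_tc": b_tc,
                    "random_intercept_hdl": b_hdl,
                }
            )
        )
    pat = pd.concat(patients, ignore_index=True)

    # systematic (storage-free) lipid level per patient at follow-up 0
    btc, bhdl = config.beta_tc, config.beta_hdl
    tc_base = (
        config.tc_intercept
        + btc.get("age", 0.0) * (pat["age"] - config.age_ref)
        + btc.get("female", 0.0) * pat["female"]
        + btc.get("bmi", 0.0) * (pat["bmi"] - config.bmi_ref)
        + btc.get("statin", 0.0) * pat["statin"]
        + btc.get("glucocorticoid", 0.0) * pat["glucocorticoid"]
        + pat["random_intercept_tc"]
    ).to_numpy()
    hdl_base = (
        config.hdl_intercept
        + bhdl.get("age", 0.0) * (pat["age"] - config.age_ref)
        + bhdl.get("female", 0.0) * pat["female"]
        + pat["random_intercept_hdl"]
    ).to_numpy()

    g1_tc, g2_tc = config.followup_trend_tc
    g1_h, g2_h = config.followup_trend_hdl
    incl = pat["inclusion_date"].to_numpy()

    frames = []
    for t_f in config.followup_years:
        date = incl + t_f
        keep = date <= config.analysis_date
        if not keep.any():
            continue
        t_s = storage_years(date[keep], config.analysis_date)
        tc_true = tc_base[keep] + g1_tc * t_f + g2_tc * t_f**2
        hdl_true = hdl_base[keep] + g1_h * t_f + g2_h * t_f**2
        tc_obs = _resample_floor(
            rng, tc_true - config.true_decay_tc * t_s,
            config.residual_sd, config.lipid_floor,
        )
        hdl_obs = _resample_floor(
            rng, hdl_true - config.true_decay_hdl * t_s,
            sd_hdl_e, config.lipid_floor,
        )
        tg = np.exp(rng.normal(config.tg_log_mean, config.tg_log_sd, int(keep.sum())))
        tg = np.minimum(tg, 4.4)  # keep within Friedewald validity
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pat.loc[keep, "patient_id"].to_numpy(),
                    "subcohort": pat.loc[keep, "subcohort"].to_numpy(),
                    "followup_time": float(t_f),
                    "sample_date": date[keep],
                    "storage_time": t_s,
                    "tc_true": tc_true,
                    "hdl_true": hdl_true,
                    "tc_obs": tc_obs,
                    "hdl_obs": hdl_obs,
                    "tg_obs": tg,
                    "sbp": pat.loc[keep, "sbp"].to_numpy(),
                }
            )
        )
    samples = pd.concat(frames, ignore_index=True)
    samples = samples.sort_values(
        ["patient_id", "followup_time"], kind="mergesort"
    ).reset_index(drop=True)
    return pat, samples


def records_from_frames(
    patients: pd.DataFrame, samples: pd.DataFrame
) -> tuple[list[PatientRecord], list[SampleRecord]]:
    """Dataclass view of the two tables (row-wise)."""
    ps = [PatientRecord(**row) for row in patients.to_dict("records")]
    ss = [SampleRecord(**row) for row in samples.to_dict("records")]
    return ps, ss
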