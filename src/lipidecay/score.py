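"""SCORE 10-year fatal cardiovascular risk (Weibull model, Conroy 2003).

The risk engine follows the published algorithm.  For each cause c in
{CHD, non-CHD CVD} with sex- and region-specific Weibull parameters
(alpha, p):

    S0(age)   = exp(-exp(alpha) * (age - 20)^p)          baseline survival
    w         = sum_k beta_k * (x_k - ref_k)             linear predictor
    S(age)    = S0(age)^exp(w)
    risk_c    = 1 - S(age+10) / S(age)                   10-y conditional risk
    risk      = risk_CHD + risk_nonCHD

Two cholesterol variants exist: total cholesterol (mmol/L, reference 6) and
the TC:HDL ratio (reference 5).  Risk categories follow the clinical
cut-offs: low < 10 %, intermediate 10-20 % (closed interval), high > 20 %.
Coefficients live in a versioned YAML constants file shipped with the
package; nothing numeric is hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ScoreCoefficients",
    "RiskProfile",
    "RiskResult",
    "load_coefficients",
    "baseline_survival",
    "ten_year_risk",
    "classify_risk",
    "CATEGORIES",
    "DEFAULT_CUTOFFS",
]

CATEGORIES = ("low", "intermediate", "high")
DEFAULT_CUTOFFS = (0.10, 0.20)
AGE_RANGE = (20.0, 85.0)  # calibrated range of the published model


@dataclass(frozen=True)
class CauseCoefficients:
    alpha: dict  # sex -> Weibull location
    p: dict  # sex -> Weibull shape
    beta: dict  # factor -> coefficient


@dataclass(frozen=True)
class ScoreCoefficients:
    region: str
    variant: str  # "total_cholesterol" or "tc_hdl_ratio"
    chd: CauseCoefficients
    non_chd: CauseCoefficients
    reference_values: dict
    version: str

    def cholesterol_beta(self, cause: CauseCoefficients) -> tuple[float, float]:
        """(beta, reference) of the cholesterol term for this variant."""
        key = "cholesterol" if self.variant == "total_cholesterol" else "ratio"
        return cause.beta[key], self.reference_values[key]


@dataclass(frozen=True)
class RiskProfile:
    """Inputs to the SCORE calculation for one person."""

    age: float
    sex: str  # "female" | "male"
    sbp: float
    smoker: bool
    cholesterol_term: float  # mmol/L TC, or TC:HDL ratio, per variant

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 19 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside plausible range [19, 100]")
        if not 70 <= self.sbp <= 260:
            raise ValueError(f"SBP {self.sbp} outside plausible range [70, 260]")
        if self.cholesterol_term <= 0:
            raise ValueError("cholesterol term must be positive")


@dataclass(frozen=True)
class RiskResult:
    risk_10yr: float  # fraction in [0, 1)
    category: str
    risk_chd: float
    risk_non_chd: float


@lru_cache(maxsize=8)
def load_coefficients(
    region: str = "low_risk", variant: str = "tc_hdl_ratio"
) -> ScoreCoefficients:
    """Load the versioned SCORE constants shipped with the package."""
    if variant not in ("total_cholesterol", "tc_hdl_ratio"):
        raise ValueError(f"unknown variant {variant!r}")
    text = (
        resources.files("lipidecay").joinpath("data/score_conroy2003.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    try:
        reg = raw["regions"][region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; available: {sorted(raw['regions'])}"
        ) from None
    return ScoreCoefficients(
        region=region,
        variant=variant,
        chd=CauseCoefficients(**reg["chd"]),
        non_chd=CauseCoefficients(**reg["non_chd"]),
        reference_values=raw["reference_values"],
        version=raw["version"],
    )


def baseline_survival(age, alpha: float, p: float):
    """Weibull baseline survival S0(age) = exp(-exp(alpha) * (age-20)^p).

    Ages at or below 20 give S0 = 1 (the exponent base clamps at zero).
    """
    if p <= 0:
        raise ValueError(f"Weibull shape p must be positive, got {p}")
    age = np.asarray(age, dtype=float)
    base = np.maximum(age - 20.0, 0.0)
    out = np.exp(-np.exp(alpha) * base**p)
    return float(out) if out.ndim == 0 else out


def _cause_risk(
    profile: RiskProfile, cause: CauseCoefficients, coeffs: ScoreCoefficients
) -> float:
    alpha = cause.alpha[profile.sex]
    p = cause.p[profile.sex]
    beta_chol, ref_chol = coeffs.cholesterol_beta(cause)
    refs = coeffs.reference_values
    w = (
        beta_chol * (profile.cholesterol_term - ref_chol)
        + cause.beta["sbp"] * (profile.sbp - refs["sbp"])
        + cause.beta["smoker"] * (float(profile.smoker) - refs["smoker"])
    )
    ew = np.exp(w)
    s_now = baseline_survival(profile.age, alpha, p) ** ew
    s_10 = baseline_survival(profile.age + 10.0, alpha, p) ** ew
    return float(1.0 - s_10 / s_now)


def ten_year_risk(
    profile: RiskProfile,
    coeffs: ScoreCoefficients | None = None,
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS,
    allow_out_of_range: bool = False,
) -> RiskResult:
    """Total 10-year fatal-CVD risk (CHD + non-CHD) with its category.

    Ages outside the calibrated range [20, 85] raise by default; pass
    ``allow_out_of_range=True`` to extrapolate deliberately.
    """
    if coeffs is None:
        coeffs = load_coefficients()
    if not allow_out_of_range and not AGE_RANGE[0] <= profile.age <= AGE_RANGE[1]:
        raise ValueError(
            f"age {profile.age} outside the calibrated range {AGE_RANGE}; "
            "pass allow_out_of_range=True to extrapolate"
        )
    r_chd = _cause_risk(profile, coeffs.chd, coeffs)
    r_non = _cause_risk(profile, coeffs.non_chd, coeffs)
    total = min(r_chd + r_non, 1.0 - 1e-12)
    return RiskResult(total, classify_risk(total, cutoffs), r_chd, r_non)


def classify_risk(
    risk_10yr: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS
) -> str:
    """Risk category: low < c1; intermediate in [c1, c2]; high > c2."""
    lo, hi = cutoffs
    if not 0.0 <= risk_10yr <= 1.0:
        raise ValueError(f"risk {risk_10yr} outside [0, 1]")
    if risk_10yr < lo:
        return "low"
    if risk_10yr <= hi:
        return "intermediate"
    return "high"
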