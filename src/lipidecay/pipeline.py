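"""End-to-end pipeline: simulate (or load) -> period-effect test ->
confounder screen -> decay fits -> correction -> SCORE risk before/after ->
reclassification summary.  Fully deterministic under a fixed seed; every
output file carries the seed and config hash in its metadata header."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .decay import DecayFactor, correct_samples, factor_from_fits
from .io import read_patients_csv, read_samples_csv, write_table
from .longitudinal import (
    DesignSpec,
    fit_random_intercept,
    period_effect_test,
    screen_confounders,
)
from .reclassify import build_table, render_summary, summarize
from .score import RiskProfile, load_coefficients, ten_year_risk

log = logging.getLogger("lipidecay")

__all__ = ["PipelineConfig", "run_pipeline", "risk_categories"]

#: confounder candidates offered to the change-in-estimate screen
DEFAULT_CANDIDATES = (
    "age",
    "female",
    "bmi",
    "smoker",
    "statin",
    "glucocorticoid",
    "das28",
    "rf_positive",
)


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from a YAML file."""

    out_dir: str = "lipidecay_out"
    patients_csv: str | None = None  # when set, load instead of simulate
    samples_csv: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    method: str = "REML"
    confounder_candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    confounder_threshold: float = 0.10
    decay_override: tuple[float, float] | None = None  # (tc, hdl)
    variant: str = "tc_hdl_ratio"
    region: str = "low_risk"
    cutoffs: tuple[float, float] = (0.10, 0.20)
    apply_correction: bool = True
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        cfg = cls(**raw)
        cfg.cohort = CohortConfig(**cohort_raw)
        cfg.cohort.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        import hashlib

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = repr(sorted(payload.items())).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def risk_categories(
    patients: pd.DataFrame,
    samples: pd.DataFrame,
    ratio_col: str,
    variant: str = "tc_hdl_ratio",
    region: str = "low_risk",
    cutoffs: tuple[float, float] = (0.10, 0.20),
) -> pd.DataFrame:
    """SCORE risk and category per patient from the baseline sample.

    The cholesterol term is taken from ``ratio_col`` of each patient's
    earliest sample.  Ages are clamped to the calibrated range [20, 85]
    before evaluation (simulated cohorts contain a few older patients; this
    keeps the engine's range guard intact for interactive use).
    """
    coeffs = load_coefficients(region=region, variant=variant)
    baseline = samples.sort_values("followup_time").groupby("patient_id").first()
    merged = patients.set_index("patient_id").join(
        baseline[[ratio_col]], how="inner"
    )
    rows = []
    for pid, row in merged.iterrows():
        profile = RiskProfile(
            age=float(np.clip(row["age"], 20.0, 85.0)),
            sex="female" if bool(row["female"]) else "male",
            sbp=float(row["sbp"]),
            smoker=bool(row["smoker"]),
            cholesterol_term=float(row[ratio_col]),
        )
        res = ten_year_risk(profile, coeffs, cutoffs=cutoffs)
        rows.append(
            {"patient_id": pid, "risk_10yr": res.risk_10yr, "category": res.category}
        )
    return pd.DataFrame(rows).set_index("patient_id")


# fixed-effect designs of the two decay analyses (storage-time models)
TC_DECAY_SPEC = DesignSpec(
    "tc",
    (
        "intercept",
        "storage_time",
        "followup_time",
        "followup_time_sq",
        "age",
        "female",
        "bmi",
        "statin",
        "glucocorticoid",
    ),
)
HDL_DECAY_SPEC = DesignSpec(
    "hdl",
    ("intercept", "storage_time", "followup_time", "followup_time_sq", "age", "female"),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "lipidecay_version": __version__,
    }

    if config.patients_csv and config.samples_csv:
        log.info("loading cohort from %s / %s", config.patients_csv, config.samples_csv)
        patients, _ = read_patients_csv(config.patients_csv)
        samples, _ = read_samples_csv(config.samples_csv)
    else:
        log.info("simulating cohort (seed %d)", config.seed)
        config.cohort.seed = config.seed
        patients, samples = generate_cohort(config.cohort)
    write_table(patients, out / "patients.csv", meta)
    write_table(samples, out / "samples.csv", meta)

    period = {}
    for lipid in ("tc", "hdl"):
        test, _fit = period_effect_test(patients, samples, lipid, method="ML")
        period[lipid] = test
        log.info("period effect (%s): chi2=%.3f df=%d p=%.3f",
                 lipid, test.statistic, test.df, test.p_value)
    write_table(
        pd.DataFrame(
            [
                {"response": k, "statistic": v.statistic, "df": v.df,
                 "p_value": v.p_value, "kind": v.kind}
                for k, v in period.items()
            ]
        ),
        out / "period_tests.csv",
        meta,
    )

    base_tc = DesignSpec("tc", ("intercept", "storage_time", "followup_time",
                                "followup_time_sq"))
    selected, changes = screen_confounders(
        patients,
        samples,
        base_tc,
        config.confounder_candidates,
        threshold=config.confounder_threshold,
        monitored=["storage_time"],
        method=config.method,
        return_details=True,
    )
    log.info("confounders selected for TC decay model: %s", selected)

    fit_tc = fit_random_intercept(patients, samples, TC_DECAY_SPEC, config.method)
    fit_hdl = fit_random_intercept(patients, samples, HDL_DECAY_SPEC, config.method)
    write_table(fit_tc.coefficient_table(), out / "coef_tc.csv", meta)
    write_table(fit_hdl.coefficient_table(), out / "coef_hdl.csv", meta)

    if config.decay_override is not None:
        factor = DecayFactor(*config.decay_override, source="override")
    else:
        factor = factor_from_fits(fit_tc, fit_hdl)
    log.info("decay factor: TC %.4f, HDL %.4f mmol/L per year",
             factor.decay_tc, factor.decay_hdl)

    corrected = correct_samples(samples, factor)
    write_table(corrected, out / "corrected_samples.csv", meta)

    before = risk_categories(
        patients, corrected, "ratio_observed",
        config.variant, config.region, config.cutoffs,
    )
    after_col = "ratio_corrected" if config.apply_correction else "ratio_observed"
    after = risk_categories(
        patients, corrected, after_col,
        config.variant, config.region, config.cutoffs,
    )
    table = build_table(before["category"], after["category"])
    summary = summarize(table)
    write_table(summary, out / "reclassification.csv", meta)
    (out / "reclassification.txt").write_text(render_summary(summary) + "\n")

    manifest = {
        **meta,
        "n_patients": int(len(patients)),
        "n_samples": int(len(samples)),
        "decay_tc": factor.decay_tc,
        "decay_hdl": factor.decay_hdl,
        "decay_source": factor.source,
        "confounders_selected": list(selected),
        "confounder_changes": {k: float(v) for k, v in changes.items()},
        "period_p_values": {k: v.p_value for k, v in period.items()},
        "n_reclassified": table.n_reclassified,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "patients": patients,
        "samples": samples,
        "corrected": corrected,
        "period": period,
        "fit_tc": fit_tc,
        "fit_hdl": fit_hdl,
        "factor": factor,
        "before": before,
        "after": after,
        "table": table,
        "summary": summary,
        "manifest": manifest,
    }
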