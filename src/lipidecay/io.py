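"""CSV round-trip for cohort tables and run metadata headers.

Files are comma-separated UTF-8 with '.' decimals and decimal-year dates.
Metadata (seed, config hash, package version) is carried in leading comment
lines of the form ``# key: value`` so every output is traceable to its run.
Unknown columns survive a read/write round trip untouched.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "write_table",
    "read_table",
    "read_patients_csv",
    "read_samples_csv",
    "PATIENT_REQUIRED",
    "SAMPLE_REQUIRED",
]

PATIENT_REQUIRED = ("patient_id", "subcohort", "inclusion_date", "age", "female")
SAMPLE_REQUIRED = (
    "patient_id",
    "followup_time",
    "sample_date",
    "storage_time",
    "tc_obs",
    "hdl_obs",
)
_LIPID_COLUMNS = ("tc_obs", "hdl_obs", "tg_obs", "tc_true", "hdl_true")


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a CSV with ``# key: value`` metadata comment lines on top."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, metadata)."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def _require(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_numeric_lipids(df: pd.DataFrame, path) -> pd.DataFrame:
    n_meta_lines = 0  # reported line numbers are 1-based within the data body
    for col in _LIPID_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r} "
                f"at data row {row + 1 + n_meta_lines}"
            )
        df[col] = coerced
    return df


def read_patients_csv(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_table(path)
    _require(df, PATIENT_REQUIRED, path)
    for col in ("female", "smoker", "statin", "glucocorticoid", "rf_positive"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df, meta


def read_samples_csv(path) -> tuple[pd.DataFrame, dict]:
    df, meta = read_table(path)
    _require(df, SAMPLE_REQUIRED, path)
    df = _check_numeric_lipids(df, path)
    return df, meta
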