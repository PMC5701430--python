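"""Readers and writers for the delimited EHR extract tables.

The pipeline consumes three comma-delimited UTF-8 tables with headers:

``patients``
    patient_id, birth_date, gender, ethnicity, death_date (blank allowed),
    plus an optional 0/1 ``terminal_flag`` column marking patients with a
    clinician-recorded terminal illness;
``diagnoses``
    patient_id, code, system (ICD9 | ICD10 | primary_care), date;
``encounters``
    patient_id, modality (inpatient | ED | specialist_clinic |
    primary_care), start_date, end_date (inpatient only, blank allowed).

and emits an ``assignments`` table: patient_id, segment, n_conditions,
index_year_admissions, rule_fired.  All dates are ISO 8601 (YYYY-MM-DD).

Readers run in lenient mode by default: malformed rows are skipped and
reported through the module logger (real EHR extracts are dirty).  In
strict mode any invalid row raises :class:`~popseg.errors.RowError`
carrying the full row-numbered report.  Tables are returned as pandas
DataFrames with parsed dtypes; the two modes agree on fully valid files.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import RowError, SchemaError

logger = logging.getLogger(__name__)

GENDERS = ("male", "female")
ETHNICITIES = ("chinese", "indian", "malay", "other")
SYSTEMS = ("ICD9", "ICD10", "primary_care")
MODALITIES = ("inpatient", "ED", "specialist_clinic", "primary_care")

PATIENT_COLUMNS = ["patient_id", "birth_date", "gender", "ethnicity", "death_date"]
DIAGNOSIS_COLUMNS = ["patient_id", "code", "system", "date"]
ENCOUNTER_COLUMNS = ["patient_id", "modality", "start_date", "end_date"]
ASSIGNMENT_COLUMNS = [
    "patient_id",
    "segment",
    "n_conditions",
    "index_year_admissions",
    "rule_fired",
]
TRUTH_COLUMNS = ["patient_id", "segment"]


def _read_raw(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"{path}: cannot read table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def _parse_dates(series: pd.Series) -> pd.Series:
    # blank -> NaT; anything non-blank must parse as YYYY-MM-DD
    return pd.to_datetime(series.replace("", None), format="%Y-%m-%d", errors="coerce")


def _finalize(df: pd.DataFrame, bad: pd.Series, reasons: pd.Series, path, strict: bool):
    """Drop (lenient) or raise on (strict) rows flagged invalid."""
    if not bad.any():
        return df.reset_index(drop=True)
    report = [(int(i) + 1, reasons.iloc[i]) for i in np.flatnonzero(bad.to_numpy())]
    if strict:
        head = "; ".join(f"row {r}: {m}" for r, m in report[:5])
        raise RowError(f"{path}: {len(report)} invalid row(s): {head}", errors=report)
    logger.warning(
        "%s: skipped %d invalid row(s); first: row %d: %s",
        path, len(report), report[0][0], report[0][1],
    )
    return df.loc[~bad].reset_index(drop=True)


def _flag(bad: pd.Series, reasons: pd.Series, mask: pd.Series, message: str) -> None:
    newly = mask & ~bad
    reasons[newly] = message
    bad[mask.to_numpy()] = True


def read_patients(path, strict: bool = False) -> pd.DataFrame:
    """Read the patients table; see module docstring for the schema."""
    df = _read_raw(path, PATIENT_COLUMNS)
    bad = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)

    birth = _parse_dates(df["birth_date"])
    death = _parse_dates(df["death_date"])
    _flag(bad, reasons, df["patient_id"].str.strip() == "", "empty patient_id")
    _flag(bad, reasons, birth.isna(), "unparseable birth_date")
    _flag(bad, reasons, (df["death_date"] != "") & death.isna(), "unparseable death_date")
    _flag(bad, reasons, ~df["gender"].isin(GENDERS), "gender not in " + "/".join(GENDERS))
    _flag(bad, reasons, ~df["ethnicity"].isin(ETHNICITIES),
          "ethnicity not in " + "/".join(ETHNICITIES))
    _flag(bad, reasons, death.notna() & (death < birth), "death_date before birth_date")
    _flag(bad, reasons, df["patient_id"].duplicated(keep=False) & ~bad,
          "duplicate patient_id")

    out = df.copy()
    out["birth_date"] = birth
    out["death_date"] = death
    if "terminal_flag" in out.columns:
        flag_ok = out["terminal_flag"].isin(("", "0", "1"))
        _flag(bad, reasons, ~flag_ok, "terminal_flag must be 0/1/blank")
        out["terminal_flag"] = (out["terminal_flag"] == "1")
    keep = PATIENT_COLUMNS + (["terminal_flag"] if "terminal_flag" in out.columns else [])
    return _finalize(out[keep], bad, reasons, path, strict)


def read_diagnoses(path, strict: bool = False) -> pd.DataFrame:
    """Read the diagnoses table; see module docstring for the schema."""
    df = _read_raw(path, DIAGNOSIS_COLUMNS)
    bad = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)

    date = _parse_dates(df["date"])
    _flag(bad, reasons, df["patient_id"].str.strip() == "", "empty patient_id")
    _flag(bad, reasons, df["code"].str.strip() == "", "empty code")
    _flag(bad, reasons, ~df["system"].isin(SYSTEMS), "system not in " + "/".join(SYSTEMS))
    _flag(bad, reasons, date.isna(), "unparseable date")

    out = df[DIAGNOSIS_COLUMNS].copy()
    out["date"] = date
    return _finalize(out, bad, reasons, path, strict)


def read_encounters(path, strict: bool = False) -> pd.DataFrame:
    """Read the encounters table; see module docstring for the schema."""
    df = _read_raw(path, ENCOUNTER_COLUMNS)
    bad = pd.Series(False, index=df.index)
    reasons = pd.Series("", index=df.index)

    start = _parse_dates(df["start_date"])
    end = _parse_dates(df["end_date"])
    _flag(bad, reasons, df["patient_id"].str.strip() == "", "empty patient_id")
    _flag(bad, reasons, ~df["modality"].isin(MODALITIES),
          "modality not in " + "/".join(MODALITIES))
    _flag(bad, reasons, start.isna(), "unparseable start_date")
    _flag(bad, reasons, (df["end_date"] != "") & end.isna(), "unparseable end_date")
    _flag(bad, reasons, end.notna() & (end < start), "end_date before start_date")
    _flag(bad, reasons, (df["modality"] != "inpatient") & (df["end_date"] != ""),
          "end_date only allowed for inpatient encounters")

    out = df[ENCOUNTER_COLUMNS].copy()
    out["start_date"] = start
    out["end_date"] = end
    return _finalize(out, bad, reasons, path, strict)


def read_assignments(path) -> pd.DataFrame:
    """Read an assignments table written by :func:`write_assignments`."""
    df = _read_raw(path, ASSIGNMENT_COLUMNS)
    out = df[ASSIGNMENT_COLUMNS].copy()
    out["n_conditions"] = out["n_conditions"].astype(int)
    out["index_year_admissions"] = out["index_year_admissions"].astype(int)
    return out


def read_truth_labels(path) -> pd.DataFrame:
    """Read a truth-labels table (patient_id, segment)."""
    df = _read_raw(path, TRUTH_COLUMNS)
    return df[TRUTH_COLUMNS].copy()


def _dates_to_iso(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d").fillna("")
    return out


def write_patients(df: pd.DataFrame, path) -> None:
    keep = PATIENT_COLUMNS + (["terminal_flag"] if "terminal_flag" in df.columns else [])
    out = _dates_to_iso(df[keep], ["birth_date", "death_date"])
    if "terminal_flag" in out.columns:
        out["terminal_flag"] = out["terminal_flag"].astype(int)
    out.to_csv(path, index=False)


def write_diagnoses(df: pd.DataFrame, path) -> None:
    _dates_to_iso(df[DIAGNOSIS_COLUMNS], ["date"]).to_csv(path, index=False)


def write_encounters(df: pd.DataFrame, path) -> None:
    _dates_to_iso(df[ENCOUNTER_COLUMNS], ["start_date", "end_date"]).to_csv(path, index=False)


def write_assignments(df: pd.DataFrame, path) -> None:
    """Write assignments with a stable column order; round-trips through
    :func:`read_assignments`."""
    df[ASSIGNMENT_COLUMNS].to_csv(path, index=False)


def write_truth_labels(df: pd.DataFrame, path) -> None:
    df[TRUTH_COLUMNS].to_csv(path, index=False)
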