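"""Builders for small hand-written EHR table fixtures."""

from __future__ import annotations

import pandas as pd


def patients_df(rows: list[dict]) -> pd.DataFrame:
    """rows: dicts with patient_id and optional overrides."""
    defaults = {
        "birth_date": "1960-06-15",
        "gender": "female",
        "ethnicity": "chinese",
        "death_date": None,
    }
    records = [{**defaults, **r} for r in rows]
    df = pd.DataFrame(records)[
        ["patient_id", "birth_date", "gender", "ethnicity", "death_date"]
    ]
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


def diagnoses_df(rows: list[tuple]) -> pd.DataFrame:
    """rows: (patient_id, code, system, date) tuples."""
    df = pd.DataFrame(rows, columns=["patient_id", "code", "system", "date"])
    df["date"] = pd.to_datetime(df["date"])
    return df


def encounters_df(rows: list[tuple]) -> pd.DataFrame:
    """rows: (patient_id, modality, start_date[, end_date]) tuples."""
    norm = [r if len(r) == 4 else (*r, None) for r in rows]
    df = pd.DataFrame(
        norm, columns=["patient_id", "modality", "start_date", "end_date"]
    )
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df
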