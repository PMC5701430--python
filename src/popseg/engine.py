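"""Core segmentation computation.

A cohort is segmented in four steps:

1. **Eligibility** — adults at or above a minimum age (default 21,
   completed years at 1 January of the index year) with at least one
   healthcare encounter of any modality starting in the index year.
2. **Condition detection** — every diagnosis code dated within the
   look-back window (default 5 calendar years ending with the index
   year) is resolved against the condition catalog; a patient's
   condition set is the union over their records.
3. **Admission counting** — inpatient records are merged into episodes
   (overlapping or abutting stays — next start no later than one day
   after the previous discharge — count once, so inter-hospital
   transfers are not double-counted) and episodes starting in the index
   year are counted.
4. **Hierarchical assignment** — the first matching rule in precedence
   order wins:

   ====================  =============================================
   segment               rule
   ====================  =============================================
   ``end_of_life``       any terminal-category condition (or terminal
                         flag in the patients table)
   ``complex_freq``      any complex-category condition and at least
                         *threshold* (default 3) index-year admissions
   ``complex_no_freq``   any complex-category condition
   ``serious_acute``     at least one index-year admission
   ``stable_chronic``    any stable-category condition
   ``mostly_healthy``    everything else
   ====================  =============================================

The precedence order is configurable; the default places every admitted
patient without complex disease in ``serious_acute``, which is the only
order under which the healthy and stable-chronic segments have exactly
zero index-year admissions.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .catalog import Category, ConditionCatalog, match_code
from .errors import ConsistencyError

logger = logging.getLogger(__name__)

#: The six mutually exclusive population segments, in default precedence order
#: (highest precedence first).
SEGMENTS = (
    "end_of_life",
    "complex_freq",
    "complex_no_freq",
    "serious_acute",
    "stable_chronic",
    "mostly_healthy",
)

#: Short label of the rule that places a patient in each segment.
RULE_LABELS = {
    "end_of_life": "terminal_condition",
    "complex_freq": "complex_and_frequent_admissions",
    "complex_no_freq": "complex_condition",
    "serious_acute": "index_year_admission",
    "stable_chronic": "stable_condition",
    "mostly_healthy": "no_rule_matched",
}


class SegmentationConfig(BaseModel):
    """Tunable parameters of the segmentation pipeline."""

    model_config = ConfigDict(frozen=True)

    index_year: int = 2012
    lookback_years: int = Field(default=5, ge=1)
    frequent_admission_threshold: int = Field(default=3, ge=1)
    min_age: int = Field(default=21, ge=0)
    precedence: tuple[str, ...] = SEGMENTS

    @model_validator(mode="after")
    def _precedence_is_permutation(self) -> "SegmentationConfig":
        if sorted(self.precedence) != sorted(SEGMENTS):
            raise ValueError(
                f"precedence must be a permutation of {sorted(SEGMENTS)}"
            )
        return self

    @property
    def reference_date(self) -> pd.Timestamp:
        """Date at which eligibility age is evaluated (1 January, index year)."""
        return pd.Timestamp(self.index_year, 1, 1)

    @property
    def lookback_start_year(self) -> int:
        return self.index_year - self.lookback_years + 1

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def _age_at_reference(birth: pd.Series, config: SegmentationConfig) -> pd.Series:
    """Completed years of age at 1 January of the index year."""
    ref = config.reference_date
    birthday_after_ref = (birth.dt.month > ref.month) | (
        (birth.dt.month == ref.month) & (birth.dt.day > ref.day)
    )
    return config.index_year - birth.dt.year - birthday_after_ref.astype(int)


def filter_eligible(
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    config: SegmentationConfig,
) -> set[str]:
    """Patients aged >= min_age at the reference date with >= 1 encounter
    of any modality starting in the index year."""
    age = _age_at_reference(patients["birth_date"], config)
    of_age = set(patients.loc[age >= config.min_age, "patient_id"])
    in_year = encounters["start_date"].dt.year == config.index_year
    used_services = set(encounters.loc[in_year, "patient_id"])
    return of_age & used_services


def detect_conditions(
    diagnoses: pd.DataFrame,
    catalog: ConditionCatalog,
    config: SegmentationConfig,
) -> frozenset[str]:
    """Condition set for one patient's diagnosis records.

    Only records dated within the look-back window (calendar years
    ``index_year - lookback_years + 1`` .. ``index_year``) contribute.
    """
    pids = diagnoses["patient_id"].unique()
    if len(pids) > 1:
        raise ConsistencyError("detect_conditions expects records of a single patient")
    mapped = _conditions_long(diagnoses, catalog, config)
    return frozenset(mapped["condition"])


def _conditions_long(
    diagnoses: pd.DataFrame,
    catalog: ConditionCatalog,
    config: SegmentationConfig,
) -> pd.DataFrame:
    """Map a diagnoses table to unique (patient_id, condition) pairs."""
    year = diagnoses["date"].dt.year
    window = (year >= config.lookback_start_year) & (year <= config.index_year)
    dx = diagnoses.loc[window, ["patient_id", "code", "system"]]
    if dx.empty:
        return pd.DataFrame(columns=["patient_id", "condition"])
    # resolve each distinct (code, system) pair once, then broadcast
    uniq = dx[["code", "system"]].drop_duplicates()
    rows = []
    for code, system in uniq.itertuples(index=False):
        for name in match_code(code, system, catalog):
            rows.append((code, system, name))
    if not rows:
        return pd.DataFrame(columns=["patient_id", "condition"])
    mapping = pd.DataFrame(rows, columns=["code", "system", "condition"])
    long = dx.merge(mapping, on=["code", "system"], how="inner")
    return long[["patient_id", "condition"]].drop_duplicates()


def count_admissions(encounters: pd.DataFrame, year: int) -> int:
    """Merged inpatient-episode count for one patient in a calendar year."""
    pids = encounters["patient_id"].unique()
    if len(pids) > 1:
        raise ConsistencyError("count_admissions expects records of a single patient")
    counts = _admissions_by_patient(encounters, year)
    return int(counts.iloc[0]) if len(counts) else 0


def _admissions_by_patient(encounters: pd.DataFrame, year: int) -> pd.Series:
    """Merged inpatient-episode counts per patient for one calendar year.

    Overlapping or abutting stays (next start <= previous discharge + 1
    day) are merged into a single episode; an episode is attributed to
    the calendar year of its (merged) start date.
    """
    ip = encounters.loc[encounters["modality"] == "inpatient",
                        ["patient_id", "start_date", "end_date"]].copy()
    if ip.empty:
        return pd.Series(dtype=int)
    ip["end_date"] = ip["end_date"].fillna(ip["start_date"])
    ip = ip.sort_values(["patient_id", "start_date", "end_date"], kind="stable")
    grp = ip.groupby("patient_id", sort=False)
    prev_end = grp["end_date"].cummax().shift(1)
    first_of_patient = ~ip["patient_id"].duplicated()
    new_episode = first_of_patient | (
        ip["start_date"] > prev_end + pd.Timedelta(days=1)
    )
    episode_start_in_year = new_episode & (ip["start_date"].dt.year == year)
    return episode_start_in_year.groupby(ip["patient_id"], sort=False).sum().astype(int)


def _segment_predicates(
    has_terminal: np.ndarray,
    has_complex: np.ndarray,
    has_stable: np.ndarray,
    admissions: np.ndarray,
    config: SegmentationConfig,
) -> dict[str, np.ndarray]:
    thr = config.frequent_admission_threshold
    return {
        "end_of_life": has_terminal,
        "complex_freq": has_complex & (admissions >= thr),
        "complex_no_freq": has_complex,
        "serious_acute": admissions >= 1,
        "stable_chronic": has_stable,
        "mostly_healthy": np.ones_like(has_terminal, dtype=bool),
    }


def assign_segment(
    conditions: Iterable[str],
    catalog: ConditionCatalog,
    index_admissions: int,
    config: SegmentationConfig | None = None,
    terminal_flag: bool = False,
) -> tuple[str, str]:
    """Assign one patient; returns ``(segment, rule_fired)``.

    ``conditions`` must all exist in ``catalog`` (otherwise a
    :class:`~popseg.errors.ConsistencyError` is raised).
    """
    config = config or SegmentationConfig()
    conditions = set(conditions)
    unknown = [c for c in conditions if c not in catalog]
    if unknown:
        raise ConsistencyError(f"conditions not in catalog: {sorted(unknown)}")
    cats = {catalog.category_of(c) for c in conditions}
    preds = _segment_predicates(
        np.array([terminal_flag or Category.terminal in cats]),
        np.array([Category.complex in cats]),
        np.array([Category.stable in cats]),
        np.array([index_admissions]),
        config,
    )
    for segment in config.precedence:
        if preds[segment][0]:
            return segment, RULE_LABELS[segment]
    raise AssertionError("unreachable: mostly_healthy predicate is always true")


def segment_cohort(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    encounters: pd.DataFrame,
    catalog: ConditionCatalog,
    config: SegmentationConfig | None = None,
) -> pd.DataFrame:
    """Segment every eligible patient of a cohort.

    Returns one row per eligible patient with columns ``patient_id``,
    ``segment``, ``conditions_found`` (sorted tuple of condition names),
    ``n_conditions``, ``index_year_admissions`` and ``rule_fired``.
    """
    config = config or SegmentationConfig()
    eligible = sorted(filter_eligible(patients, encounters, config))
    if not eligible:
        logger.warning("no eligible patients in cohort")
        return pd.DataFrame(
            columns=["patient_id", "segment", "conditions_found", "n_conditions",
                     "index_year_admissions", "rule_fired"]
        )
    index = pd.Index(eligible, name="patient_id")

    long = _conditions_long(diagnoses, catalog, config)
    long = long[long["patient_id"].isin(index)]
    cond_sets = (
        long.sort_values(["patient_id", "condition"], kind="stable")
        .groupby("patient_id", sort=False)["condition"]
        .agg(tuple)
        .reindex(index)
    )
    cond_sets = cond_sets.apply(lambda v: v if isinstance(v, tuple) else ())

    cat_of = {c.name: c.category for c in catalog}
    flags = pd.DataFrame(index=index, data=False,
                         columns=["stable", "complex", "terminal"])
    if not long.empty:
        long_cat = long["condition"].map(lambda n: cat_of[n].value)
        for cat in ("stable", "complex", "terminal"):
            hit = long.loc[long_cat == cat, "patient_id"].unique()
            flags.loc[flags.index.isin(hit), cat] = True

    admissions = (
        _admissions_by_patient(encounters, config.index_year)
        .reindex(index)
        .fillna(0)
        .astype(int)
    )

    terminal_flag = pd.Series(False, index=index)
    if "terminal_flag" in patients.columns:
        flagged = patients.set_index("patient_id")["terminal_flag"].reindex(index)
        terminal_flag = flagged.fillna(False).astype(bool)

    preds = _segment_predicates(
        (flags["terminal"] | terminal_flag).to_numpy(),
        flags["complex"].to_numpy(),
        flags["stable"].to_numpy(),
        admissions.to_numpy(),
        config,
    )
    order = list(config.precedence)
    segment = np.select([preds[s] for s in order], order, default="")
    rule = np.select([preds[s] for s in order], [RULE_LABELS[s] for s in order],
                     default="")

    out = pd.DataFrame(
        {
            "patient_id": index.to_numpy(),
            "segment": segment,
            "conditions_found": cond_sets.to_numpy(),
            "n_conditions": [len(t) for t in cond_sets],
            "index_year_admissions": admissions.to_numpy(),
            "rule_fired": rule,
        }
    )
    counts = out["segment"].value_counts()
    logger.info(
        "segmented %d patients: %s",
        len(out),
        ", ".join(f"{s}={int(counts.get(s, 0))}" for s in SEGMENTS),
    )
    return out
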