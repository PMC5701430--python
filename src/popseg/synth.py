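"""Synthetic regional-health-system cohort generator with known truth segments.

The generator emits the three EHR tables (patients, diagnoses,
encounters) plus a truth-label table for a population calibrated to the
published segment structure in :mod:`popseg.calibration`.  Each patient
is constructed to satisfy exactly their truth segment's rule and no
higher-precedence rule, so the segmentation engine recovers the truth
labels with probability 1 — the pipeline's primary correctness oracle.

Count model
-----------
Utilization counts (ED visits, specialist-clinic visits, inpatient
admissions per index year) are overdispersed in the calibration targets
(SD > mean for most cells), so counts are drawn from a negative
binomial fitted by the method of moments, ``k = mu^2 / (sd^2 - mu)``,
falling back to Poisson when ``sd^2 <= mu``.  Structural constraints are
enforced by shifting (``at_least(k)``: draw ``k`` plus a
moment-matched residual) or rejection (``at_most(k)``); for rejected
cells the base mean is pre-calibrated so that the *truncated* mean
matches the target.

Structural constraints per truth segment
----------------------------------------
==================  =====================================================
mostly_healthy      no chronic conditions, 0 admissions
serious_acute       no chronic conditions, >= 1 admission
stable_chronic      >= 1 stable condition, no complex/terminal, 0 admissions
complex_no_freq     >= 1 complex condition, <= threshold-1 admissions
complex_freq        >= 1 complex condition, >= threshold admissions
end_of_life         >= 1 terminal condition
==================  =====================================================

Guaranteeing "at least one condition of category R" while preserving
the configured per-condition prevalences is done with an
index-condition construction: one condition of R is drawn from a
categorical with weights ``w_j = p_j / sum(p_R)``, and every other
condition of R is added independently with the residual probability
``r_j = (p_j - w_j) / (1 - w_j)``, which reproduces the marginal
``p_j`` exactly.  This requires ``sum(p_R) >= 1``; rows of the default
prevalence matrix where the defining category's mass falls below 1 are
edited at config-construction time (see :func:`default_generator_config`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

from . import calibration as cal
from .catalog import Category, ConditionCatalog, default_catalog
from .engine import SEGMENTS
from .errors import ConfigurationError

__all__ = [
    "CountConstraint",
    "sample_count",
    "GeneratorConfig",
    "SyntheticCohort",
    "default_generator_config",
    "generate",
]

#: Hard cap on index-year inpatient episodes per patient; keeps the
#: non-overlapping episode layout feasible within one calendar year.
MAX_ADMISSIONS = 36

_ETHNICITIES = ("chinese", "indian", "malay", "other")


class CountConstraint(BaseModel):
    """Structural constraint on a sampled utilization count."""

    model_config = ConfigDict(frozen=True)

    kind: Literal["none", "zero", "at_least", "at_most"] = "none"
    k: int | None = None

    @model_validator(mode="after")
    def _k_required(self) -> "CountConstraint":
        if self.kind in ("at_least", "at_most") and (self.k is None or self.k < 0):
            raise ValueError(f"constraint {self.kind!r} needs a non-negative k")
        return self

    @classmethod
    def none(cls) -> "CountConstraint":
        return cls(kind="none")

    @classmethod
    def zero(cls) -> "CountConstraint":
        return cls(kind="zero")

    @classmethod
    def at_least(cls, k: int) -> "CountConstraint":
        return cls(kind="at_least", k=k)

    @classmethod
    def at_most(cls, k: int) -> "CountConstraint":
        return cls(kind="at_most", k=k)


def _base_draw(mean: float, sd: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Moment-matched negative binomial (Poisson when not overdispersed)."""
    if mean < 0 or sd < 0:
        raise ConfigurationError("count mean and sd must be non-negative")
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    var = sd * sd
    if var > mean:
        k = mean * mean / (var - mean)
        p = k / (k + mean)
        return rng.negative_binomial(k, p, size=size).astype(np.int64)
    return rng.poisson(mean, size=size).astype(np.int64)


def sample_count(
    mean: float,
    sd: float,
    constraint: CountConstraint,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw utilization counts from the moment-matched count model.

    Returns a scalar int when ``size`` is None, else an int array of
    length ``size``.  Raises :class:`~popseg.errors.ConfigurationError`
    for infeasible constraints (e.g. ``at_least(3)`` with mean below 3).
    """
    n = 1 if size is None else int(size)
    if constraint.kind == "zero":
        if mean != 0:
            raise ConfigurationError("constraint 'zero' is infeasible with mean > 0")
        out = np.zeros(n, dtype=np.int64)
    elif constraint.kind == "none":
        out = _base_draw(mean, sd, rng, n)
    elif constraint.kind == "at_least":
        k = int(constraint.k)
        if mean < k:
            raise ConfigurationError(
                f"constraint at_least({k}) is infeasible with mean {mean}"
            )
        out = k + _base_draw(mean - k, sd, rng, n)
    elif constraint.kind == "at_most":
        k = int(constraint.k)
        out = _base_draw(mean, sd, rng, n)
        for _ in range(1000):
            over = out > k
            if not over.any():
                break
            out[over] = _base_draw(mean, sd, rng, int(over.sum()))
        else:
            raise ConfigurationError(
                f"constraint at_most({k}) rejection did not converge (mean {mean})"
            )
    else:  # pragma: no cover - pydantic enforces the literal
        raise ConfigurationError(f"unknown constraint kind {constraint.kind!r}")
    return int(out[0]) if size is None else out


def _truncated_mean(mean: float, sd: float, k_max: int) -> float:
    """Mean of the base count distribution conditioned on X <= k_max."""
    xs = np.arange(k_max + 1)
    var = sd * sd
    if mean == 0:
        return 0.0
    if var > mean:
        k = mean * mean / (var - mean)
        p = k / (k + mean)
        pmf = stats.nbinom.pmf(xs, k, p)
    else:
        pmf = stats.poisson.pmf(xs, mean)
    total = pmf.sum()
    if total <= 0:
        return float(k_max)
    return float((xs * pmf).sum() / total)


def calibrate_truncated_mean(target_mean: float, sd: float, k_max: int) -> float:
    """Base mean whose ``at_most(k_max)``-truncated mean equals ``target_mean``.

    Rejection sampling under ``at_most`` pulls the realized mean below
    the base mean; this inversion lets a truncated cell reproduce its
    calibration target exactly in expectation.
    """
    if target_mean == 0:
        return 0.0
    if target_mean >= k_max:
        raise ConfigurationError(
            f"truncated mean target {target_mean} unreachable with cap {k_max}"
        )

    def gap(mu: float) -> float:
        return _truncated_mean(mu, sd, k_max) - target_mean

    lo, hi = target_mean, target_mean * 2 + 1.0
    for _ in range(60):
        if gap(hi) > 0:
            break
        hi *= 1.5
    else:
        raise ConfigurationError("truncated-mean calibration failed to bracket")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


class GeneratorConfig(BaseModel):
    """Full parameterization of the synthetic cohort generator."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=1)
    seed: int
    index_year: int = 2012
    lookback_years: int = Field(default=5, ge=1)
    segment_proportions: dict[str, float]
    age_group_distributions: dict[str, tuple[float, float, float, float]]
    male_fraction: dict[str, float]
    ethnicity_distribution: dict[str, tuple[float, float, float, float]]
    prevalence_matrix: dict[str, dict[str, float]]
    utilization_params: dict[str, dict[str, tuple[float, float]]]
    admission_constraints: dict[str, CountConstraint]
    mortality_prob: dict[str, float]

    @model_validator(mode="after")
    def _validate(self) -> "GeneratorConfig":
        missing = [s for s in SEGMENTS if s not in self.segment_proportions]
        if missing:
            raise ValueError(f"segment_proportions missing segments {missing}")
        total = sum(self.segment_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment_proportions sum to {total!r}, expected 1")
        for name, mapping in (
            ("segment_proportions", self.segment_proportions),
            ("male_fraction", self.male_fraction),
            ("mortality_prob", self.mortality_prob),
        ):
            for seg, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{seg!r}] = {p} outside [0, 1]")
        for seg, row in self.prevalence_matrix.items():
            for cond, p in row.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"prevalence_matrix[{seg!r}][{cond!r}] = {p} outside [0, 1]"
                    )
        for seg, row in self.utilization_params.items():
            for modality, (m, s) in row.items():
                if m < 0 or s < 0:
                    raise ValueError(
                        f"utilization_params[{seg!r}][{modality!r}] negative"
                    )
        return self


@dataclass
class SyntheticCohort:
    """Generated EHR tables plus the generator's truth labels."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    encounters: pd.DataFrame
    truth_labels: pd.DataFrame
    config: GeneratorConfig


#: Category whose presence each segment's rule requires ("defining category").
_REQUIRED_CATEGORY = {
    "stable_chronic": Category.stable,
    "complex_no_freq": Category.complex,
    "complex_freq": Category.complex,
    "end_of_life": Category.terminal,
}


def default_generator_config(
    n_patients: int,
    seed: int,
    index_year: int = 2012,
    frequent_admission_threshold: int = 3,
    catalog: ConditionCatalog | None = None,
) -> GeneratorConfig:
    """The shipped calibration with its feasibility edits applied.

    Prevalence rows are taken from the published per-segment prevalence
    fractions, then edited so that every truth segment's structural
    constraint is satisfiable while the per-condition marginals the
    generator realizes equal the configured values:

    * healthy and acute segments carry no chronic conditions;
    * the stable-chronic row zeroes complex/terminal conditions (its
      stable mass, about 1.24, already supports the index-condition
      construction unchanged);
    * in the two complex rows the complex-condition mass (0.42 / 0.36)
      cannot support a guaranteed complex condition, so complex
      prevalences are renormalized to a single categorical draw (mass
      exactly 1) and the stable prevalences are scaled so the expected
      condition count still matches the published per-segment mean;
    * in the end-of-life row the sole terminal condition is set to
      prevalence 1 and the remaining prevalences are scaled the same
      way, preserving the published mean condition count.
    """
    catalog = catalog or default_catalog()
    prevalence = cal.prevalence_fractions()
    cat_of = {c.name: c.category for c in catalog}
    mean_conditions = {seg: m for seg, (m, _sd) in cal.MEAN_CONDITIONS.items()}

    matrix: dict[str, dict[str, float]] = {
        "mostly_healthy": {},
        "serious_acute": {},
    }
    for seg in cal.PREVALENCE_SEGMENTS:
        row = dict(prevalence[seg])
        required = _REQUIRED_CATEGORY[seg]
        required_names = [n for n in row if cat_of[n] is required]
        other_names = [n for n in row if cat_of[n] is not required]
        if seg == "stable_chronic":
            for name in other_names:  # complex + terminal zeroed
                row[name] = 0.0
        else:
            req_mass = sum(row[n] for n in required_names)
            if req_mass < 1.0:
                for name in required_names:
                    row[name] = row[name] / req_mass
                req_mass = 1.0
            # drop conditions of higher-precedence categories, then rescale
            # the rest to preserve the published mean condition count
            if required is Category.complex:
                for name in other_names:
                    if cat_of[name] is Category.terminal:
                        row[name] = 0.0
            other_mass = sum(row[n] for n in other_names)
            target_other = mean_conditions[seg] - req_mass
            if other_mass > 0 and target_other >= 0:
                scale = target_other / other_mass
                for name in other_names:
                    row[name] = min(1.0, row[name] * scale)
        matrix[seg] = row

    def _dist(counts: dict[str, tuple]) -> dict[str, tuple[float, float, float, float]]:
        out = {}
        for seg, cs in counts.items():
            total = sum(cs)
            out[seg] = tuple(c / total for c in cs)
        return out

    thr = frequent_admission_threshold
    constraints = {
        "mostly_healthy": CountConstraint.zero(),
        "serious_acute": CountConstraint.at_least(1),
        "stable_chronic": CountConstraint.zero(),
        "complex_no_freq": CountConstraint.at_most(thr - 1),
        "complex_freq": CountConstraint.at_least(thr),
        "end_of_life": CountConstraint.none(),
    }

    return GeneratorConfig(
        n_patients=n_patients,
        seed=seed,
        index_year=index_year,
        segment_proportions=cal.segment_proportions(),
        age_group_distributions=_dist(cal.AGE_GROUP_COUNTS),
        male_fraction={s: cal.MALE_COUNTS[s] / cal.SEGMENT_COUNTS[s]
                       for s in cal.TABLE_ORDER},
        ethnicity_distribution=_dist(cal.ETHNICITY_COUNTS),
        prevalence_matrix=matrix,
        utilization_params={s: dict(cal.UTILIZATION[s]) for s in cal.TABLE_ORDER},
        admission_constraints=constraints,
        mortality_prob=cal.mortality_probs(),
    )


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draw by inverse CDF."""
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="right")


def _sample_conditions(
    rng: np.random.Generator,
    row: dict[str, float],
    required: Category | None,
    catalog: ConditionCatalog,
    n: int,
) -> np.ndarray:
    """Boolean (n x n_conditions) matrix honoring the required-category rule."""
    names = list(catalog.names)
    p = np.array([row.get(name, 0.0) for name in names])
    out = rng.random((n, len(names))) < p[None, :]
    if required is None:
        return out
    req_idx = np.array([i for i, name in enumerate(names)
                        if catalog.category_of(name) is required])
    p_req = p[req_idx]
    mass = p_req.sum()
    if mass < 1.0 - 1e-9:
        raise ConfigurationError(
            f"required-category prevalence mass {mass:.4f} < 1; the "
            f"'at least one {required.value} condition' constraint is unsatisfiable"
        )
    w = p_req / mass
    # index condition: guaranteed membership with exact marginals p_req
    idx = _draw_categorical(rng, w, n)
    residual = np.where(w < 1.0, (p_req - w) / np.where(w < 1.0, 1.0 - w, 1.0), 0.0)
    out[:, req_idx] = rng.random((n, len(req_idx))) < residual[None, :]
    out[np.arange(n), req_idx[idx]] = True
    return out


def _admission_days(rng: np.random.Generator, counts: np.ndarray):
    """Day-of-year layout for inpatient episodes that never merge.

    For a patient with ``c`` episodes the year is cut into ``c`` slots
    of ``365 // c`` days; episode ``i`` starts inside slot ``i`` with a
    jitter of up to ``slot - 4`` days and lasts 1-3 days, which leaves
    at least a 2-day gap between consecutive episodes.
    """
    total = int(counts.sum())
    if total == 0:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([], dtype=np.int64)
    owner = np.repeat(np.arange(len(counts)), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    episode_idx = np.arange(total) - np.repeat(offsets, counts)
    slot_len = 365 // np.repeat(counts, counts)
    jitter = rng.integers(0, np.maximum(slot_len - 4, 1))
    los = rng.integers(0, 3, size=total)  # extra days beyond the first
    start = episode_idx * slot_len + jitter
    end = start + los
    return owner, start, end


def generate(config: GeneratorConfig, catalog: ConditionCatalog | None = None) -> SyntheticCohort:
    """Generate a synthetic cohort; deterministic under (config, seed).

    Every emitted patient is eligible by construction (adult, at least
    one index-year encounter) and satisfies exactly their truth
    segment's rule under the default precedence.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    year = config.index_year
    year_start = np.datetime64(f"{year}-01-01")
    names = list(catalog.names)

    seg_probs = np.array([config.segment_proportions[s] for s in cal.TABLE_ORDER])
    seg_idx = _draw_categorical(rng, seg_probs / seg_probs.sum(), n)
    segments = np.array(cal.TABLE_ORDER, dtype=object)[seg_idx]
    patient_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    ages = np.zeros(n, dtype=np.int64)
    genders = np.empty(n, dtype=object)
    ethnicities = np.empty(n, dtype=object)
    died = np.zeros(n, dtype=bool)
    conditions = np.zeros((n, len(names)), dtype=bool)
    ed_counts = np.zeros(n, dtype=np.int64)
    soc_counts = np.zeros(n, dtype=np.int64)
    adm_counts = np.zeros(n, dtype=np.int64)

    for s, seg in enumerate(cal.TABLE_ORDER):
        mask = seg_idx == s
        m = int(mask.sum())
        if m == 0:
            continue
        band = _draw_categorical(
            rng, np.array(config.age_group_distributions[seg]), m)
        lows = np.array([lo for lo, _hi in cal.AGE_GROUPS])[band]
        highs = np.array([hi for _lo, hi in cal.AGE_GROUPS])[band]
        ages[mask] = rng.integers(lows, highs + 1)
        genders[mask] = np.where(rng.random(m) < config.male_fraction[seg],
                                 "male", "female")
        eth = _draw_categorical(rng, np.array(config.ethnicity_distribution[seg]), m)
        ethnicities[mask] = np.array(_ETHNICITIES, dtype=object)[eth]
        died[mask] = rng.random(m) < config.mortality_prob[seg]

        row = config.prevalence_matrix.get(seg, {})
        conditions[mask] = _sample_conditions(
            rng, row, _REQUIRED_CATEGORY.get(seg), catalog, m)

        util = config.utilization_params[seg]
        ed_counts[mask] = sample_count(*util["ED"], CountConstraint.none(), rng, m)
        soc_counts[mask] = sample_count(
            *util["specialist_clinic"], CountConstraint.none(), rng, m)
        adm_constraint = config.admission_constraints[seg]
        adm_mean, adm_sd = util["inpatient"]
        if adm_constraint.kind == "at_most" and adm_mean > 0:
            adm_mean = calibrate_truncated_mean(adm_mean, adm_sd, adm_constraint.k)
        adm_counts[mask] = sample_count(adm_mean, adm_sd, adm_constraint, rng, m)
    adm_counts = np.minimum(adm_counts, MAX_ADMISSIONS)

    # --- patients table ----------------------------------------------------
    # birth date uniform over the 1-year window yielding the drawn completed
    # age at 1 January of the index year
    birth_dates = (
        np.array([np.datetime64(f"{year - a}-01-01") for a in ages])
        - rng.integers(0, 365, size=n).astype("timedelta64[D]")
    )

    # --- diagnoses table ---------------------------------------------------
    lb_start = np.datetime64(f"{year - config.lookback_years + 1}-01-01")
    lb_days = int((np.datetime64(f"{year + 1}-01-01") - lb_start)
                  / np.timedelta64(1, "D"))
    pat_idx, cond_idx = np.nonzero(conditions)
    n_dx = len(pat_idx)
    dx_codes = np.empty(n_dx, dtype=object)
    dx_systems = np.empty(n_dx, dtype=object)
    system_pref = (("ICD10", 0.60), ("ICD9", 0.25), ("primary_care", 0.15))
    for ci, cond in enumerate(catalog):
        rows = np.flatnonzero(cond_idx == ci)
        if len(rows) == 0:
            continue
        pools = {"ICD10": cond.icd10, "ICD9": cond.icd9,
                 "primary_care": cond.primary_care}
        sys_names = [s for s, _w in system_pref if pools[s]]
        sys_w = np.array([w for s, w in system_pref if pools[s]])
        sys_choice = _draw_categorical(rng, sys_w / sys_w.sum(), len(rows))
        for si, sname in enumerate(sys_names):
            sel = rows[sys_choice == si]
            if len(sel) == 0:
                continue
            pool = np.array(pools[sname], dtype=object)
            dx_codes[sel] = pool[rng.integers(0, len(pool), size=len(sel))]
            dx_systems[sel] = sname
    dx_dates = lb_start + rng.integers(0, lb_days, size=n_dx).astype("timedelta64[D]")

    # --- encounters table --------------------------------------------------
    year_days = int((np.datetime64(f"{year + 1}-01-01") - year_start)
                    / np.timedelta64(1, "D"))

    def _visit_rows(counts: np.ndarray, modality: str):
        owner = np.repeat(np.arange(n), counts)
        days = rng.integers(0, year_days, size=len(owner))
        return owner, np.full(len(owner), modality, dtype=object), days

    ed_owner, ed_mod, ed_days = _visit_rows(ed_counts, "ED")
    soc_owner, soc_mod, soc_days = _visit_rows(soc_counts, "specialist_clinic")
    ip_owner, ip_start, ip_end = _admission_days(rng, adm_counts)

    # primary-care fill-in: everyone must have >= 1 index-year encounter
    no_enc = (ed_counts == 0) & (soc_counts == 0) & (adm_counts == 0)
    pc_owner = np.flatnonzero(no_enc)
    pc_days = rng.integers(0, year_days, size=len(pc_owner))

    enc_owner = np.concatenate([ed_owner, soc_owner, ip_owner, pc_owner])
    enc_modality = np.concatenate([
        ed_mod, soc_mod,
        np.full(len(ip_owner), "inpatient", dtype=object),
        np.full(len(pc_owner), "primary_care", dtype=object),
    ])
    enc_start_days = np.concatenate([ed_days, soc_days, ip_start, pc_days])
    enc_start = year_start + enc_start_days.astype("timedelta64[D]")
    enc_end = np.full(len(enc_owner), np.datetime64("NaT"), dtype="datetime64[D]")
    enc_end[len(ed_owner) + len(soc_owner):
            len(ed_owner) + len(soc_owner) + len(ip_owner)] = (
        year_start + ip_end.astype("timedelta64[D]"))

    encounters = pd.DataFrame(
        {
            "patient_id": patient_ids[enc_owner],
            "modality": enc_modality,
            "start_date": pd.to_datetime(enc_start),
            "end_date": pd.to_datetime(enc_end),
        }
    ).sort_values(["patient_id", "start_date", "modality"], kind="stable")
    encounters = encounters.reset_index(drop=True)

    # --- death dates -------------------------------------------------------
    # uniform within the index year, but never before the last encounter
    death_dates = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
    if died.any():
        draw = year_start + rng.integers(0, year_days, size=int(died.sum())).astype(
            "timedelta64[D]")
        last_enc = (
            encounters.groupby("patient_id", sort=False)["start_date"].max()
        )
        last = last_enc.reindex(patient_ids[died]).to_numpy().astype("datetime64[D]")
        death_dates[died] = np.maximum(draw, last)

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "birth_date": pd.to_datetime(birth_dates),
            "gender": genders,
            "ethnicity": ethnicities,
            "death_date": pd.to_datetime(death_dates),
        }
    ).sort_values("patient_id", kind="stable").reset_index(drop=True)

    diagnoses = pd.DataFrame(
        {
            "patient_id": patient_ids[pat_idx],
            "code": dx_codes,
            "system": dx_systems,
            "date": pd.to_datetime(dx_dates),
        }
    ).sort_values(["patient_id", "code", "date"], kind="stable").reset_index(drop=True)

    truth = pd.DataFrame({"patient_id": patient_ids, "segment": segments})
    truth = truth.sort_values("patient_id", kind="stable").reset_index(drop=True)

    return SyntheticCohort(
        patients=patients,
        diagnoses=diagnoses,
        encounters=encounters,
        truth_labels=truth,
        config=config,
    )
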