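"""Per-segment descriptive profiling and significance tests.

Reproduces the study-style output surface: a demographics table
(headcounts, age bands, gender, ethnicity per segment), an index-year
utilization and mortality table (mean (SD) visit counts per modality,
deaths), and a chronic-disease prevalence table (count and percent per
condition per chronic segment, mean (SD) condition count), each with a
test statistic in the final column — Pearson chi-square for categorical
variables, one-way ANOVA for continuous ones.

Percent cells are computed with :func:`rate_from_counts`, which rounds
half away from zero at a per-cell decimal convention so that printed
rates reproduce published cells exactly from their count pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ConditionCatalog
from .engine import SEGMENTS, SegmentationConfig
from .errors import ConsistencyError

__all__ = [
    "StatTestResult",
    "SegmentProfile",
    "rate_from_counts",
    "chi_square_test",
    "one_way_anova",
    "profile_segments",
    "recovery_report",
    "format_p",
]

#: Segment display order for profile tables.
PROFILE_ORDER = (
    "mostly_healthy",
    "serious_acute",
    "stable_chronic",
    "complex_no_freq",
    "complex_freq",
    "end_of_life",
)

_AGE_BANDS = ((21, 39), (40, 64), (65, 84), (85, 200))
_AGE_LABELS = ("21-39", "40-64", "65-84", ">=85")


def rate_from_counts(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half away from zero.

    Exact decimal arithmetic is used so cells like 769/4705 -> 16 (0 dp)
    and 2540/4705 -> 54.0 (1 dp) reproduce printed values bit-for-bit.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of a chi-square or one-way ANOVA comparison."""

    statistic: float
    df: tuple[int, ...]
    p_value: float


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value the way comparison tables print it (*<0.001* floor)."""
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3g}"


def chi_square_test(contingency) -> StatTestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied; expected counts come from the
    row/column margins and ``df = (r - 1)(c - 1)``.
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (table < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has an all-zero row or column")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatTestResult(statistic=float(chi2), df=(int(dof),), p_value=float(p))


def one_way_anova(*groups) -> StatTestResult:
    """One-way ANOVA across two or more groups of real values.

    Degenerate inputs are reported rather than rejected: zero
    between-group variance gives F = 0, p = 1; zero within-group
    variance with distinct group means gives an infinite statistic with
    p = 0.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and all(
        hasattr(g, "__len__") for g in groups[0]
    ):  # allow a single iterable of groups
        groups = tuple(groups[0])
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need at least two non-empty groups")
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_between, df_within = k - 1, n_total - k
    if df_within < 1:
        raise ValueError("total within-group degrees of freedom must be >= 1")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_between == 0:
        return StatTestResult(0.0, (df_between, df_within), 1.0)
    if ss_within == 0:
        return StatTestResult(float("inf"), (df_between, df_within), 0.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return StatTestResult(float(f), (df_between, df_within), p)


@dataclass
class SegmentProfile:
    """Per-segment descriptive tables plus their comparison tests."""

    demographics: pd.DataFrame
    utilization: pd.DataFrame
    prevalence: pd.DataFrame
    tests: dict[str, StatTestResult] = field(default_factory=dict)
    segment_n: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, outdir) -> None:
        """Write the three tables as tab-separated files plus a test summary."""
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(outdir / "profile_demographics.tsv", sep="\t")
        self.utilization.to_csv(outdir / "profile_utilization.tsv", sep="\t")
        self.prevalence.to_csv(outdir / "profile_prevalence.tsv", sep="\t")
        rows = [
            {
                "variable": name,
                "statistic": res.statistic,
                "df": "/".join(str(d) for d in res.df),
                "p_value": res.p_value,
                "p_printed": format_p(res.p_value),
            }
            for name, res in self.tests.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "profile_tests.tsv", sep="\t", index=False)


def _mean_sd(series_by_segment: dict[str, np.ndarray]) -> dict[str, str]:
    out = {}
    for seg, values in series_by_segment.items():
        if len(values) == 0:
            out[seg] = "-"
            continue
        out[seg] = f"{values.mean():.2f}({values.std(ddof=1) if len(values) > 1 else 0:.2f})"
    return out


def profile_segments(
    assignments: pd.DataFrame,
    patients: pd.DataFrame,
    encounters: pd.DataFrame,
    catalog: ConditionCatalog,
    config: SegmentationConfig | None = None,
) -> SegmentProfile:
    """Build the per-segment descriptive profile of a segmented cohort.

    Utilization columns count index-year encounters only; mortality uses
    a death date falling within the index year.
    """
    config = config or SegmentationConfig()
    if assignments.empty:
        raise ValueError("assignments table is empty")
    pat = patients.set_index("patient_id")
    unknown = set(assignments["patient_id"]) - set(pat.index)
    if unknown:
        raise ConsistencyError(
            f"assignments reference {len(unknown)} unknown patient(s)"
        )
    asg = assignments.set_index("patient_id")
    segments_present = [s for s in PROFILE_ORDER if (asg["segment"] == s).any()]
    seg_n = {s: int((asg["segment"] == s).sum()) for s in PROFILE_ORDER}
    total = len(asg)
    seg_of = asg["segment"]

    tests: dict[str, StatTestResult] = {}

    # -- demographics -------------------------------------------------------
    demo = pat.loc[asg.index]
    age = config.index_year - demo["birth_date"].dt.year - (
        (demo["birth_date"].dt.month > 1)
        | ((demo["birth_date"].dt.month == 1) & (demo["birth_date"].dt.day > 1))
    ).astype(int)
    rows: dict[str, dict[str, object]] = {}
    rows["n"] = {s: seg_n[s] for s in PROFILE_ORDER}
    rows["percent_of_cohort"] = {
        s: rate_from_counts(seg_n[s], total, 1) for s in PROFILE_ORDER
    }
    age_band_counts = {}
    for (lo, hi), label in zip(_AGE_BANDS, _AGE_LABELS):
        in_band = (age >= lo) & (age <= hi)
        counts = {s: int((in_band & (seg_of == s)).sum()) for s in PROFILE_ORDER}
        age_band_counts[label] = counts
        rows[f"age_{label}_n"] = counts
        rows[f"age_{label}_pct"] = {
            s: rate_from_counts(counts[s], seg_n[s], 0) if seg_n[s] else float("nan")
            for s in PROFILE_ORDER
        }
    male = demo["gender"] == "male"
    male_counts = {s: int((male & (seg_of == s)).sum()) for s in PROFILE_ORDER}
    rows["male_n"] = male_counts
    rows["male_pct"] = {
        s: rate_from_counts(male_counts[s], seg_n[s], 0) if seg_n[s] else float("nan")
        for s in PROFILE_ORDER
    }
    eth_counts = {}
    for eth in ("chinese", "indian", "malay", "other"):
        hit = demo["ethnicity"] == eth
        counts = {s: int((hit & (seg_of == s)).sum()) for s in PROFILE_ORDER}
        eth_counts[eth] = counts
        rows[f"ethnicity_{eth}_n"] = counts

    def _maybe_chi2(name: str, table) -> None:
        # skip variables that are degenerate in this cohort (zero margin)
        arr = np.asarray(table)
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            return
        tests[name] = chi_square_test(arr)

    if len(segments_present) >= 2:
        _maybe_chi2("age_band", [[age_band_counts[l][s] for l in _AGE_LABELS]
                                 for s in segments_present])
        _maybe_chi2("gender", [[male_counts[s], seg_n[s] - male_counts[s]]
                               for s in segments_present])
        _maybe_chi2("ethnicity", [[eth_counts[e][s] for e in eth_counts]
                                  for s in segments_present])
        tests["age_years"] = one_way_anova(
            *[age[seg_of == s].to_numpy() for s in segments_present])

    demographics = pd.DataFrame(rows).T[list(PROFILE_ORDER)]

    # -- utilization & mortality -------------------------------------------
    in_year = encounters[encounters["start_date"].dt.year == config.index_year]
    util_rows: dict[str, dict[str, object]] = {}
    per_patient: dict[str, dict[str, np.ndarray]] = {}
    from .engine import _admissions_by_patient

    modal_counts = {
        "ed_visits": in_year[in_year["modality"] == "ED"]
        .groupby("patient_id").size(),
        "specialist_visits": in_year[in_year["modality"] == "specialist_clinic"]
        .groupby("patient_id").size(),
        "admissions": _admissions_by_patient(encounters, config.index_year),
    }
    for name, counts in modal_counts.items():
        filled = counts.reindex(asg.index).fillna(0).astype(float)
        per_patient[name] = {
            s: filled[seg_of == s].to_numpy() for s in PROFILE_ORDER
        }
        util_rows[f"{name}_mean_sd"] = _mean_sd(per_patient[name])
        if len(segments_present) >= 2:
            tests[name] = one_way_anova(
                *[per_patient[name][s] for s in segments_present])

    deaths = demo["death_date"].dt.year == config.index_year
    death_counts = {s: int((deaths & (seg_of == s)).sum()) for s in PROFILE_ORDER}
    util_rows["mortality_n"] = death_counts
    util_rows["mortality_pct"] = {
        s: rate_from_counts(death_counts[s], seg_n[s], 1) if seg_n[s] else float("nan")
        for s in PROFILE_ORDER
    }
    if len(segments_present) >= 2:
        _maybe_chi2("mortality",
                    [[death_counts[s], seg_n[s] - death_counts[s]]
                     for s in segments_present])
    utilization = pd.DataFrame(util_rows).T[list(PROFILE_ORDER)]

    # -- chronic-disease prevalence ----------------------------------------
    n_cond = asg["n_conditions"].astype(float)
    prev_rows: dict[str, dict[str, object]] = {}
    prev_rows["n_conditions_mean_sd"] = _mean_sd(
        {s: n_cond[seg_of == s].to_numpy() for s in PROFILE_ORDER}
    )
    # per-condition prevalence needs the in-memory conditions_found column;
    # a round-tripped assignments file only carries n_conditions
    if "conditions_found" in asg.columns:
        cond_sets = asg["conditions_found"]
        exploded = cond_sets[cond_sets.apply(len) > 0].explode()
        for cond in catalog.names:
            hit_ids = exploded.index[exploded == cond]
            counts = {
                s: int((seg_of.loc[hit_ids] == s).sum()) for s in PROFILE_ORDER
            }
            prev_rows[f"{cond}_n"] = counts
            prev_rows[f"{cond}_pct"] = {
                s: rate_from_counts(counts[s], seg_n[s], 1)
                if seg_n[s] else float("nan")
                for s in PROFILE_ORDER
            }
    prevalence = pd.DataFrame(prev_rows).T[list(PROFILE_ORDER)]
    if len(segments_present) >= 2:
        tests["n_conditions"] = one_way_anova(
            *[n_cond[seg_of == s].to_numpy() for s in segments_present])

    return SegmentProfile(
        demographics=demographics,
        utilization=utilization,
        prevalence=prevalence,
        tests=tests,
        segment_n=seg_n,
    )


def recovery_report(
    truth_labels: pd.DataFrame, assignments: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (truth rows x assigned columns) and overall accuracy."""
    truth = truth_labels.set_index("patient_id")["segment"]
    assigned = assignments.set_index("patient_id")["segment"]
    if set(truth.index) != set(assigned.index):
        raise ConsistencyError("truth and assignment patient-id sets differ")
    assigned = assigned.reindex(truth.index)
    matrix = pd.crosstab(truth, assigned, dropna=False).reindex(
        index=list(PROFILE_ORDER), columns=list(PROFILE_ORDER), fill_value=0
    )
    matrix.index.name = "truth"
    matrix.columns.name = "assigned"
    accuracy = float(np.trace(matrix.to_numpy()) / matrix.to_numpy().sum())
    return matrix, accuracy
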