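# Methods

## The segmentation model

The package implements an expert-defined, rule-based segmentation of an
adult service-using population into six mutually exclusive segments.
The unit of analysis is the patient-index-year: a patient enters the
cohort if they are at least `min_age` (default 21) completed years old
at 1 January of the index year and have at least one encounter of any
modality (inpatient, ED, specialist clinic, primary care) starting in
that year. A fixed reference date makes eligibility deterministic and
matches the calendar-year cohort definition.

Chronic disease burden is measured over a look-back window of
`lookback_years` calendar years ending with the index year (default 5,
i.e. 2008–2012 for index year 2012). "Five years back" is ambiguous
about inclusivity; the calendar-year-aligned reading was chosen because
the cohort itself is calendar-year defined. Each diagnosis record in
the window is resolved against the condition catalog: ICD codes by
normalized prefix match (uppercase, periods stripped), primary-care
codes by case-insensitive label equality. A patient's condition set is
the union over records; repeat codings carry no extra information.

Admissions are counted as merged inpatient episodes: records whose date
ranges overlap, or where the next admission starts no later than one
day after the previous discharge, are one episode (inter-hospital
transfers within a regional system would otherwise double-count). An
episode belongs to the calendar year of its merged start date. The
frequent-admitter threshold is ≥ 3 episodes in the index year. The
threshold window is the index year itself rather than the year before:
in the calibration tables the frequent-admitter segment's *prior-year*
mean admissions (1.71) is below the threshold while its index-year mean
(4.33) has every member at ≥ 3, which is only consistent with an
index-year window.

Assignment applies the first matching rule in precedence order:
terminal condition → `end_of_life`; complex condition + threshold
admissions → `complex_freq`; complex condition → `complex_no_freq`;
any admission → `serious_acute`; stable condition → `stable_chronic`;
otherwise `mostly_healthy`. The source framework does not state its
tie-breaking explicitly; this order is the unique one under which the
healthy and stable-chronic segments show exactly zero index-year
admissions, as the calibration tables require. It is configurable, as
is whether ED-only contact should count toward `serious_acute` (it does
not by default — only admissions fire rule 4).

## The condition catalog

The default catalog holds 34 chronic conditions: the chronic-disease
roster of the Singapore Chronic Disease Management Program merged with
Charlson and Elixhauser comorbidities, with ICD-9/ICD-10 prefixes
adapted from the published Quan et al. administrative-code mappings.
Primary-care codes are modeled as verbatim condition labels because no
public polyclinic coding scheme exists.

The stable/complex split is a heuristic reconstruction: conditions with
zero printed prevalence in the stable-chronic column of the calibration
prevalence table (diabetes with chronic complications, non-metastatic
malignancy, atrial fibrillation, moderate/severe liver disease,
thromboembolism) are complex-defining; metastatic disease is terminal;
everything else is stable. The calibration table shows small non-zero
stable-segment prevalence for some intuitively severe conditions (heart
failure 0.5 %, CKD5/ESRF 0.5 %, stroke 2.7 %), so the original expert
classification cannot be fully recovered; for this reason every
category in the catalog file is user-overridable, and the patients
table accepts an optional per-patient `terminal_flag` column for
end-of-life criteria that are not condition-derivable.

Within each code system no condition's pattern is a prefix of another
condition's pattern, so a code emitted from one condition's pattern
list maps back to exactly that condition (tested exhaustively).

## The synthetic-cohort generator

The generator emulates the cross-sectional statistical structure of an
adult regional-health-system population (index year 2012): per-segment
headcount shares (61.3 / 5.3 / 21.5 / 11.0 / 0.6 / 0.4 %, stored as
exact count ratios), age-band, gender and ethnicity multinomials,
index-year utilization count distributions per modality, one-year
mortality, and per-condition prevalence. Each patient draws a truth
segment first; everything else is conditional on it.

**Count model.** Utilization cells are overdispersed (SD > mean almost
everywhere), so counts follow a negative binomial fitted by moments
(`k = μ²/(σ²−μ)`), with a Poisson fallback when `σ² ≤ μ`. Structural
constraints per truth segment (0 admissions for healthy/stable; ≥ 1 for
serious-acute; ≤ 2 for complex without frequent admissions; ≥ 3 for
frequent admitters) are enforced by shifting — `at_least(k)` draws `k`
plus a moment-matched residual, which preserves the target mean exactly
— or by rejection for `at_most(k)`. Rejection truncation pulls the
realized mean below the configured one, so for truncated cells the base
mean is first inverted numerically (Brent root-finding on the truncated
mean) so that the realized mean still equals the target. Admission
counts are capped at 36 per year to keep the episode layout feasible;
the expected mean loss from the cap is < 0.001 %.

**Episode layout.** A patient with `c` admissions has the year cut into
`c` equal slots; each episode starts inside its own slot with jitter
and lasts 1–3 days, leaving at least a two-day gap between consecutive
episodes, so the engine's episode merge never collapses two generated
admissions and the merged count equals the drawn count with
probability 1.

**Prevalence sampling and feasibility edits.** Condition sets are drawn
per patient from a per-segment Bernoulli row, with the segment-defining
category guaranteed by an index-condition construction: one condition
of the required category is drawn from a categorical with weights
`w_j = p_j / Σp`, and the others of that category are added with
residual probability `r_j = (p_j − w_j)/(1 − w_j)`, which reproduces
the marginal `p_j` exactly. This requires the category's prevalence
mass `Σp ≥ 1`; the generator refuses configurations where it is not.
The default matrix therefore carries three edits relative to the raw
published fractions:

* the stable-chronic row zeroes complex/terminal conditions; its stable
  mass (≈ 1.24) already satisfies the construction, so stable
  prevalences are used unedited;
* in the two complex rows the complex-condition mass is only 0.42 /
  0.36, which cannot guarantee a complex condition, so complex
  prevalences are renormalized to a single categorical draw (mass
  exactly 1) and stable prevalences are scaled so the expected
  condition count equals the published segment mean (2.4 and 3.5);
* in the end-of-life row the sole terminal condition (metastatic
  disease) gets prevalence 1 — the published 39 % implies terminal
  criteria beyond metastatic disease that are not recoverable — and the
  remaining prevalences are scaled to preserve the published mean count
  (1.6).

A consequence worth stating plainly: the published stable-chronic
column is internally inconsistent — its prevalences sum to ≈ 1.24
conditions per patient while the printed mean count is 2.4, which no
dependence structure can reconcile (the mean of a sum is the sum of the
marginals). The generator preserves the prevalences, so its
stable-segment mean condition count is ≈ 1.24, not 2.4. The same
applies proportionally wherever the edits above trade marginal fidelity
for mean-count fidelity (complex and end-of-life rows) or vice versa.

**Other choices.** Ages are drawn by age band then uniformly within the
band (≥ 85 capped at 100), with the birth date uniform over the 1-year
window consistent with the drawn completed age at the reference date.
Diagnosis dates are uniform over the look-back window, one record per
condition. Deaths occur within the index year with the segment's
mortality probability; the death date is drawn uniformly and floored at
the patient's last encounter date. Patients who would otherwise have no
index-year encounter receive one primary-care visit, so 100 % of
generated patients are eligible. The whole generator is vectorized and
deterministic under `(config, seed)`; generating and segmenting 200,000
patients takes a few seconds.

**What passing tests do and do not show.** The generator has no
correlation structure between conditions beyond segment conditioning,
no longitudinal progression (no prior-year utilization, no multi-year
outcomes), no household or geographic structure, and clean,
well-formed records. Round-trip recovery therefore validates the
pipeline's logic — windowing, matching, merging, precedence — not its
robustness to the coding noise, linkage errors and cross-system
utilization of real EHR data (the readers' lenient mode and row
reports exist for that, but are exercised only on synthetic dirt).

## Profiling and statistics

The profiler reproduces the study-style output surface: demographics,
index-year utilization/mortality, and condition prevalence per segment,
with Pearson chi-square tests (no continuity correction) for
categorical variables and one-way ANOVA for continuous ones; p-values
below 0.001 print as `<0.001` but are stored at full precision.
Percent cells are rounded half away from zero at per-table decimal
conventions, using exact decimal arithmetic so printed rates reproduce
published cells bit-for-bit from their count pairs. Degenerate ANOVA
inputs are reported rather than rejected (all-identical values → F = 0,
p = 1; zero within-group variance with distinct means → F = ∞, p = 0);
chi-square tables with a zero margin are skipped in bulk profiles and
rejected in direct calls. Prior-year ("past utilization") columns are
out of the profiler's scope because the generator does not emit
prior-year encounters.

## Problem sizes and tolerances in the test suite

Unit and property tests run on hand-built cohorts of 5–10 patients and
generated cohorts of 800–5,000. Generator calibration is checked on a
50,000-patient cohort (every per-segment utilization mean, mortality
rate and condition prevalence within 3 Monte-Carlo standard errors of
its configured value), and the pipeline-level checks use one
200,000-patient cohort: exact truth-label recovery, the partition
property, and the five headline statistics within 3 MC standard errors
(segment share within 0.5 percentage points; mean condition count
within 5 %). At that size the frequent-admitter segment holds ≈ 1,140
patients, so a 3-SE band on its mean admissions is ≈ ±0.19 around 4.33.

## Known limitations

* The stable/complex classification is a reconstruction (see above);
  users with access to the original expert table should supply it as a
  custom catalog.
* Primary-care code matching is exact-label only.
* The published segment-level mean age (55.6 ± 9.8) is inconsistent
  with the published age-band frequencies (32 % aged 21–39); the
  generator calibrates to the bands and makes no attempt to match the
  printed mean.
* Diagnosis dates are not constrained to precede death, and death
  competing with utilization within the index year is not modeled.
* No ICD-9↔ICD-10 equivalence mapping, SNOMED, severity weighting,
  risk prediction, cost attribution or multi-year outcome follow-up.
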