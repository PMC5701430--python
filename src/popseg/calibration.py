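"""Published calibration surface for the default synthetic-cohort generator.

The constants below describe the segment structure of an adult regional
health system population in Singapore (index year 2012, cohort of
825,874 service users): per-segment headcounts, demographics
(age-group, gender, ethnicity), index-year healthcare utilization
(count means and standard deviations per patient), one-year mortality,
and per-segment chronic-disease prevalence counts for the built-in
34-condition catalog.  They are the *targets* the default generator is
calibrated to; the generator itself lives in :mod:`popseg.synth`.

All cells are stored as raw counts where the source reports counts so
that derived proportions are exact (printed percentages are rounded).
"""

from __future__ import annotations

#: Segment keys in cohort-table order (not precedence order).
TABLE_ORDER = (
    "mostly_healthy",
    "serious_acute",
    "stable_chronic",
    "complex_no_freq",
    "complex_freq",
    "end_of_life",
)

COHORT_TOTAL = 825_874

SEGMENT_COUNTS = {
    "mostly_healthy": 506_101,
    "serious_acute": 44_023,
    "stable_chronic": 177_550,
    "complex_no_freq": 90_540,
    "complex_freq": 4_705,
    "end_of_life": 2_955,
}

#: Age bands used for demographic calibration: [low, high] completed years.
AGE_GROUPS = ((21, 39), (40, 64), (65, 84), (85, 100))

#: Patients per age band, by segment (same band order as AGE_GROUPS).
AGE_GROUP_COUNTS = {
    "mostly_healthy": (217_648, 230_499, 54_890, 3_064),
    "serious_acute": (23_898, 15_011, 4_646, 468),
    "stable_chronic": (10_873, 92_032, 68_607, 6_038),
    "complex_no_freq": (8_217, 43_387, 35_063, 3_873),
    "complex_freq": (279, 1_955, 2_157, 314),
    "end_of_life": (180, 1_712, 991, 72),
}

MALE_COUNTS = {
    "mostly_healthy": 209_969,
    "serious_acute": 12_620,
    "stable_chronic": 79_196,
    "complex_no_freq": 42_186,
    "complex_freq": 2_447,
    "end_of_life": 1_286,
}

#: (chinese, indian, malay, other) headcounts per segment.
ETHNICITY_COUNTS = {
    "mostly_healthy": (346_461, 45_406, 50_589, 63_645),
    "serious_acute": (25_617, 5_121, 7_022, 6_263),
    "stable_chronic": (137_299, 12_286, 21_226, 6_739),
    "complex_no_freq": (69_173, 7_248, 9_152, 4_967),
    "complex_freq": (3_415, 469, 614, 207),
    "end_of_life": (2_324, 127, 239, 265),
}

#: Index-year utilization per patient: (mean, sd) of visit counts by modality.
UTILIZATION = {
    "mostly_healthy": {"ED": (0.11, 0.38), "specialist_clinic": (2.42, 3.67),
                       "inpatient": (0.0, 0.0)},
    "serious_acute": {"ED": (0.56, 0.95), "specialist_clinic": (8.20, 7.25),
                      "inpatient": (1.18, 0.51)},
    "stable_chronic": {"ED": (0.05, 0.31), "specialist_clinic": (2.04, 4.34),
                       "inpatient": (0.0, 0.0)},
    "complex_no_freq": {"ED": (0.44, 0.94), "specialist_clinic": (8.52, 11.09),
                        "inpatient": (0.44, 0.72)},
    "complex_freq": {"ED": (3.21, 3.16), "specialist_clinic": (24.30, 19.54),
                     "inpatient": (4.33, 2.12)},
    "end_of_life": {"ED": (0.96, 1.36), "specialist_clinic": (27.48, 23.68),
                    "inpatient": (1.50, 1.63)},
}

#: Deaths within the index year, by segment.
MORTALITY_COUNTS = {
    "mostly_healthy": 666,
    "serious_acute": 266,
    "stable_chronic": 286,
    "complex_no_freq": 2_903,
    "complex_freq": 769,
    "end_of_life": 982,
}

#: Mean (sd) number of chronic conditions per patient in the four
#: chronic-disease segments.
MEAN_CONDITIONS = {
    "stable_chronic": (2.4, 1.3),
    "complex_no_freq": (2.4, 2.0),
    "complex_freq": (3.5, 2.9),
    "end_of_life": (1.6, 1.6),
}

#: Chronic-disease prevalence headcounts per segment, keyed by the
#: condition names of the default catalog.  Tuple order:
#: (stable_chronic, complex_no_freq, complex_freq, end_of_life).
PREVALENCE_SEGMENTS = ("stable_chronic", "complex_no_freq", "complex_freq",
                       "end_of_life")

PREVALENCE_COUNTS = {
    "diabetes_without_complication": (30_823, 23_506, 1_622, 178),
    "hypertension": (62_413, 39_054, 2_540, 433),
    "ckd_without_esrf": (4_954, 6_674, 1_341, 42),
    "asthma": (7_041, 3_697, 246, 34),
    "hyperlipidemia": (59_426, 34_951, 1_885, 219),
    "osteoarthritis": (22_367, 10_966, 619, 98),
    "osteoporosis": (452, 208, 2, 2),
    "benign_prostatic_hypertrophy": (1_265, 687, 28, 3),
    "copd_without_cor_pulmonale": (3_084, 4_154, 453, 72),
    "hyperthyroidism": (1_720, 422, 14, 2),
    "hypothyroidism": (2_915, 1_076, 45, 1),
    "diabetes_with_complications": (0, 8_935, 450, 12),
    "stroke": (4_737, 8_207, 680, 67),
    "ckd5_or_esrf": (950, 3_600, 1_241, 40),
    "copd_with_cor_pulmonale": (2_169, 3_763, 441, 72),
    "major_depression": (1_302, 5_398, 212, 22),
    "schizophrenia": (273, 959, 50, 7),
    "dementia": (331, 671, 65, 4),
    "bipolar_disorder": (2, 7, 0, 0),
    "collagen_vascular_disease": (107, 1_412, 128, 15),
    "anxiety": (693, 2_616, 53, 6),
    "parkinsons_disease": (282, 841, 62, 7),
    "epilepsy": (289, 1_801, 108, 16),
    "coronary_heart_disease": (10_159, 19_562, 1_513, 122),
    "atrial_fibrillation": (0, 718, 91, 2),
    "hip_fracture": (20, 12, 2, 0),
    "spine_fracture": (185, 827, 77, 8),
    "liver_disease_moderate_severe": (0, 2_843, 245, 34),
    "malignancy_non_metastatic": (0, 25_630, 885, 1_915),
    "thromboembolism": (0, 42, 12, 3),
    "pressure_ulcer": (10, 166, 29, 2),
    "heart_failure": (936, 4_880, 811, 40),
    "peripheral_vascular_disease": (655, 3_223, 372, 25),
    "metastatic_disease": (6, 181, 16, 1_151),
}


def segment_proportions() -> dict[str, float]:
    """Exact segment shares derived from the published headcounts."""
    return {s: SEGMENT_COUNTS[s] / COHORT_TOTAL for s in TABLE_ORDER}


def mortality_probs() -> dict[str, float]:
    return {s: MORTALITY_COUNTS[s] / SEGMENT_COUNTS[s] for s in TABLE_ORDER}


def prevalence_fractions() -> dict[str, dict[str, float]]:
    """Raw per-segment prevalence fractions (before feasibility edits)."""
    out: dict[str, dict[str, float]] = {s: {} for s in PREVALENCE_SEGMENTS}
    for cond, counts in PREVALENCE_COUNTS.items():
        for seg, n in zip(PREVALENCE_SEGMENTS, counts):
            out[seg][cond] = n / SEGMENT_COUNTS[seg]
    return out
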