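# popseg

Rule-based population segmentation of longitudinal electronic health
record (EHR) extracts, for health-services researchers and regional
health systems that need to split an entire adult service-using
population into a small number of mutually exclusive, clinically
meaningful segments for integrated-care and resource planning.

## The segmentation framework

Every adult (≥ 21 years) with at least one healthcare encounter in an
index calendar year is assigned to exactly one of six segments. Chronic
conditions are detected by scanning ICD-9, ICD-10 and primary-care
diagnosis codes over a five-calendar-year look-back window (index year
inclusive) against a 34-condition catalog in which each condition is
classed *stable*, *complex* or *terminal*. Inpatient records are merged
into admission episodes (overlapping or abutting stays count once), and
a patient is a **frequent hospital admitter** when they have ≥ 3 merged
admissions in the index year. The first matching rule in precedence
order wins:

| precedence | segment | rule |
|---|---|---|
| 1 | `end_of_life` | any terminal condition (metastatic disease by default) |
| 2 | `complex_freq` | any complex condition **and** ≥ 3 index-year admissions |
| 3 | `complex_no_freq` | any complex condition |
| 4 | `serious_acute` | ≥ 1 index-year admission |
| 5 | `stable_chronic` | any stable condition |
| 6 | `mostly_healthy` | everything else |

The look-back length, admission threshold, minimum age, index year and
precedence order are all configurable (`SegmentationConfig`), and the
condition catalog — including every stable/complex/terminal class — can
be replaced by a user file.

Because real EHR extracts of this kind cannot be shipped, the package
includes a calibrated synthetic-cohort generator (`popseg.synth`) whose
defaults reproduce the segment shares, demographics, per-segment
utilization count distributions, mortality and condition prevalence of
a published adult regional-health-system population (Singapore, index
year 2012, 825,874 patients). Each synthetic patient is constructed to
satisfy exactly their truth segment's rule, so running the segmenter on
a generated cohort must recover 100 % of truth labels — the pipeline's
primary correctness oracle.

## Worked example

```sh
popseg --quiet generate --n 5000 --seed 7 --outdir cohort/
popseg --quiet segment  --inputs cohort/ --out assignments.csv
popseg --quiet profile  --assignments assignments.csv --inputs cohort/ --outdir profile/
popseg --quiet validate --assignments assignments.csv --truth cohort/truth_labels.csv
```

The last command prints

```
accuracy 1.000000 on 5000 patients
```

i.e. the segmenter reproduced every truth label. `assignments.csv`
carries the evidence behind each assignment:

```
patient_id,segment,n_conditions,index_year_admissions,rule_fired
P0000000,serious_acute,0,1,index_year_admission
P0000001,complex_no_freq,4,1,complex_condition
```

`profile/profile_utilization.tsv` is the per-segment utilization and
mortality table (mean (SD) visits per patient in the index year):

```
                        mostly_healthy  serious_acute  stable_chronic  complex_no_freq  complex_freq  end_of_life
ed_visits_mean_sd       0.10(0.36)      0.56(0.98)     0.04(0.26)      0.40(0.87)       2.96(3.47)    0.62(0.89)
specialist_visits_...   2.47(3.65)      7.78(6.42)     1.90(3.95)      9.32(11.66)      27.00(17.85)  30.94(25.04)
admissions_mean_sd      0.00(0.00)      1.16(0.53)     0.00(0.00)      0.42(0.62)       4.22(1.69)    1.00(2.03)
mortality_n             6               1              1               21               3             6
mortality_pct           0.2             0.4            0.1             3.8              11.1          37.5
```

Even at n = 5000 the structure of the calibration shows through: the
frequent-admitter segment is ~0.5 % of the cohort but has by far the
highest admission and ED burden, while the end-of-life segment has the
highest specialist-clinic use and mortality. At n = 200,000 these
statistics converge on the calibration targets (mean admissions 4.33,
mean ED visits 3.21, specialist visits 27.48, mostly-healthy share
61.3 %, mean condition count 3.5 in the respective segments).

The same pipeline runs on real extracts: point `popseg segment` at any
directory containing `patients.csv`, `diagnoses.csv` and
`encounters.csv` in the documented schemas (see `popseg/io.py`).

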