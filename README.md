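# hfpheno

Rule-based e-phenotyping of **acute heart failure** (including acute
exacerbation of chronic heart failure) from multi-source Japanese hospital
data, with the statistical machinery to validate each identification
algorithm against physician chart review.

The package is aimed at pharmacoepidemiologists and medical informaticians
who work with hospital-information-system extracts standardized across
three sources — SS-MIX2 electronic medical records, DPC case-mix data and
health-insurance claims — and who need case-identification algorithms with
quantified positive predictive value (PPV) and sensitivity before using
them in drug-safety studies.

## What it implements

**Conditions.** Twenty-one atomic conditions ground the algorithms: six
disease-code conditions (ICD-10 heart-failure codes, varying by source and
DPC diagnosis field, one requiring an inpatient stay ≥ 3 days), eight
drug-class exposures (carperitide, catecholamines/pimobendan, diuretic
classes, tolvaptan, PDE inhibitors, digitalis), six natriuretic-peptide
thresholds (BNP at 100/400 pg/ml, NT-proBNP at 400/3,000 pg/ml) and
transthoracic echocardiography.

**Screen and algorithms.** The *All Possible Cases* (APC) screen — an HF
diagnosis in any source plus BNP ≥ 100 or NT-proBNP ≥ 400 pg/ml within ±30
days of the first diagnosis date — defines the target population, assumed
to capture every true case. Eighteen algorithms, each a disjunction of
branches of condition groups evaluated in a symmetric ±7/±14/±30-day window
around the index date (the first qualifying diagnosis date), are run on a
random per-hospital sample of the screened population.

**Validation.** Chart-review categories (True case A/B, Suspected, Other)
come from three judgements (Framingham criteria; comprehensive clinical
assessment; treatment for acute HF). For each algorithm,

    PPV         = TP / (TP + FP)
    Sensitivity = TP / (TP + FN)   (denominator: adjudicated true cases in
                                    the screened sample, APC sensitivity
                                    taken as 100%)

with Clopper–Pearson exact 95% intervals, under a primary analysis
(Suspected counted as not true) and a sensitivity analysis (Suspected
counted as true). Inter-reviewer agreement is the Fleiss–Cohen
(quadratic-weight) kappa over the ordered categories.

**Synthetic cohort.** Real records cannot be redistributed, so a seeded
generator draws patients from archetype mixtures (acute HF,
acute-on-chronic HF, stable chronic HF, renal failure with high BNP,
cardiac-function screening, respiratory disease, stable arrhythmia,
postoperative circulatory failure) with latent review categories, emulating
both the true cases and the documented false-positive mechanisms.

## Worked example

```
$ hfpheno simulate --n 1000 --seed 7 --out cohort
wrote 1000 patients across 3 hospitals to cohort

$ hfpheno identify --records cohort --seed 11 --min-per-hospital 100 --out matches.csv
APC matched 868/1000 patients; sampled 300 cases; wrote matches.csv

$ hfpheno validate --matches matches.csv --adjudications cohort/adjudications.csv \
      --mode primary --out report.csv
wrote 19 validity rows to report.csv

$ hfpheno kappa --adjudications cohort/adjudications.csv
weighted kappa 0.98 (SE 0.0029, 95% CI 0.97-0.98, n=1000)
```

The first rows of `report.csv`:

```
algorithm  possible_cases  tp  fp  fn   ppv  ppv_low  ppv_high  sensitivity  sensitivity_low  sensitivity_high
      APC             300  78 222   0 26.00    21.13     31.35       100.00
     ALG1             120  64  56  14 53.33    44.01     62.49        82.05            71.72             89.83
     ALG2             146  75  71   3 51.37    42.97     59.72        96.15            89.17             99.20
```

Reading: of the 1,000 simulated patients, 868 pass the APC screen and 100
per hospital are sampled for review. 78 of the 300 sampled cases (26.00%)
are adjudicated true — the screen's PPV. Algorithm 1 flags 120 of the
sampled cases ("possible cases"), of which 64 are true, giving PPV 53.33%
(95% CI 44.01–62.49) and sensitivity 64/78 = 82.05% against the sampled
true cases. The APC row's sensitivity is 100% by design (it anchors the
denominator). On synthetic data these numbers characterize the simulator's
archetype mixture, not any real population.

The same analyses are available as library calls (`generate_cohort`,
`run_panel`, `report_tables`, `weighted_kappa`); see the module docstrings
and `docs/methods.md`.

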