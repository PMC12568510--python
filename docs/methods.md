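# Methods

## Data model

Records are modelled per source as they appear in standardized Japanese
hospital extracts. Diagnoses carry an ICD-10 code and one date: the
admission date for DPC records (whichever of the six DPC fields the
diagnosis occupies, including complications arising during the stay) and
the start date for SS-MIX2 and claims records. SS-MIX2 diagnoses carry the
suspected-diagnosis modifier as a boolean; claims diagnoses carry no
suspected semantics here, so the claims disease condition includes them
regardless. Laboratory conditions are defined on SS-MIX2 only, so lab
records have no source column. Procedure records exist only in DPC and
claims.

Record tables are four comma-separated UTF-8 files with fixed headers and
ISO-8601 dates (`diagnoses.csv`, `drugs.csv`, `labs.csv`,
`procedures.csv`). `diagnoses.csv` is mandatory; an absent drug, lab or
procedure table is read as empty. One *case* is one (hospital, patient)
pair — a patient is counted once per hospital within the study period.

**Code sets are configuration, not knowledge shipped by the package.** The
exact disease, drug and procedure code catalogues used in the original
validation are institutional and not redistributable, so every condition is
grounded in a `CodeSetConfig` (YAML-loadable). Matching is by code prefix
throughout — the standard dialect for ICD-10 families (`I50` covers
`I500`, `I501`, …) — and the same rule serves ATC-style drug-class
prefixes. The shipped defaults (`default_codeset()`) are documented
placeholders: ICD-10 `{I110, I130, I132, I50*}` for heart failure,
ATC-style classes for the eight drug groups, a single echo procedure code.
Config validation enforces that loop and potassium-sparing diuretic codes
are covered by the general diuretics class, which is what forces a loop
diuretic record to satisfy both drug conditions.

## Condition semantics

Natriuretic-peptide bands: "at least X" is a closed lower bound;
"between X and Y" is the half-open interval [X, Y). This makes
{moderate band, high band} an exact partition of the at-or-above-lower-
threshold band for each analyte (BNP 100/400, NT-proBNP 400/3,000 pg/ml),
so the two-branch algorithm structure covers each measurement exactly
once; boundary ownership is otherwise arbitrary and is asserted by
property tests.

Length of stay counts both admission and discharge days
(stay = discharge − admission + 1, the Japanese hospital-day convention),
so a two-night admission has a three-day stay and satisfies the ≥ 3-day
disease condition. A DPC record without a discharge date conservatively
never satisfies that condition.

## Algorithm evaluation

An algorithm is a disjunction of branches; a branch is a conjunction of
condition groups; a group is satisfied by at least one event of any member
condition inside the window. The "[Drug 4 and 5]" conjunction is encoded
as two singleton groups. Evaluation:

1. The index date is fixed first: the earliest event date over the
   algorithm's disease conditions, independent of which branch later
   matches. A later disease event is never promoted to index even when it
   would bring more conditions in-window.
2. Windows are closed day-granular intervals [index − w, index + w] with
   w ∈ {7, 14, 30}. Conditions in a branch may be satisfied on different
   dates, each independently in-window.
3. Branches are tried in their printed order; the reported evidence is the
   earliest in-window event per group of the first satisfied branch.
   Matching itself is order-independent.

The APC screen's definition names disease conditions 1, 3 or 5 but anchors
its index on the first diagnosis date of conditions 1–3. A patient whose
only HF diagnosis is in claims therefore has no literal index; the engine
falls back to the earliest claims diagnosis date and flags the result
(`index_fallback_used`). This fallback is this package's documented
choice, not part of the published definition.

Study-period clipping is left to the caller: the engine evaluates whatever
history it is given. Sampling of the study population is uniform without
replacement within each hospital (a hospital at or below the minimum
contributes all its matches), driven by a required seed.

## Validity statistics

Confusion counts are assembled within the sampled screened population:
TP = matched ∧ adjudicated true, FP = matched ∧ not true, FN = not matched
∧ true. The sensitivity denominator TP + FN is the number of adjudicated
true cases in that population — i.e. the screen is assumed to have 100%
sensitivity, and the screen's own row reports sensitivity 100 with no
interval. TN is obtained by subtraction from the total patient count of
the participating hospitals, which the caller must supply (it is not
derivable from the record tables); NPV and specificity are reported only
then, and a zero denominator yields an explicit undefined rather than 0.

Intervals are Clopper–Pearson exact central intervals via beta quantiles,
with the degenerate one-sided bounds at k = 0 and k = n. The test suite
cross-checks them against direct bisection inversion of the binomial CDF.

Reviewer agreement is Cohen's kappa with Fleiss–Cohen (quadratic) weights
w_ij = 1 − ((i−j)/(k−1))² over the four ordered categories, pooled across
hospitals. The standard error is the Fleiss–Cohen–Everitt large-sample
formula and the 95% interval the normal approximation truncated to
[−1, 1]; the point estimate is the target of record, the interval method a
documented choice. The implementation is cross-checked against
statsmodels' `cohens_kappa` in the tests.

Percentages are rounded half-up to two decimals at presentation only.

## Adjudication logic

The three judgements binarize as Framingham {positive, inconclusive},
comprehensive assessment {positive, inconclusive} and treatment
{positive, negative}. Treatment gates everything: an untreated case is
Other regardless of the clinical judgements. Among treated cases,
Framingham-positive → True A; otherwise clinically positive → True B;
otherwise Suspected. This catch-all mapping of the remaining combinations
to Other is a stated assumption; finer sub-branches of the original
decision chart are not recoverable from its textual description.
Reviewer-disagreement resolution is an input (the final label), never
simulated.

## Synthetic cohort

The generator emulates the *mechanics* that drive algorithm behaviour —
sources, DPC fields, suspected flags, threshold-straddling lab values,
drug classes, echo procedures, event timing, reviewer noise — not
epidemiological reality. Eight archetypes mirror the situations that
produce true and false positives: acute HF and acute-on-chronic HF (the
true cases), and stable chronic HF, renal failure with elevated BNP (no
HF treatment, so treatment judgement negative), cardiac-function
screening, respiratory disease, stable arrhythmia and postoperative
circulatory failure (the false-positive mechanisms).

Defaults, chosen once as plausible for the mechanics they exercise:

* Mixture weights (0.17, 0.08, 0.24, 0.08, 0.15, 0.06, 0.10, 0.12 in the
  order above) put roughly a quarter of the screened population in true
  categories, with stable chronic HF the largest false-positive stratum.
* Lab values are log-normal per archetype (e.g. BNP medians 600 pg/ml
  acute, 180 stable-chronic, 300 renal; σ 0.5–0.9 on the log scale),
  straddling the 100/400 thresholds so both bands occur.
* Anchor dates are uniform over a 24-day study window; event offsets are
  uniform within archetype-specific ranges (tight, ±5 days, for acute
  cases; wide, up to ±15, for chronic ones) so window boundaries are
  exercised.
* Review judgements are drawn per archetype (acute: Framingham-positive
  0.80, treated 0.97; renal: treated 0.02; etc.), and the final category
  follows the classification logic exactly.
* One reviewer's label is perturbed to an adjacent ordinal category with
  probability 0.06. Note that adjacent-only disagreement is mild under
  quadratic weights, so the simulated kappa (~0.98 at that rate) sits
  above an agreement table with occasional distant disagreements.

`apc_saturated_archetypes(true_fraction)` is a calibration variant in
which every patient deterministically passes the screen (guaranteed
SS-MIX2 HF diagnosis; one BNP measurement floored at 100 pg/ml within ±25
days of it) and review outcomes are deterministic per archetype. Under it
the screen's expected PPV equals the configured true fraction exactly,
which is what the parameter-recovery tests exploit.

`expected_match_probability` is the Monte-Carlo oracle for cohort-level
checks: it generates archetype patients and reports the fraction matching
a given algorithm, optionally jointly with the screen (the relevant
quantity when conditioning on the sampled population). Recovery tests
compare pipeline PPV/sensitivity to mixture-weighted oracle values within
three combined (empirical + Monte-Carlo) standard errors.

What passing these tests shows: the conditions, windows, index rule,
sampling, confusion assembly and interval/kappa computations behave as
specified, at realistic scale. What it does not show: that the shipped
placeholder code sets, the archetype parameters or the resulting PPV /
sensitivity figures transfer to any real hospital population.

## Problem sizes

Default verification runs use cohorts of 400–2,000 synthetic patients,
1,000 random small bundles for the brute-force cross-check, and 4,000
Monte-Carlo draws per archetype for the oracle — sizes at which binomial
standard errors are small enough for three-sigma recovery checks while the
whole suite completes in well under a minute on one core.

## Known limitations

* One case per patient: episode-level evaluation (several admissions per
  patient) is out of scope, matching the one-sample-per-patient design.
* The claims suspected-diagnosis question (whether claims records flagged
  as suspected should be excluded from the claims disease condition) is
  unresolved in the source material; current behaviour includes them.
* Native SS-MIX2 message stores, DPC E/F files and receipt-format claims
  are not parsed; inputs are the documented CSV extracts.
* NPV and specificity depend on an externally supplied total patient
  count and are omitted otherwise.
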