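"""Seeded synthetic cohort generator with latent ground truth.

No raw hospital data can ship with this package, so testing and
calibration run on a simulated three-source cohort.  Each patient is drawn
from a mixture of archetypes modelled on the clinical situations that
produce true and false positives in acute-heart-failure phenotyping:
genuinely acute cases (de novo or acute-on-chronic), stable chronic heart
failure on oral diuretics, renal failure with elevated BNP but no
heart-failure treatment, cardiac-function screening (e.g. during cancer
treatment), respiratory disease, stable treated arrhythmia, and
postoperative circulatory failure.  An archetype fixes the emission
probabilities of diagnosis records per source, log-normal natriuretic
peptide distributions straddling the 100/400 (BNP) and 400/3,000
(NT-proBNP) pg/ml thresholds, drug-class exposures, echocardiography, event
timing around a per-patient anchor date, and the probabilities of the three
review judgements — so every patient also carries a latent review category
consistent with the classification logic.

The generator emulates record mechanics (sources, codes, dates, thresholds,
reviewer noise), not epidemiological reality; see the methods note for what
passing tests on this cohort do and do not establish.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .adjudication import (
    AdjudicatedCase,
    AnalysisMode,
    CaseCategory,
    Judgement,
    JudgementSet,
    TreatmentJudgement,
    classify,
)
from .algorithms import AlgorithmSpec, all_events, evaluate_algorithm
from .conditions import ConditionId
from .records import (
    ClinicalRecordBundle,
    CodeSetConfig,
    DiagnosisRecord,
    DpcField,
    DrugRecord,
    LabAnalyte,
    LabRecord,
    ProcedureRecord,
    SourceTag,
    default_codeset,
)

__all__ = [
    "ArchetypeConfig",
    "LatentTruth",
    "default_archetypes",
    "apc_saturated_archetypes",
    "generate_cohort",
    "expected_match_probability",
    "match_profile",
    "truth_probability",
    "adjudicated_cases",
    "STUDY_PERIOD",
]

# the study window the cohort emulates (24 days in March)
STUDY_PERIOD = (dt.date(2021, 3, 8), dt.date(2021, 3, 31))

# one concrete code per drug class, consistent with default_codeset()
EXAMPLE_DRUG_CODES = {
    "DRUG1": "C01CE91",   # carperitide
    "DRUG2": "C01CA07",   # dobutamine
    "DRUG3": "C03DA01",   # spironolactone
    "DRUG4": "C01AA05",   # digoxin
    "DRUG5": "C03AA03",   # hydrochlorothiazide (diuretic, not loop/K-sparing)
    "DRUG6": "C03CA01",   # furosemide (also a diuretic by prefix)
    "DRUG7": "C03XA01",   # tolvaptan
    "DRUG8": "C01CE02",   # milrinone
}

HF_ICD10_CODES = ("I500", "I501", "I509", "I110")

_DPC_FIELDS = tuple(DpcField)
_DPC_FIELD_P = (0.45, 0.15, 0.15, 0.10, 0.10, 0.05)


@dataclass(frozen=True)
class ArchetypeConfig:
    """Generation parameters for one patient archetype.

    Probabilities are per patient; lab values are log-normal with the given
    median (pg/ml) and log-scale sigma, truncated below at the floor.
    ``diag_offset_days`` / ``event_offset_days`` bound the uniform offsets
    of secondary diagnoses and of labs/drugs/procedures from the anchor
    date, so window-boundary behaviour is exercised.
    """

    name: str
    weight: float
    p_dpc_diagnosis: float
    p_long_stay: float
    p_ssmix_diagnosis: float
    p_suspected: float
    p_claims_diagnosis: float
    p_ntprobnp: float
    bnp_median: float
    bnp_sigma: float
    ntprobnp_median: float
    ntprobnp_sigma: float
    drug_probs: Mapping[str, float]
    p_tte: float
    diag_offset_days: int
    event_offset_days: int
    p_j1_positive: float
    p_j2_positive: float
    p_j3_positive: float
    n_labs: tuple[int, int] = (1, 2)
    bnp_floor: float = 0.0
    ntprobnp_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("archetype weight must be non-negative")


@dataclass(frozen=True)
class LatentTruth:
    """The generator's ground truth for one patient."""

    patient_id: str
    hospital_id: str
    archetype: str
    judgements: JudgementSet
    final: CaseCategory
    reviewer_a: CaseCategory
    reviewer_b: CaseCategory

    def __post_init__(self) -> None:
        if classify(self.judgements) is not self.final:
            raise ValueError("final category inconsistent with judgements")


def default_archetypes() -> list[ArchetypeConfig]:
    """An eight-archetype mixture for pipeline testing.

    Weights and judgement probabilities are fixed so that roughly a quarter
    of the screened population is adjudicated true and stable chronic heart
    failure dominates the false positives; lab medians straddle the
    guideline thresholds.
    """
    return [
        ArchetypeConfig(
            name="ACUTE_HF", weight=0.17,
            p_dpc_diagnosis=0.90, p_long_stay=0.85,
            p_ssmix_diagnosis=0.90, p_suspected=0.05, p_claims_diagnosis=0.80,
            p_ntprobnp=0.25, bnp_median=600.0, bnp_sigma=0.6,
            ntprobnp_median=4000.0, ntprobnp_sigma=0.7,
            drug_probs={"DRUG1": 0.5, "DRUG2": 0.3, "DRUG3": 0.2, "DRUG4": 0.1,
                        "DRUG5": 0.3, "DRUG6": 0.85, "DRUG7": 0.2, "DRUG8": 0.1},
            p_tte=0.8, diag_offset_days=3, event_offset_days=5,
            p_j1_positive=0.80, p_j2_positive=0.80, p_j3_positive=0.97,
        ),
        ArchetypeConfig(
            name="ACUTE_ON_CHRONIC_HF", weight=0.08,
            p_dpc_diagnosis=0.85, p_long_stay=0.80,
            p_ssmix_diagnosis=0.90, p_suspected=0.10, p_claims_diagnosis=0.85,
            p_ntprobnp=0.25, bnp_median=800.0, bnp_sigma=0.6,
            ntprobnp_median=5000.0, ntprobnp_sigma=0.7,
            drug_probs={"DRUG1": 0.35, "DRUG2": 0.25, "DRUG3": 0.3, "DRUG4": 0.15,
                        "DRUG5": 0.3, "DRUG6": 0.9, "DRUG7": 0.3, "DRUG8": 0.05},
            p_tte=0.75, diag_offset_days=4, event_offset_days=6,
            p_j1_positive=0.55, p_j2_positive=0.75, p_j3_positive=0.95,
        ),
        ArchetypeConfig(
            name="STABLE_CHRONIC_HF", weight=0.24,
            p_dpc_diagnosis=0.30, p_long_stay=0.50,
            p_ssmix_diagnosis=0.95, p_suspected=0.15, p_claims_diagnosis=0.90,
            p_ntprobnp=0.25, bnp_median=180.0, bnp_sigma=0.5,
            ntprobnp_median=900.0, ntprobnp_sigma=0.6,
            drug_probs={"DRUG3": 0.25, "DRUG4": 0.15, "DRUG5": 0.3, "DRUG6": 0.6,
                        "DRUG7": 0.1},
            p_tte=0.5, diag_offset_days=10, event_offset_days=15,
            p_j1_positive=0.02, p_j2_positive=0.05, p_j3_positive=0.12,
        ),
        ArchetypeConfig(
            name="RENAL_FAILURE_HIGH_BNP", weight=0.08,
            p_dpc_diagnosis=0.20, p_long_stay=0.60,
            p_ssmix_diagnosis=0.80, p_suspected=0.50, p_claims_diagnosis=0.60,
            p_ntprobnp=0.30, bnp_median=300.0, bnp_sigma=0.7,
            ntprobnp_median=2000.0, ntprobnp_sigma=0.8,
            drug_probs={"DRUG5": 0.3, "DRUG6": 0.7},
            p_tte=0.3, diag_offset_days=8, event_offset_days=12,
            p_j1_positive=0.02, p_j2_positive=0.05, p_j3_positive=0.02,
        ),
        ArchetypeConfig(
            name="CARDIAC_SCREENING", weight=0.15,
            p_dpc_diagnosis=0.10, p_long_stay=0.30,
            p_ssmix_diagnosis=0.80, p_suspected=0.70, p_claims_diagnosis=0.85,
            p_ntprobnp=0.30, bnp_median=80.0, bnp_sigma=0.8,
            ntprobnp_median=300.0, ntprobnp_sigma=0.9,
            drug_probs={"DRUG5": 0.1},
            p_tte=0.9, diag_offset_days=10, event_offset_days=15,
            p_j1_positive=0.01, p_j2_positive=0.02, p_j3_positive=0.02,
        ),
        ArchetypeConfig(
            name="RESPIRATORY_DISEASE", weight=0.06,
            p_dpc_diagnosis=0.30, p_long_stay=0.70,
            p_ssmix_diagnosis=0.60, p_suspected=0.40, p_claims_diagnosis=0.60,
            p_ntprobnp=0.25, bnp_median=150.0, bnp_sigma=0.6,
            ntprobnp_median=800.0, ntprobnp_sigma=0.7,
            drug_probs={"DRUG5": 0.15, "DRUG6": 0.3},
            p_tte=0.4, diag_offset_days=8, event_offset_days=12,
            p_j1_positive=0.02, p_j2_positive=0.03, p_j3_positive=0.05,
        ),
        ArchetypeConfig(
            name="STABLE_ARRHYTHMIA", weight=0.10,
            p_dpc_diagnosis=0.20, p_long_stay=0.40,
            p_ssmix_diagnosis=0.85, p_suspected=0.20, p_claims_diagnosis=0.80,
            p_ntprobnp=0.25, bnp_median=160.0, bnp_sigma=0.5,
            ntprobnp_median=850.0, ntprobnp_sigma=0.6,
            drug_probs={"DRUG4": 0.3, "DRUG5": 0.2, "DRUG6": 0.25},
            p_tte=0.7, diag_offset_days=10, event_offset_days=14,
            p_j1_positive=0.01, p_j2_positive=0.03, p_j3_positive=0.05,
        ),
        ArchetypeConfig(
            name="POSTOP_CIRCULATORY", weight=0.12,
            p_dpc_diagnosis=0.70, p_long_stay=0.90,
            p_ssmix_diagnosis=0.70, p_suspected=0.20, p_claims_diagnosis=0.60,
            p_ntprobnp=0.25, bnp_median=350.0, bnp_sigma=0.7,
            ntprobnp_median=2200.0, ntprobnp_sigma=0.8,
            drug_probs={"DRUG1": 0.4, "DRUG2": 0.6, "DRUG5": 0.2, "DRUG6": 0.35},
            p_tte=0.6, diag_offset_days=6, event_offset_days=10,
            p_j1_positive=0.05, p_j2_positive=0.10, p_j3_positive=0.15,
        ),
    ]


def apc_saturated_archetypes(true_fraction: float = 0.25) -> list[ArchetypeConfig]:
    """A calibration mixture whose every patient is certain to pass the APC
    screen, with deterministic review outcomes.

    The true archetype is always Framingham-positive and treated
    (True case A); the rest are never treated (Other).  Every patient gets
    an SS-MIX2 HF diagnosis and a BNP measurement floored at 100 pg/ml no
    further than 25 days from the first diagnosis date, so the APC match
    probability is exactly 1 and the expected APC PPV equals
    ``true_fraction``.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")

    def saturated(base: ArchetypeConfig, weight: float, true_case: bool) -> ArchetypeConfig:
        return replace(
            base,
            weight=weight,
            p_ssmix_diagnosis=1.0,
            p_ntprobnp=0.0,
            bnp_floor=100.0,
            n_labs=(1, 1),
            diag_offset_days=5,
            event_offset_days=20,
            p_j1_positive=1.0 if true_case else 0.0,
            p_j2_positive=1.0 if true_case else 0.0,
            p_j3_positive=1.0 if true_case else 0.0,
        )

    base = {a.name: a for a in default_archetypes()}
    rest = (1.0 - true_fraction) / 3.0
    return [
        saturated(base["ACUTE_HF"], true_fraction, True),
        saturated(base["STABLE_CHRONIC_HF"], rest, False),
        saturated(base["RENAL_FAILURE_HIGH_BNP"], rest, False),
        saturated(base["CARDIAC_SCREENING"], rest, False),
    ]


def _offset_date(rng: np.random.Generator, anchor: dt.date, max_abs: int) -> dt.date:
    return anchor + dt.timedelta(days=int(rng.integers(-max_abs, max_abs + 1)))


def _lab_value(rng: np.random.Generator, median: float, sigma: float, floor: float) -> float:
    return max(floor, float(rng.lognormal(np.log(median), sigma)))


def _generate_patient(
    rng: np.random.Generator,
    a: ArchetypeConfig,
    patient_id: str,
    hospital_id: str,
    period: tuple[dt.date, dt.date],
) -> tuple[ClinicalRecordBundle, JudgementSet]:
    n_days = (period[1] - period[0]).days + 1
    anchor = period[0] + dt.timedelta(days=int(rng.integers(0, n_days)))
    bundle = ClinicalRecordBundle(patient_id=patient_id, hospital_id=hospital_id)

    code = str(rng.choice(HF_ICD10_CODES, p=(0.55, 0.15, 0.2, 0.1)))
    if rng.random() < a.p_dpc_diagnosis:
        stay_offset = (
            int(rng.integers(2, 14)) if rng.random() < a.p_long_stay
            else int(rng.integers(0, 2))
        )
        bundle.diagnoses.append(
            DiagnosisRecord(
                patient_id, hospital_id, SourceTag.DPC, code, anchor,
                dpc_field=_DPC_FIELDS[int(rng.choice(6, p=_DPC_FIELD_P))],
                discharge_date=anchor + dt.timedelta(days=stay_offset),
            )
        )
    if rng.random() < a.p_ssmix_diagnosis:
        bundle.diagnoses.append(
            DiagnosisRecord(
                patient_id, hospital_id, SourceTag.SSMIX2, code,
                _offset_date(rng, anchor, a.diag_offset_days),
                suspected=bool(rng.random() < a.p_suspected),
            )
        )
    if rng.random() < a.p_claims_diagnosis:
        bundle.diagnoses.append(
            DiagnosisRecord(
                patient_id, hospital_id, SourceTag.CLAIMS, code,
                _offset_date(rng, anchor, a.diag_offset_days),
            )
        )
    for _ in range(int(rng.integers(a.n_labs[0], a.n_labs[1] + 1))):
        if rng.random() < a.p_ntprobnp:
            analyte, value = LabAnalyte.NTPROBNP, _lab_value(
                rng, a.ntprobnp_median, a.ntprobnp_sigma, a.ntprobnp_floor
            )
        else:
            analyte, value = LabAnalyte.BNP, _lab_value(
                rng, a.bnp_median, a.bnp_sigma, a.bnp_floor
            )
        bundle.labs.append(
            LabRecord(patient_id, hospital_id, analyte, round(value, 1),
                      _offset_date(rng, anchor, a.event_offset_days))
        )
    for class_id, p in a.drug_probs.items():
        if rng.random() < p:
            bundle.drugs.append(
                DrugRecord(
                    patient_id, hospital_id,
                    SourceTag(str(rng.choice([s.value for s in SourceTag]))),
                    EXAMPLE_DRUG_CODES[class_id],
                    _offset_date(rng, anchor, a.event_offset_days),
                )
            )
    if rng.random() < a.p_tte:
        bundle.procedures.append(
            ProcedureRecord(
                patient_id, hospital_id,
                SourceTag.DPC if rng.random() < 0.5 else SourceTag.CLAIMS,
                "160074710",
                _offset_date(rng, anchor, a.event_offset_days),
            )
        )
    judgements = JudgementSet(
        j1=Judgement.POSITIVE if rng.random() < a.p_j1_positive else Judgement.INCONCLUSIVE,
        j2=Judgement.POSITIVE if rng.random() < a.p_j2_positive else Judgement.INCONCLUSIVE,
        j3=TreatmentJudgement.POSITIVE if rng.random() < a.p_j3_positive
        else TreatmentJudgement.NEGATIVE,
    )
    return bundle, judgements


def _perturb_category(
    rng: np.random.Generator, category: CaseCategory, rate: float
) -> CaseCategory:
    """Move to an adjacent ordinal category with probability ``rate``."""
    if rng.random() >= rate:
        return category
    lo, hi = 0, len(CaseCategory) - 1
    if category.value == lo:
        return CaseCategory(category.value + 1)
    if category.value == hi:
        return CaseCategory(category.value - 1)
    return CaseCategory(category.value + (1 if rng.random() < 0.5 else -1))


def generate_cohort(
    archetypes: Sequence[ArchetypeConfig],
    n_patients: int,
    n_hospitals: int = 3,
    period: tuple[dt.date, dt.date] = STUDY_PERIOD,
    seed: int = 0,
    disagreement_rate: float = 0.06,
) -> tuple[list[ClinicalRecordBundle], list[LatentTruth]]:
    """Draw a cohort from the archetype mixture; deterministic given seed."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    weights = np.array([a.weight for a in archetypes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"archetype weights sum to {weights.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    bundles: list[ClinicalRecordBundle] = []
    truths: list[LatentTruth] = []
    for i in range(n_patients):
        a = archetypes[int(rng.choice(len(archetypes), p=weights))]
        patient_id = f"P{i:06d}"
        hospital_id = f"H{int(rng.integers(1, n_hospitals + 1))}"
        bundle, judgements = _generate_patient(rng, a, patient_id, hospital_id, period)
        final = classify(judgements)
        truths.append(
            LatentTruth(
                patient_id=patient_id,
                hospital_id=hospital_id,
                archetype=a.name,
                judgements=judgements,
                final=final,
                reviewer_a=final,
                reviewer_b=_perturb_category(rng, final, disagreement_rate),
            )
        )
        bundles.append(bundle)
    return bundles, truths


def adjudicated_cases(truths: Iterable[LatentTruth]) -> list[AdjudicatedCase]:
    """Reviewer labels and resolved category in the adjudication-table form."""
    return [
        AdjudicatedCase(
            patient_id=t.patient_id,
            hospital_id=t.hospital_id,
            reviewer_a=t.reviewer_a,
            reviewer_b=t.reviewer_b,
            final=t.final,
        )
        for t in truths
    ]


def truth_probability(a: ArchetypeConfig, mode: AnalysisMode) -> float:
    """Closed-form probability a patient of this archetype is adjudicated true."""
    if mode is AnalysisMode.PRIMARY:
        return a.p_j3_positive * (
            a.p_j1_positive + (1.0 - a.p_j1_positive) * a.p_j2_positive
        )
    return a.p_j3_positive


def match_profile(
    archetype: ArchetypeConfig,
    specs: Mapping[str, AlgorithmSpec],
    config: CodeSetConfig | None = None,
    n_mc: int = 2000,
    seed: int = 0,
    period: tuple[dt.date, dt.date] = STUDY_PERIOD,
) -> dict[str, np.ndarray]:
    """Per-draw match indicators of every spec for Monte-Carlo patients of
    one archetype; the oracle behind :func:`expected_match_probability`."""
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    if config is None:
        config = default_codeset()
    rng = np.random.default_rng(seed)
    out = {alg_id: np.zeros(n_mc, dtype=bool) for alg_id in specs}
    for i in range(n_mc):
        bundle, _ = _generate_patient(rng, archetype, f"MC{i:06d}", "H1", period)
        events = all_events(bundle, config)
        for alg_id, spec in specs.items():
            out[alg_id][i] = evaluate_algorithm(bundle, spec, config, events).matched
    return out


def expected_match_probability(
    archetype: ArchetypeConfig,
    spec: AlgorithmSpec,
    config: CodeSetConfig | None = None,
    n_mc: int = 2000,
    seed: int = 0,
    joint_with: AlgorithmSpec | None = None,
) -> float:
    """Monte-Carlo probability that an archetype patient matches ``spec``.

    With ``joint_with`` (typically the APC screen) the joint match
    probability is estimated instead, which is what the possible-case
    denominator of a validity analysis conditions on.
    """
    specs = {"target": spec}
    if joint_with is not None:
        specs["given"] = joint_with
    profile = match_profile(archetype, specs, config, n_mc, seed)
    hits = profile["target"]
    if joint_with is not None:
        hits = hits & profile["given"]
    return float(hits.mean())
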