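"""Chart-review classification: three judgements to an ordinal case category.

Two physicians independently review each sampled case.  Judgement 1 applies
the Framingham diagnostic criteria; Judgement 2 is a comprehensive clinical
assessment (biomarkers, imaging); Judgement 3 asks whether the patient was
treated for acute heart failure.  The three judgements map to four ordered
categories:

* True case A  — Framingham-positive and treated,
* True case B  — Framingham-inconclusive but clinically positive and treated,
* Suspected    — treated, but both clinical judgements inconclusive,
* Other        — not treated for acute heart failure.

The clinical content of the judgements (imaging reads, criteria
application) is outside this package; only the classification logic and its
use in validity statistics are implemented.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path

import pandas as pd

__all__ = [
    "Judgement",
    "TreatmentJudgement",
    "JudgementSet",
    "CaseCategory",
    "AdjudicatedCase",
    "AnalysisMode",
    "classify",
    "as_true",
    "read_adjudications",
    "write_adjudications",
]


class Judgement(str, Enum):
    POSITIVE = "POSITIVE"
    INCONCLUSIVE = "INCONCLUSIVE"


class TreatmentJudgement(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


@dataclass(frozen=True)
class JudgementSet:
    j1: Judgement            # Framingham criteria
    j2: Judgement            # comprehensive clinical assessment
    j3: TreatmentJudgement   # treated for acute heart failure


class CaseCategory(IntEnum):
    """Ordered review categories; the ordinal order drives the kappa weights."""

    TRUE_A = 0
    TRUE_B = 1
    SUSPECTED = 2
    OTHER = 3


class AnalysisMode(str, Enum):
    """Whether Suspected cases count as true (sensitivity) or not (primary)."""

    PRIMARY = "PRIMARY"
    SENSITIVITY = "SENSITIVITY"


def classify(j: JudgementSet) -> CaseCategory:
    """Total classification of a judgement triple.

    Treatment (Judgement 3) gates everything: an untreated case is Other
    regardless of the clinical judgements.
    """
    if j.j3 is TreatmentJudgement.NEGATIVE:
        return CaseCategory.OTHER
    if j.j1 is Judgement.POSITIVE:
        return CaseCategory.TRUE_A
    if j.j2 is Judgement.POSITIVE:
        return CaseCategory.TRUE_B
    return CaseCategory.SUSPECTED


def as_true(category: CaseCategory, mode: AnalysisMode) -> bool:
    """Is this category a 'True case' under the given analysis mode?"""
    if mode is AnalysisMode.PRIMARY:
        return category in (CaseCategory.TRUE_A, CaseCategory.TRUE_B)
    return category is not CaseCategory.OTHER


@dataclass(frozen=True)
class AdjudicatedCase:
    """Paired reviewer labels and the discussion-resolved final category."""

    patient_id: str
    hospital_id: str
    reviewer_a: CaseCategory
    reviewer_b: CaseCategory
    final: CaseCategory

    @property
    def key(self) -> tuple[str, str]:
        return (self.hospital_id, self.patient_id)


_COLUMNS = ["patient_id", "hospital_id", "reviewer_a", "reviewer_b", "final"]


def read_adjudications(path: str | Path) -> list[AdjudicatedCase]:
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return [
        AdjudicatedCase(
            patient_id=row.patient_id,
            hospital_id=row.hospital_id,
            reviewer_a=CaseCategory[row.reviewer_a],
            reviewer_b=CaseCategory[row.reviewer_b],
            final=CaseCategory[row.final],
        )
        for row in df.itertuples(index=False)
    ]


def write_adjudications(cases: list[AdjudicatedCase], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "hospital_id": c.hospital_id,
                "reviewer_a": c.reviewer_a.name,
                "reviewer_b": c.reviewer_b.name,
                "final": c.final.name,
            }
            for c in sorted(cases, key=lambda c: c.key)
        ],
        columns=_COLUMNS,
    ).to_csv(path, index=False)
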