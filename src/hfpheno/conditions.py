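"""Atomic phenotyping conditions evaluated against a patient bundle.

Twenty-one conditions ground the case-identification algorithms: six
disease-code conditions (varying by source and DPC field), eight drug-class
exposures, six natriuretic-peptide threshold conditions (BNP at 100/400
pg/ml, NT-proBNP at 400/3,000 pg/ml) and one procedure condition
(transthoracic echocardiography).  Each satisfied condition yields a dated
:class:`ConditionEvent` pointing back at the originating record; the
algorithm engine then reasons purely over events and dates.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum

from .records import (
    ClinicalRecordBundle,
    CodeSetConfig,
    DpcField,
    LabAnalyte,
    SourceTag,
)

__all__ = ["ConditionId", "ConditionEvent", "match_condition", "match_disease",
           "match_drug", "match_blood", "match_procedure", "all_events"]


class ConditionId(str, Enum):
    DISEASE1 = "DISEASE1"
    DISEASE2 = "DISEASE2"
    DISEASE3 = "DISEASE3"
    DISEASE4 = "DISEASE4"
    DISEASE5 = "DISEASE5"
    DISEASE6 = "DISEASE6"
    DRUG1 = "DRUG1"
    DRUG2 = "DRUG2"
    DRUG3 = "DRUG3"
    DRUG4 = "DRUG4"
    DRUG5 = "DRUG5"
    DRUG6 = "DRUG6"
    DRUG7 = "DRUG7"
    DRUG8 = "DRUG8"
    BLOOD1 = "BLOOD1"
    BLOOD2 = "BLOOD2"
    BLOOD3 = "BLOOD3"
    BLOOD4 = "BLOOD4"
    BLOOD5 = "BLOOD5"
    BLOOD6 = "BLOOD6"
    MEDPRACTICE1 = "MEDPRACTICE1"

    @property
    def is_disease(self) -> bool:
        return self.value.startswith("DISEASE")

    @property
    def is_drug(self) -> bool:
        return self.value.startswith("DRUG")

    @property
    def is_blood(self) -> bool:
        return self.value.startswith("BLOOD")


@dataclass(frozen=True)
class ConditionEvent:
    """A dated satisfaction of one condition, with its originating record.

    For DPC diagnoses the event date is the admission date.
    """

    condition: ConditionId
    date: dt.date
    source: SourceTag
    evidence: object


def length_of_stay(admission: dt.date, discharge: dt.date) -> int:
    """Hospital days counting both admission and discharge day (2 nights = 3 days)."""
    return (discharge - admission).days + 1


def match_disease(
    bundle: ClinicalRecordBundle, cid: ConditionId, config: CodeSetConfig
) -> list[ConditionEvent]:
    """Dated events for one of the six disease-code conditions.

    DISEASE1: HF code in any of the six DPC fields; DISEASE2: the
    three-field DPC subset; DISEASE3: SS-MIX2 including suspected;
    DISEASE4: SS-MIX2 excluding suspected; DISEASE5: claims; DISEASE6:
    DISEASE1 with an inpatient stay of three days or more.
    """
    if not cid.is_disease:
        raise ValueError(f"{cid} is not a disease condition")
    events = []
    for rec in bundle.diagnoses:
        if not config.is_hf_code(rec.icd10_code):
            continue
        ok = False
        if cid is ConditionId.DISEASE1:
            ok = rec.source is SourceTag.DPC
        elif cid is ConditionId.DISEASE2:
            ok = rec.source is SourceTag.DPC and rec.dpc_field in DpcField.THREE_FIELD
        elif cid is ConditionId.DISEASE3:
            ok = rec.source is SourceTag.SSMIX2
        elif cid is ConditionId.DISEASE4:
            ok = rec.source is SourceTag.SSMIX2 and not rec.suspected
        elif cid is ConditionId.DISEASE5:
            ok = rec.source is SourceTag.CLAIMS
        elif cid is ConditionId.DISEASE6:
            # missing discharge date -> stay unknown -> conservatively no match
            ok = (
                rec.source is SourceTag.DPC
                and rec.discharge_date is not None
                and length_of_stay(rec.date, rec.discharge_date) >= 3
            )
        if ok:
            events.append(ConditionEvent(cid, rec.date, rec.source, rec))
    return events


def match_drug(
    bundle: ClinicalRecordBundle, cid: ConditionId, config: CodeSetConfig
) -> list[ConditionEvent]:
    """Events for a drug-class exposure in any of the three sources."""
    if not cid.is_drug:
        raise ValueError(f"{cid} is not a drug condition")
    return [
        ConditionEvent(cid, rec.date, rec.source, rec)
        for rec in bundle.drugs
        if config.in_drug_class(rec.drug_code, cid.value)
    ]


# (analyte, lower bound inclusive, upper bound exclusive or None)
_BLOOD_RULES: dict[ConditionId, tuple[LabAnalyte, float, float | None]] = {
    ConditionId.BLOOD1: (LabAnalyte.BNP, 100.0, None),
    ConditionId.BLOOD2: (LabAnalyte.BNP, 400.0, None),
    ConditionId.BLOOD3: (LabAnalyte.BNP, 100.0, 400.0),
    ConditionId.BLOOD4: (LabAnalyte.NTPROBNP, 400.0, None),
    ConditionId.BLOOD5: (LabAnalyte.NTPROBNP, 3000.0, None),
    ConditionId.BLOOD6: (LabAnalyte.NTPROBNP, 400.0, 3000.0),
}


def match_blood(bundle: ClinicalRecordBundle, cid: ConditionId) -> list[ConditionEvent]:
    """Events for a natriuretic-peptide threshold condition.

    "Between X and Y" is the half-open interval [X, Y), so the moderate and
    high bands partition the at-or-above-lower-threshold band exactly.
    """
    if not cid.is_blood:
        raise ValueError(f"{cid} is not a blood-test condition")
    analyte, lo, hi = _BLOOD_RULES[cid]
    return [
        ConditionEvent(cid, rec.date, SourceTag.SSMIX2, rec)
        for rec in bundle.labs
        if rec.analyte is analyte and rec.value >= lo and (hi is None or rec.value < hi)
    ]


def match_procedure(
    bundle: ClinicalRecordBundle, config: CodeSetConfig
) -> list[ConditionEvent]:
    """Transthoracic echocardiography events in DPC or claims."""
    return [
        ConditionEvent(ConditionId.MEDPRACTICE1, rec.date, rec.source, rec)
        for rec in bundle.procedures
        if config.is_tte_code(rec.procedure_code)
    ]


def match_condition(
    bundle: ClinicalRecordBundle, cid: ConditionId, config: CodeSetConfig
) -> list[ConditionEvent]:
    if cid.is_disease:
        return match_disease(bundle, cid, config)
    if cid.is_drug:
        return match_drug(bundle, cid, config)
    if cid.is_blood:
        return match_blood(bundle, cid)
    return match_procedure(bundle, config)


def all_events(
    bundle: ClinicalRecordBundle, config: CodeSetConfig
) -> dict[ConditionId, list[ConditionEvent]]:
    """Evaluate every condition once; the algorithm engine's event cache."""
    return {cid: match_condition(bundle, cid, config) for cid in ConditionId}
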