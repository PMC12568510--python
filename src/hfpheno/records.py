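"""Domain types and delimited-text I/O for multi-source hospital records.

Patients in Japanese hospital information systems leave traces in three
structured sources: SS-MIX2-standardized electronic medical records
(diagnoses, drug orders, laboratory results), DPC case-mix data (inpatient
diagnoses in six defined fields, procedures, drugs) and health-insurance
claims (diagnoses, drugs, procedures).  This module defines one record type
per clinical event kind, a per-patient bundle, and the code-set
configuration that grounds every phenotyping condition, together with CSV
readers and writers for the four record tables.
"""

from __future__ import annotations

import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SourceTag",
    "DpcField",
    "DiagnosisRecord",
    "DrugRecord",
    "LabAnalyte",
    "LabRecord",
    "ProcedureRecord",
    "ClinicalRecordBundle",
    "CodeSetConfig",
    "SchemaError",
    "RecordValidationError",
    "read_record_tables",
    "write_record_tables",
    "default_codeset",
]


class SchemaError(ValueError):
    """A record table does not conform to the documented column schema."""


class RecordValidationError(ValueError):
    """A row violates a record-level invariant."""


class SourceTag(str, Enum):
    """Which of the three data sources a record originates from."""

    SSMIX2 = "SSMIX2"
    DPC = "DPC"
    CLAIMS = "CLAIMS"


class DpcField(str, Enum):
    """The six DPC diagnosis fields.

    The "three-field" subset (main diagnosis, admission-precipitating
    diagnosis, most resource-consuming diagnosis) is ``DpcField.THREE_FIELD``.
    """

    MAIN = "MAIN"
    ADMISSION_PRECIPITATING = "ADMISSION_PRECIPITATING"
    MOST_RESOURCE = "MOST_RESOURCE"
    SECOND_MOST_RESOURCE = "SECOND_MOST_RESOURCE"
    COMORBIDITY_ON_ADMISSION = "COMORBIDITY_ON_ADMISSION"
    COMPLICATION_DURING_ADMISSION = "COMPLICATION_DURING_ADMISSION"


DpcField.THREE_FIELD = frozenset(
    {DpcField.MAIN, DpcField.ADMISSION_PRECIPITATING, DpcField.MOST_RESOURCE}
)


class LabAnalyte(str, Enum):
    BNP = "BNP"
    NTPROBNP = "NTPROBNP"


@dataclass(frozen=True)
class DiagnosisRecord:
    """A dated diagnosis.

    ``date`` is the admission date for DPC records and the start date for
    SS-MIX2 and claims records.  ``suspected`` carries the SS-MIX2
    suspected-diagnosis modifier and is meaningful only for SSMIX2 rows.
    ``dpc_field`` is present exactly when the source is DPC.
    """

    patient_id: str
    hospital_id: str
    source: SourceTag
    icd10_code: str
    date: dt.date
    suspected: bool = False
    dpc_field: DpcField | None = None
    discharge_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.icd10_code:
            raise RecordValidationError("icd10_code must be non-empty")
        if (self.dpc_field is not None) != (self.source is SourceTag.DPC):
            raise RecordValidationError(
                "dpc_field must be present iff source is DPC "
                f"(source={self.source.value}, dpc_field={self.dpc_field})"
            )
        if self.discharge_date is not None and self.discharge_date < self.date:
            raise RecordValidationError(
                f"discharge_date {self.discharge_date} precedes admission date {self.date}"
            )


@dataclass(frozen=True)
class DrugRecord:
    patient_id: str
    hospital_id: str
    source: SourceTag
    drug_code: str
    date: dt.date

    def __post_init__(self) -> None:
        if not self.drug_code:
            raise RecordValidationError("drug_code must be non-empty")


@dataclass(frozen=True)
class LabRecord:
    """A BNP or NT-proBNP measurement in pg/ml.

    Laboratory conditions are defined on SS-MIX2 only, so the source is
    implicit.
    """

    patient_id: str
    hospital_id: str
    analyte: LabAnalyte
    value: float
    date: dt.date

    def __post_init__(self) -> None:
        if self.value < 0:
            raise RecordValidationError(f"lab value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class ProcedureRecord:
    patient_id: str
    hospital_id: str
    source: SourceTag
    procedure_code: str
    date: dt.date

    def __post_init__(self) -> None:
        if self.source is SourceTag.SSMIX2:
            raise RecordValidationError("procedure records exist only in DPC or claims")
        if not self.procedure_code:
            raise RecordValidationError("procedure_code must be non-empty")


@dataclass
class ClinicalRecordBundle:
    """All records of one patient at one hospital (one case per patient)."""

    patient_id: str
    hospital_id: str
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    drugs: list[DrugRecord] = field(default_factory=list)
    labs: list[LabRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)

    def validate(self) -> None:
        for rec in (*self.diagnoses, *self.drugs, *self.labs, *self.procedures):
            if rec.patient_id != self.patient_id or rec.hospital_id != self.hospital_id:
                raise RecordValidationError(
                    f"record {rec!r} does not belong to bundle "
                    f"({self.hospital_id}, {self.patient_id})"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.hospital_id, self.patient_id)


DRUG_CLASS_IDS = tuple(f"DRUG{i}" for i in range(1, 9))


def _matches_any(code: str, prefixes: frozenset[str]) -> bool:
    """Prefix matching: 'I50' covers 'I500', 'I501'; exact codes match themselves."""
    return any(code.startswith(p) for p in prefixes)


@dataclass(frozen=True)
class CodeSetConfig:
    """The code lists grounding each phenotyping condition.

    The shipped defaults (:func:`default_codeset`) are documented
    placeholders in the style of ICD-10 families and WHO-ATC drug classes;
    real deployments substitute institution-specific lists via YAML.
    Matching is by code prefix throughout.
    """

    hf_disease_codes: frozenset[str]
    drug_class_codes: Mapping[str, frozenset[str]]
    tte_procedure_codes: frozenset[str]
    bnp_analyte_ids: frozenset[str] = frozenset({"BNP"})
    ntprobnp_analyte_ids: frozenset[str] = frozenset({"NTPROBNP"})

    def __post_init__(self) -> None:
        for key in DRUG_CLASS_IDS:
            if key not in self.drug_class_codes or not self.drug_class_codes[key]:
                raise RecordValidationError(f"drug class {key} missing or empty")
        d5 = self.drug_class_codes["DRUG5"]
        for sub in ("DRUG6", "DRUG3"):
            for code in self.drug_class_codes[sub]:
                if not _matches_any(code, d5):
                    raise RecordValidationError(
                        f"{sub} code {code!r} is not covered by the DRUG5 (diuretics) code set"
                    )
        if self.bnp_analyte_ids & self.ntprobnp_analyte_ids:
            raise RecordValidationError("BNP and NT-proBNP analyte id sets overlap")

    def is_hf_code(self, icd10_code: str) -> bool:
        return _matches_any(icd10_code, self.hf_disease_codes)

    def in_drug_class(self, drug_code: str, class_id: str) -> bool:
        return _matches_any(drug_code, self.drug_class_codes[class_id])

    def is_tte_code(self, procedure_code: str) -> bool:
        return _matches_any(procedure_code, self.tte_procedure_codes)

    def analyte_for(self, raw_id: str) -> LabAnalyte:
        if raw_id in self.bnp_analyte_ids:
            return LabAnalyte.BNP
        if raw_id in self.ntprobnp_analyte_ids:
            return LabAnalyte.NTPROBNP
        raise RecordValidationError(f"unknown lab analyte identifier {raw_id!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeSetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            hf_disease_codes=frozenset(raw["hf_disease_codes"]),
            drug_class_codes={
                k: frozenset(v) for k, v in raw["drug_class_codes"].items()
            },
            tte_procedure_codes=frozenset(raw["tte_procedure_codes"]),
            bnp_analyte_ids=frozenset(raw.get("bnp_analyte_ids", ["BNP"])),
            ntprobnp_analyte_ids=frozenset(raw.get("ntprobnp_analyte_ids", ["NTPROBNP"])),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "hf_disease_codes": sorted(self.hf_disease_codes),
            "drug_class_codes": {
                k: sorted(v) for k, v in sorted(self.drug_class_codes.items())
            },
            "tte_procedure_codes": sorted(self.tte_procedure_codes),
            "bnp_analyte_ids": sorted(self.bnp_analyte_ids),
            "ntprobnp_analyte_ids": sorted(self.ntprobnp_analyte_ids),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_codeset() -> CodeSetConfig:
    """Placeholder code sets: ICD-10 heart-failure family, ATC-style drug classes.

    These stand in for institution-curated lists and are suitable for
    synthetic data and testing; they are NOT a clinically validated code
    catalogue.
    """
    return CodeSetConfig(
        hf_disease_codes=frozenset({"I110", "I130", "I132", "I50"}),
        drug_class_codes={
            # carperitide (recombinant hANP) — placeholder code
            "DRUG1": frozenset({"C01CE91"}),
            # catecholamines + pimobendan
            "DRUG2": frozenset({"C01CA04", "C01CA07", "C01CA24", "C01CE90"}),
            # potassium-sparing diuretics (subset of DRUG5 by prefix)
            "DRUG3": frozenset({"C03D"}),
            # digitalis glycosides
            "DRUG4": frozenset({"C01AA"}),
            # all diuretics
            "DRUG5": frozenset({"C03"}),
            # loop diuretics (subset of DRUG5 by prefix)
            "DRUG6": frozenset({"C03C"}),
            # tolvaptan
            "DRUG7": frozenset({"C03XA01"}),
            # phosphodiesterase inhibitors (milrinone, olprinone)
            "DRUG8": frozenset({"C01CE02", "C01CE04"}),
        },
        tte_procedure_codes=frozenset({"160074710"}),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_TABLES = {
    "diagnoses": [
        "patient_id", "hospital_id", "source", "icd10_code", "date",
        "suspected", "dpc_field", "discharge_date",
    ],
    "drugs": ["patient_id", "hospital_id", "source", "drug_code", "date"],
    "labs": ["patient_id", "hospital_id", "analyte", "value", "date"],
    "procedures": ["patient_id", "hospital_id", "source", "procedure_code", "date"],
}


def _load_table(path: Path, name: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLES[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {', '.join(missing)}")
    return df


def _parse_date(raw: str, path: Path, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(raw)
    except ValueError:
        raise RecordValidationError(
            f"{path} row {row}: unparseable {column} {raw!r} (expected ISO-8601)"
        ) from None


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in {"true", "1", "yes", "t"}


def read_record_tables(
    directory: str | Path, config: CodeSetConfig
) -> list[ClinicalRecordBundle]:
    """Read the four record CSVs from ``directory`` into per-patient bundles.

    ``diagnoses.csv`` must exist; an absent drugs/labs/procedures table is
    treated as empty.  Returns one bundle per distinct
    (hospital_id, patient_id), ordered by that key.
    """
    directory = Path(directory)
    bundles: dict[tuple[str, str], ClinicalRecordBundle] = {}

    def bundle_for(hospital_id: str, patient_id: str) -> ClinicalRecordBundle:
        key = (hospital_id, patient_id)
        if key not in bundles:
            bundles[key] = ClinicalRecordBundle(patient_id=patient_id, hospital_id=hospital_id)
        return bundles[key]

    diag_path = directory / "diagnoses.csv"
    if not diag_path.exists():
        raise SchemaError(f"required table {diag_path} not found")
    df = _load_table(diag_path, "diagnoses")
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        source = SourceTag(row.source)
        dpc_field = DpcField(row.dpc_field) if row.dpc_field else None
        if dpc_field is not None and source is not SourceTag.DPC:
            raise RecordValidationError(
                f"{diag_path} row {idx}: dpc_field {row.dpc_field!r} on a "
                f"{source.value} row"
            )
        rec = DiagnosisRecord(
            patient_id=row.patient_id,
            hospital_id=row.hospital_id,
            source=source,
            icd10_code=row.icd10_code,
            date=_parse_date(row.date, diag_path, idx, "date"),
            suspected=_parse_bool(row.suspected),
            dpc_field=dpc_field,
            discharge_date=(
                _parse_date(row.discharge_date, diag_path, idx, "discharge_date")
                if row.discharge_date
                else None
            ),
        )
        bundle_for(rec.hospital_id, rec.patient_id).diagnoses.append(rec)

    drug_path = directory / "drugs.csv"
    if drug_path.exists():
        df = _load_table(drug_path, "drugs")
        for idx, row in enumerate(df.itertuples(index=False), start=2):
            rec = DrugRecord(
                patient_id=row.patient_id,
                hospital_id=row.hospital_id,
                source=SourceTag(row.source),
                drug_code=row.drug_code,
                date=_parse_date(row.date, drug_path, idx, "date"),
            )
            bundle_for(rec.hospital_id, rec.patient_id).drugs.append(rec)

    lab_path = directory / "labs.csv"
    if lab_path.exists():
        df = _load_table(lab_path, "labs")
        for idx, row in enumerate(df.itertuples(index=False), start=2):
            rec = LabRecord(
                patient_id=row.patient_id,
                hospital_id=row.hospital_id,
                analyte=config.analyte_for(row.analyte),
                value=float(row.value),
                date=_parse_date(row.date, lab_path, idx, "date"),
            )
            bundle_for(rec.hospital_id, rec.patient_id).labs.append(rec)

    proc_path = directory / "procedures.csv"
    if proc_path.exists():
        df = _load_table(proc_path, "procedures")
        for idx, row in enumerate(df.itertuples(index=False), start=2):
            rec = ProcedureRecord(
                patient_id=row.patient_id,
                hospital_id=row.hospital_id,
                source=SourceTag(row.source),
                procedure_code=row.procedure_code,
                date=_parse_date(row.date, proc_path, idx, "date"),
            )
            bundle_for(rec.hospital_id, rec.patient_id).procedures.append(rec)

    out = [bundles[k] for k in sorted(bundles)]
    for b in out:
        b.validate()
    return out


def write_record_tables(
    bundles: Iterable[ClinicalRecordBundle], directory: str | Path
) -> dict[str, Path]:
    """Write bundles back to the four CSV tables; inverse of read_record_tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[dict]] = {name: [] for name in _TABLES}
    for b in sorted(bundles, key=lambda b: b.key):
        b.validate()
        for r in sorted(b.diagnoses, key=lambda r: (r.date, r.source.value, r.icd10_code)):
            rows["diagnoses"].append(
                {
                    "patient_id": r.patient_id,
                    "hospital_id": r.hospital_id,
                    "source": r.source.value,
                    "icd10_code": r.icd10_code,
                    "date": r.date.isoformat(),
                    "suspected": str(r.suspected).lower(),
                    "dpc_field": r.dpc_field.value if r.dpc_field else "",
                    "discharge_date": r.discharge_date.isoformat() if r.discharge_date else "",
                }
            )
        for r in sorted(b.drugs, key=lambda r: (r.date, r.source.value, r.drug_code)):
            rows["drugs"].append(
                {
                    "patient_id": r.patient_id,
                    "hospital_id": r.hospital_id,
                    "source": r.source.value,
                    "drug_code": r.drug_code,
                    "date": r.date.isoformat(),
                }
            )
        for r in sorted(b.labs, key=lambda r: (r.date, r.analyte.value, r.value)):
            rows["labs"].append(
                {
                    "patient_id": r.patient_id,
                    "hospital_id": r.hospital_id,
                    "analyte": r.analyte.value,
                    "value": repr(r.value),
                    "date": r.date.isoformat(),
                }
            )
        for r in sorted(b.procedures, key=lambda r: (r.date, r.source.value, r.procedure_code)):
            rows["procedures"].append(
                {
                    "patient_id": r.patient_id,
                    "hospital_id": r.hospital_id,
                    "source": r.source.value,
                    "procedure_code": r.procedure_code,
                    "date": r.date.isoformat(),
                }
            )
    paths = {}
    for name, columns in _TABLES.items():
        path = directory / f"{name}.csv"
        pd.DataFrame(rows[name], columns=columns).to_csv(path, index=False)
        paths[name] = path
    return paths
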