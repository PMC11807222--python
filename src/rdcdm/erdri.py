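"""Flatten a PatientRecord into the 16-element ERDRI-CDS registry row.

Header labels follow the source narrative of the 16-element common data set
and are provisional (the exact official labels are cited, not reprinted, in
the source). Derivation rules beyond direct projection:

- first contact with a specialised centre = minimum 4.1 over encounters
  whose type of encounter (4.4) is the custom RD Specialist Center code;
- age at onset / age at diagnosis come from the earliest-dated disease
  instance (ERDRI's row is singular, the model's disease section is 0..n);
- diagnosis codes are filtered to the ORDO/OMIM systems.

The projection is invariant under permutation of repeatable-section
instances (minima and earliest-instance rules are order-free).
"""

from __future__ import annotations

import csv
import io


from pydantic import BaseModel

from .model import CodeSystem, ModelRegistry
from .records import PatientRecord
from .terminologies import curie
from .validation import require_valid

_RD_CENTER_CODE = "rd_cdm:rd_specialist_center"

ERDRI_COLUMNS = [
    "pseudonym",
    "date_of_birth",
    "sex",
    "patient_status",
    "date_of_death",
    "first_contact_specialised_centre",
    "age_at_onset",
    "age_at_diagnosis",
    "diagnosis_codes",
    "genetic_diagnosis",
    "undiagnosed_case",
    "agreement_to_be_contacted",
    "consent_to_reuse_of_data",
    "biological_sample",
    "biobank_link",
    "disability_classification",
]


class ErdriRow(BaseModel):
    pseudonym: str = ""
    date_of_birth: str = ""
    sex: str = ""
    patient_status: str = ""
    date_of_death: str = ""
    first_contact_specialised_centre: str = ""
    age_at_onset: str = ""
    age_at_diagnosis: str = ""
    diagnosis_codes: str = ""
    genetic_diagnosis: str = ""
    undiagnosed_case: str = ""
    agreement_to_be_contacted: str = ""
    consent_to_reuse_of_data: str = ""
    biological_sample: str = ""
    biobank_link: str = ""
    disability_classification: str = ""


def _display(value) -> str:
    if value is None:
        return ""
    code = value[0] if isinstance(value, list) else value
    return code.display or code.code


def _codes(value) -> list:
    if value is None:
        return []
    return value if isinstance(value, list) else [value]


def _first_contact(record: PatientRecord) -> str:
    dates = []
    for inst in record.instances("4"):
        enc_class = inst.get("4.4")
        start = inst.get("4.1")
        if enc_class is None or not start:
            continue
        codes = _codes(enc_class)
        if any(c.code == _RD_CENTER_CODE for c in codes):
            dates.append(start)
    return min(dates) if dates else ""


def _earliest_disease(record: PatientRecord):
    instances = record.instances("5")
    if not instances:
        return None
    def sort_key(inst):
        # earliest onset date, then diagnosis date; undated instances last
        return (inst.get("5.4") or "9999-99-99", inst.get("5.6") or "9999-99-99")
    return min(instances, key=sort_key)


def to_erdri(record: PatientRecord, registry: ModelRegistry) -> ErdriRow:
    require_valid(record, registry)
    row = ErdriRow()
    row.pseudonym = record.first("1.1") or ""
    row.date_of_birth = record.first("2.1") or ""
    row.sex = _display(record.first("2.2"))
    row.patient_status = _display(record.first("3.1"))
    row.date_of_death = record.first("3.2") or ""
    row.first_contact_specialised_centre = _first_contact(record)
    disease = _earliest_disease(record)
    if disease is not None:
        row.age_at_onset = _display(disease.get("5.3"))
        row.age_at_diagnosis = _display(disease.get("5.5"))
    diag_codes = []
    diag_systems = {
        CodeSystem.ORDO, CodeSystem.OMIM_G, CodeSystem.OMIM_P,
    }
    for value in record.all_values("5.1"):
        for code in _codes(value):
            if code.system in diag_systems:
                diag_codes.append(curie(code))
    row.diagnosis_codes = "; ".join(dict.fromkeys(diag_codes))
    genetic = []
    for inst in record.instances("6.1"):
        for eid in ("6.1.10", "6.1.7", "6.1.8", "6.1.9"):
            value = inst.get(eid)
            if value is None:
                continue
            if isinstance(value, str):
                genetic.append(value)
            else:
                genetic.extend(curie(c) for c in _codes(value))
    row.genetic_diagnosis = "; ".join(dict.fromkeys(genetic))
    undiagnosed = record.first("3.6")
    if undiagnosed is not None:
        row.undiagnosed_case = "true" if undiagnosed else "false"
    row.agreement_to_be_contacted = _display(record.first("7.4"))
    row.consent_to_reuse_of_data = _display(record.first("7.5"))
    row.biological_sample = _display(record.first("7.6"))
    row.biobank_link = record.first("7.7") or ""
    disability = record.first("8.1")
    if disability is not None:
        row.disability_classification = "; ".join(
            curie(c) for c in _codes(disability)
        )
    return row


def erdri_csv(rows: list[ErdriRow]) -> str:
    """One row per record, fixed header, ISO-8601 dates."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(ERDRI_COLUMNS)
    for row in rows:
        writer.writerow([getattr(row, col) for col in ERDRI_COLUMNS])
    return buf.getvalue()
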