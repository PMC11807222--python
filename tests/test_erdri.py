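"""ERDRI-CDS flattening: derivation rules and permutation invariance."""

import csv
import io

from rdcdm import erdri_csv, read_record, to_erdri
from rdcdm.erdri import ERDRI_COLUMNS

CENTER = {"system": "CUSTOM", "code": "rd_cdm:rd_specialist_center",
          "display": "RD Specialist Center"}
AMB = {"system": "HL7FHIR", "code": "AMB", "display": "ambulatory"}

BASE = {
    "1": {"1.1": "P-1", "1.2": "2021-03-02"},
    "7": {"7.2": "2020-01-01"},
}


def _row(registry, extra):
    doc = dict(BASE)
    doc.update(extra)
    return to_erdri(read_record(doc, registry), registry)


def test_first_contact_is_min_over_specialist_encounters(registry):
    encounters = [
        {"4.1": "2019-05-01", "4.4": AMB},
        {"4.1": "2020-02-01", "4.4": CENTER},
        {"4.1": "2018-07-01", "4.4": CENTER},
    ]
    row = _row(registry, {"4": encounters})
    assert row.first_contact_specialised_centre == "2018-07-01"
    # invariant under permutation of the repeatable instances
    row2 = _row(registry, {"4": list(reversed(encounters))})
    assert row2 == row


def test_first_contact_empty_without_specialist_encounter(registry):
    row = _row(registry, {"4": [{"4.1": "2019-05-01", "4.4": AMB}]})
    assert row.first_contact_specialised_centre == ""


def test_diagnosis_codes_filtered_and_deduplicated(registry):
    ordo = {"system": "ORDO", "code": "x-1", "display": "Toy"}
    snomed = {"system": "SNOMED_CT", "code": "x-s", "display": "Toy"}
    row = _row(registry, {"5": [
        {"5.1": [ordo, snomed]},
        {"5.1": ordo},
    ]})
    assert row.diagnosis_codes == "ORPHA:x-1"


def test_earliest_disease_provides_onset_and_diagnosis_age(registry):
    early_age = {"system": "SNOMED_CT", "code": "x-congenital-onset",
                 "display": "Congenital onset"}
    late_age = {"system": "SNOMED_CT", "code": "x-onset-in-adulthood",
                "display": "Onset in adulthood"}
    diseases = [
        {"5.4": "2015-01-01", "5.3": late_age},
        {"5.4": "2010-01-01", "5.3": early_age},
    ]
    row = _row(registry, {"5": diseases})
    assert row.age_at_onset == "Congenital onset"


def test_undiagnosed_flag(registry):
    row = _row(registry, {"3": {"3.6": True}})
    assert row.undiagnosed_case == "true"
    row = _row(registry, {})
    assert row.undiagnosed_case == ""


def test_csv_shape(registry, cohort):
    rows = [to_erdri(r, registry) for r in cohort]
    doc = erdri_csv(rows)
    parsed = list(csv.reader(io.StringIO(doc)))
    assert parsed[0] == ERDRI_COLUMNS
    assert len(parsed) == len(cohort) + 1
    pseudonyms = [r[0] for r in parsed[1:]]
    assert len(set(pseudonyms)) == len(cohort)
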