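"""FHIR R4-shaped export: resource shapes, references, unmapped manifest."""

import pytest

from rdcdm import check_fhir_shape, fhir_json, read_record, to_fhir
from rdcdm.fhir import FhirResourceSet
from rdcdm.validation import RecordInvalidError

BASE = {
    "1": {"1.1": "P-1", "1.2": "2021-03-02"},
    "7": {"7.2": "2020-01-01"},
}


def _fhir(registry, extra):
    doc = dict(BASE)
    doc.update(extra)
    return to_fhir(read_record(doc, registry), registry)


def test_custom_codes_are_prefix_stripped(registry):
    rs = _fhir(registry, {"4": [{
        "4.4": {"system": "CUSTOM", "code": "rd_cdm:rd_specialist_center",
                "display": "RD Specialist Center"},
    }]})
    encounter = rs.by_type("Encounter")[0]
    assert encounter["class"] == {
        "system": "rd_cdm", "code": "rd_specialist_center",
        "display": "RD Specialist Center",
    }


@pytest.mark.parametrize("display,code,expected", [
    ("Yes", "373066001", True),
    ("No", "373067005", False),
    ("Unknown", "261665006", None),
])
def test_family_member_deceased_boolean(registry, display, code, expected):
    rs = _fhir(registry, {"6.4": [{
        "6.4.10": {"system": "SNOMED_CT", "code": code, "display": display},
    }]})
    fmh = rs.by_type("FamilyMemberHistory")[0]
    if expected is None:
        assert "deceasedBoolean" not in fmh  # boolean cannot encode Unknown
    else:
        assert fmh["deceasedBoolean"] is expected


def test_family_member_age_is_age_quantity(registry):
    rs = _fhir(registry, {"6.4": [{"6.4.8": 42}]})
    fmh = rs.by_type("FamilyMemberHistory")[0]
    assert fmh["ageAge"]["value"] == 42
    assert fmh["ageAge"]["unit"] == "years"


def test_cohort_exports_pass_shape_check(registry, cohort):
    for record in cohort:
        rs = to_fhir(record, registry)
        assert check_fhir_shape(rs) == []


def test_resource_count_conservation(registry, cohort):
    for record in cohort:
        rs = to_fhir(record, registry)
        assert len(rs.by_type("Patient")) == 1
        assert len(rs.by_type("Encounter")) == len(record.instances("4"))
        assert len(rs.by_type("Condition")) == len(record.instances("5"))
        assert len(rs.by_type("FamilyMemberHistory")) == len(
            record.instances("6.4")
        )


def test_unmapped_manifest_lists_fhirless_elements(registry):
    rs = _fhir(registry, {"6.1": [{
        "6.1.2": {"system": "GA4GH", "code": "SOLVED", "display": "Solved"},
        "6.1.7": "NC_000001.11:g.100A>G",
    }]})
    unmapped_ids = {e["element_id"] for e in rs.unmapped}
    assert "6.1.2" in unmapped_ids  # Phenopacket-only element
    assert "6.1.7" not in unmapped_ids  # carried as a component
    # nothing populated is silently dropped: every unmapped entry has a value
    assert all(e["value"] is not None for e in rs.unmapped)


def test_disability_is_emitted_not_unmapped(registry):
    rs = _fhir(registry, {"8": {
        "8.1": {"system": "ICF", "code": "x-icf-1", "display": "Toy"},
    }})
    assert "8.1" not in {e["element_id"] for e in rs.unmapped}
    icf = [o for o in rs.by_type("Observation") if o["id"].endswith("obs-icf")]
    assert icf[0]["code"]["coding"][0]["code"] == "icf_score"


def test_shape_check_flags_bad_documents(registry):
    rs = _fhir(registry, {})
    broken = FhirResourceSet(
        resources=[
            r for r in rs.resources
        ] + [{
            "resourceType": "Observation", "id": "orphan", "status": "final",
            "code": {"coding": [{"system": "http://loinc.org"}]},  # no code
            "subject": {"reference": "Patient/someone-else"},
        }],
        unmapped=[],
    )
    rules = {i.rule_id for i in check_fhir_shape(broken)}
    assert rules == {"fhir_reference", "fhir_coding"}


def test_invalid_record_is_refused(registry):
    record = read_record({"7": {"7.2": "2020-01-01"}}, registry)
    with pytest.raises(RecordInvalidError):
        to_fhir(record, registry)


def test_fhir_json_is_deterministic(registry, cohort):
    assert fhir_json(to_fhir(cohort[0], registry)) == fhir_json(
        to_fhir(cohort[0], registry)
    )
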