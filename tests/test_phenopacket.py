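"""Phenopacket-shaped export: mapping semantics and lossless inversion."""

import json

import pytest

from rdcdm import (
    extract_mapped_projection,
    phenopacket_json,
    read_record,
    to_phenopacket,
)
from rdcdm.phenopacket import (
    PhenopacketFormatError,
    extract_record,
    phenopacket_aligned_elements,
    record_projection,
)
from rdcdm.validation import RecordInvalidError

BASE = {
    "1": {"1.1": "P-1", "1.2": "2021-03-02"},
    "7": {"7.2": "2020-01-01"},
}


def _packet(registry, extra):
    doc = dict(BASE)
    doc.update(extra)
    return to_phenopacket(read_record(doc, registry), registry)


def test_refuted_phenotype_sets_excluded(registry):
    refuted = {"system": "SNOMED_CT", "code": "410594000", "display": "Refuted"}
    confirmed = {"system": "SNOMED_CT", "code": "410605003",
                 "display": "Confirmed present"}
    packet = _packet(registry, {"6.2": [{"6.2.2": refuted}, {"6.2.2": confirmed}]})
    features = packet["phenotypicFeatures"]
    assert features[0]["excluded"] is True
    assert "excluded" not in features[1]


def test_variants_sharing_diagnosis_group_into_one_interpretation(registry):
    diag = {"system": "OMIM_G", "code": "x-1", "display": "Toy disorder"}
    other = {"system": "OMIM_G", "code": "x-2", "display": "Other disorder"}
    packet = _packet(registry, {
        "6.1": [{"6.1.1": diag}, {"6.1.1": diag}, {"6.1.1": other}],
    })
    interps = packet["interpretations"]
    assert len(interps) == 2
    sizes = sorted(
        len(i["diagnosis"]["genomicInterpretations"]) for i in interps
    )
    assert sizes == [1, 2]


def test_invalid_record_is_refused(registry):
    record = read_record({"7": {"7.2": "2020-01-01"}}, registry)
    with pytest.raises(RecordInvalidError):
        to_phenopacket(record, registry)


def test_metadata_resources_cover_used_prefixes(registry):
    hpo = {"system": "HPO", "code": "HP:x000001", "display": "Toy finding"}
    packet = _packet(registry, {"6.2": [{"6.2.1": hpo}]})
    prefixes = {r["namespacePrefix"] for r in packet["metaData"]["resources"]}
    assert "HP" in prefixes
    ids = [r["id"] for r in packet["metaData"]["resources"]]
    assert len(ids) == len(set(ids))


def test_aligned_element_population(registry):
    aligned = phenopacket_aligned_elements(registry)
    assert len(aligned) == 56
    assert "6.2.1" in aligned and "4.1" not in aligned


def test_round_trip_is_lossless_on_cohort(registry, cohort):
    for record in cohort:
        packet = to_phenopacket(record, registry)
        reparsed = json.loads(phenopacket_json(packet))
        expected = record_projection(record, registry)
        assert extract_mapped_projection(reparsed, registry) == expected


def test_extract_record_inverts_structure(registry, cohort):
    record = cohort[0]
    packet = to_phenopacket(record, registry)
    assert extract_record(packet, registry) == record


def test_extraction_from_foreign_document(registry):
    """Documents without extension maps fall back to native inverses."""
    foreign = {
        "id": "x",
        "subject": {"id": "P-9"},
        "phenotypicFeatures": [
            {"type": {"id": "HP:0001250", "label": "Seizure"},
             "excluded": True},
        ],
    }
    record = extract_record(foreign, registry)
    assert record.pseudonym() == "P-9"
    assert record.first("6.2.2").display == "Refuted"


def test_unknown_extension_keys_pass_through(registry):
    record = read_record(dict(BASE), registry)
    packet = to_phenopacket(record, registry)
    packet["rdCdmExtensions"]["1"]["x-local-field"] = "kept"
    out = extract_mapped_projection(packet, registry)
    assert out["x-local-field"] == "kept"


def test_non_phenopacket_document_rejected(registry):
    with pytest.raises(PhenopacketFormatError):
        extract_record({"not": "a packet"}, registry)


def test_vital_status_and_sex_enums(registry):
    packet = _packet(registry, {
        "2": {"2.1": "1980-01-01",
              "2.2": {"system": "SNOMED_CT", "code": "248152002",
                      "display": "Female"}},
        "3": {"3.1": {"system": "SNOMED_CT", "code": "419099009",
                      "display": "Dead"},
              "3.2": "2022-06-01"},
    })
    subject = packet["subject"]
    assert subject["sex"] == "FEMALE"
    assert subject["vitalStatus"]["status"] == "DECEASED"
    assert subject["vitalStatus"]["timeOfDeath"]["timestamp"].startswith("2022-06-01")
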