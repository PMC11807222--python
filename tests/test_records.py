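"""Record JSON parsing, serialisation and cardinality profiles."""

import json

import pytest

from rdcdm import (
    CardinalityProfile,
    Cardinality,
    RecordParseError,
    read_record,
    record_schema,
    write_record,
)

MINIMAL = {
    "1": {"1.1": "P-0001", "1.2": "2021-03-02"},
    "7": {
        "7.1": {"system": "HL7FHIR", "code": "active", "display": "Active"},
        "7.2": "2021-03-02",
    },
}


def test_round_trip_is_identity(registry, cohort):
    for record in cohort:
        doc = write_record(record)
        assert write_record(read_record(json.loads(doc), registry)) == doc


def test_read_rejects_wrong_value_type(registry):
    doc = dict(MINIMAL)
    doc["3"] = {"3.6": "yes"}  # BOOLEAN element, string given
    with pytest.raises(RecordParseError) as excinfo:
        read_record(doc, registry)
    assert "/3/3.6" in excinfo.value.pointer


def test_read_rejects_unknown_element(registry):
    doc = dict(MINIMAL)
    doc["2"] = {"2.99": "x"}
    with pytest.raises(RecordParseError):
        read_record(doc, registry)


def test_section_one_requires_pseudonym(registry):
    with pytest.raises(RecordParseError, match="1.1"):
        read_record({"1": {"1.2": "2021-03-02"}}, registry)


def test_repeatable_section_must_be_list(registry):
    doc = dict(MINIMAL)
    doc["5"] = {"5.4": "2020-01-01"}
    with pytest.raises(RecordParseError):
        read_record(doc, registry)


def test_multi_coded_elements_accept_lists(registry):
    doc = dict(MINIMAL)
    doc["5"] = [{
        "5.1": [
            {"system": "ORDO", "code": "x-1", "display": "Toy"},
            {"system": "OMIM_G", "code": "x-2", "display": "Toy"},
        ]
    }]
    record = read_record(doc, registry)
    assert len(record.first("5.1")) == 2


def test_profiles():
    default = CardinalityProfile.default()
    strict = CardinalityProfile.strict()
    assert default.cardinalities["2"] == Cardinality.ZERO_ONE
    assert strict.cardinalities["2"] == Cardinality.ONE_ONE
    assert strict.cardinalities["5"] == default.cardinalities["5"]
    with pytest.raises(KeyError):
        CardinalityProfile.named("lenient")


def test_profile_from_file(tmp_path):
    path = tmp_path / "profile.yaml"
    path.write_text(
        "name: custom\ncardinalities:\n"
        + "".join(
            f'  "{sid}": {card}\n'
            for sid, card in [
                ("1", "1..1"), ("2", "0..1"), ("3", "0..1"), ("4", "0..n"),
                ("5", "0..n"), ("6.1", "0..n"), ("6.2", "0..n"),
                ("6.3", "0..n"), ("6.4", "0..n"), ("7", "1..1"), ("8", "1..1"),
            ]
        )
    )
    profile = CardinalityProfile.from_file(path)
    assert profile.cardinalities["8"] == Cardinality.ONE_ONE


def test_record_schema_shape(registry):
    schema = record_schema(registry)
    assert schema["$schema"].endswith("2020-12/schema")
    assert set(schema["properties"]) == {
        "1", "2", "3", "4", "5", "6.1", "6.2", "6.3", "6.4", "7", "8",
    }
    assert schema["properties"]["5"]["type"] == "array"
    assert schema["properties"]["1"]["required"] == ["1.1"]
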