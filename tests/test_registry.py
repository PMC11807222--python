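"""Bundled-model structure, JSON/CSV export and schema-checked loading."""

import csv
import io
import json

import pytest

from rdcdm import (
    Cardinality,
    CodeSystem,
    DataType,
    RegistryError,
    export_registry,
    load_registry,
    registry_schema,
)
from rdcdm.model import SECTION_IDS

EXPECTED_SECTION_SIZES = {
    "1": 2, "2": 5, "3": 6, "4": 4, "5": 9, "6.1": 16, "6.2": 9,
    "6.3": 6, "6.4": 13, "7": 7, "8": 1,
}


def test_section_structure(registry):
    assert registry.version == "2.0.0"
    assert [s.id for s in registry.sections] == list(SECTION_IDS)
    sizes = {s.id: len(s.elements) for s in registry.sections}
    assert sizes == EXPECTED_SECTION_SIZES
    assert len(registry.elements) == 78
    assert len(registry.list_value_sets()) == 39


def test_known_element_codes(registry):
    pseudonym = registry.element("1.1")
    assert pseudonym.data_type == DataType.STRING
    assert any(
        c.system == CodeSystem.SNOMED_CT and c.code == "422549004"
        for c in pseudonym.codes
    )
    vital = registry.element("3.1")
    vs = registry.element_value_set("3.1")
    assert vital.data_type == DataType.CODE
    assert vs.find("419099009").display == "Dead"


def test_recommended_cardinalities(registry):
    assert registry.section("1").recommended_cardinality == Cardinality.ONE_ONE
    assert registry.section("2").recommended_cardinality == Cardinality.ZERO_ONE
    assert registry.section("5").recommended_cardinality == Cardinality.ZERO_MANY


def test_custom_codes_are_namespaced(registry):
    vs = registry.element_value_set("4.4")
    custom = [c for c in vs.choices if c.binding.system == CodeSystem.CUSTOM]
    assert len(custom) == 1
    assert custom[0].binding.code == "rd_cdm:rd_specialist_center"


def test_json_round_trip(registry):
    doc = export_registry(registry, "JSON")
    reloaded = load_registry(doc)
    assert reloaded == registry
    assert export_registry(reloaded, "JSON") == doc


def test_csv_export_has_one_row_per_element(registry):
    rows = list(csv.reader(io.StringIO(export_registry(registry, "CSV"))))
    header, data = rows[0], rows[1:]
    assert header[0] == "Data Element"
    assert len(data) == 78
    by_label = {r[0]: r for r in data}
    row_11 = by_label["1.1 Pseudonym"]
    assert "SNOMEDCT:422549004" in row_11[1]
    assert row_11[5] == "n/a"  # no value set -> concept columns are n/a


def test_load_rejects_duplicate_element_ids(registry):
    doc = json.loads(export_registry(registry, "JSON"))
    first = doc["sections"][0]["elements"]
    first.append(dict(first[0]))
    with pytest.raises(RegistryError):
        load_registry(doc)


def test_load_reports_pointer_for_missing_field(registry):
    doc = json.loads(export_registry(registry, "JSON"))
    del doc["sections"][0]["elements"][0]["data_type"]
    with pytest.raises(RegistryError) as excinfo:
        load_registry(doc)
    assert "data_type" in excinfo.value.pointer


def test_unknown_ids_raise_keyerror(registry):
    with pytest.raises(KeyError):
        registry.element("99.99")
    with pytest.raises(KeyError):
        registry.value_set("vs_nonexistent")


def test_registry_schema_is_json_schema(registry):
    schema = registry_schema()
    assert schema["$schema"].endswith("2020-12/schema")
    assert "sections" in schema.get("properties", {})


def test_value_set_reuse_counts_once_per_host(registry):
    # vs_6_4_3 and vs_6_4_5 carry the same 14 family members but are hosted
    # by distinct elements, so the net choice count includes both uses
    hosts = [
        el.element_id for el in registry.iter_elements()
        if el.value_set_id in ("vs_6_4_3", "vs_6_4_5")
    ]
    assert sorted(hosts) == ["6.4.3", "6.4.5"]
    assert len(registry.value_set("vs_6_4_3").choices) == 14
    assert len(registry.value_set("vs_6_4_5").choices) == 14
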