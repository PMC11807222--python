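"""Layer derivation, conservation, rounding and report rendering."""

import csv
import io
import json

import pytest

from rdcdm import Layer, compute_all, compute_layer, render_report
from rdcdm.harmonisation import LAYER_CATEGORIES, _round_half_up_percent
from rdcdm.model import SECTION_IDS

EXPECTED_TOTALS = {
    Layer.ALIGNMENT: {"FHIR": 19, "GA4GH": 6, "BOTH": 50, "NEITHER": 3},
    Layer.LABELLING: {"ERDRI_CDS": 11, "STANDARD": 52, "CUSTOM": 15},
    Layer.TERMINOLOGY_BINDING: {
        "FHIR_SPEC": 16, "GA4GH_SPEC": 4, "ONTOLOGY": 53, "CUSTOM": 5,
    },
    Layer.DATA_TYPE: {"FHIR": 20, "GA4GH": 4, "BOTH": 43, "NEITHER": 11},
    Layer.VALUE_SET: {
        "VS_FHIR": 12, "VS_GA4GH": 3, "ONTOLOGY_ENCODED": 23, "MIXED": 1,
    },
    Layer.VALUE_SET_CHOICE: {
        "FHIR_CODE": 78, "GA4GH_CODE": 13, "SNOMED": 99, "LOINC": 13,
        "HPO": 23, "NCIT": 0, "CUSTOM": 1,
    },
}


@pytest.mark.parametrize("layer", list(Layer))
def test_layer_totals(registry, layer):
    table = compute_layer(registry, layer)
    assert table.totals == EXPECTED_TOTALS[layer]
    assert table.grand_total == sum(EXPECTED_TOTALS[layer].values())


def test_element_layers_partition_all_elements(registry):
    for layer in (Layer.ALIGNMENT, Layer.LABELLING,
                  Layer.TERMINOLOGY_BINDING, Layer.DATA_TYPE):
        table = compute_layer(registry, layer)
        ids = [
            eid for sid in SECTION_IDS
            for cat in LAYER_CATEGORIES[layer]
            for eid in table.rows[sid][cat]
        ]
        assert len(ids) == 78
        assert len(set(ids)) == 78


def test_value_set_layer_counts_uses_not_sets(registry):
    table = compute_layer(registry, Layer.VALUE_SET)
    assert table.grand_total == 39  # one use per hosting element
    assert table.supplementary["datatype_aligned_value_sets"] == 34


def test_alignment_percentages(registry):
    table = compute_layer(registry, Layer.ALIGNMENT)
    assert table.percents == {"FHIR": 24, "GA4GH": 8, "BOTH": 64, "NEITHER": 4}


@pytest.mark.parametrize("count,total,expected", [
    (1, 3, 33), (2, 3, 67), (1, 8, 13), (1, 200, 1), (0, 5, 0), (5, 5, 100),
    (1, 0, 0),  # degenerate empty population
])
def test_round_half_up(count, total, expected):
    assert _round_half_up_percent(count, total) == expected


def test_reports_are_deterministic(registry):
    tables = compute_all(registry)
    for fmt in ("MD", "CSV", "JSON"):
        assert render_report(tables, fmt) == render_report(compute_all(registry), fmt)


def test_markdown_report_has_sum_and_percent_rows(registry):
    doc = render_report(compute_all(registry), "MD")
    assert "## ALIGNMENT" in doc
    assert "| Sum | 19 | 6 | 50 | 3 | 78 |" in doc
    assert "| % | 24% | 8% | 64% | 4% |" in doc
    assert "Supplementary — elements_with_terminology_codes: 63" in doc


def test_csv_report_is_parseable_and_conserves_counts(registry):
    doc = render_report(compute_all(registry), "CSV")
    rows = list(csv.DictReader(io.StringIO(doc)))
    per_section = sum(
        int(r["count"]) for r in rows
        if r["layer"] == "VALUE_SET_CHOICE" and r["section"] in SECTION_IDS
    )
    grand = [
        int(r["count"]) for r in rows
        if r["layer"] == "VALUE_SET_CHOICE" and r["section"] == "GrandTotal"
    ]
    assert per_section == 227
    assert grand == [227]


def test_json_report_round_trips(registry):
    doc = render_report(compute_all(registry), "JSON")
    parsed = json.loads(doc)
    assert [t["layer"] for t in parsed] == [layer.value for layer in Layer]


def test_unsupported_format_rejected(registry):
    with pytest.raises(ValueError):
        render_report(compute_all(registry), "XML")
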