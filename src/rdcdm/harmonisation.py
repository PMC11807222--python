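"""Six harmonisation layers recomputed from registry metadata.

Layers 1-4 partition the 78 data elements, layer 5 the 39 value sets, and
layer 6 the net 227 value-set choices (a reused value set counts once per
hosting element). Categories are always derived from element/value-set
metadata, never from stored category labels:

- ALIGNMENT: presence of fhir_expression / phenopacket_element (bracketed
  partial mappings and "Suggestion"-flagged extensions count as aligned).
- LABELLING: label_source.
- TERMINOLOGY_BINDING: terminology_source.
- DATA_TYPE: datatype_alignment.
- VALUE_SET: derivation + choice code systems (directly derived sets split
  by their FHIR/GA4GH source; extended/re-encoded sets split into
  ontology-encoded vs mixed-codesystem).
- VALUE_SET_CHOICE: per-choice source_category, summed over every
  element-to-value-set use.

Percentages are round-half-up integers of count/grand_total.
"""

from __future__ import annotations

import enum
import io
import json
import csv
from decimal import Decimal, ROUND_HALF_UP

from pydantic import BaseModel

from .model import (
    Alignment,
    CodeSystem,
    DataType,
    Derivation,
    ModelRegistry,
    SECTION_IDS,
    TerminologySource,
    ValueSet,
)


class Layer(str, enum.Enum):
    ALIGNMENT = "ALIGNMENT"
    LABELLING = "LABELLING"
    TERMINOLOGY_BINDING = "TERMINOLOGY_BINDING"
    DATA_TYPE = "DATA_TYPE"
    VALUE_SET = "VALUE_SET"
    VALUE_SET_CHOICE = "VALUE_SET_CHOICE"


LAYER_CATEGORIES: dict[Layer, list[str]] = {
    Layer.ALIGNMENT: ["FHIR", "GA4GH", "BOTH", "NEITHER"],
    Layer.LABELLING: ["ERDRI_CDS", "STANDARD", "CUSTOM"],
    Layer.TERMINOLOGY_BINDING: ["FHIR_SPEC", "GA4GH_SPEC", "ONTOLOGY", "CUSTOM"],
    Layer.DATA_TYPE: ["FHIR", "GA4GH", "BOTH", "NEITHER"],
    Layer.VALUE_SET: ["VS_FHIR", "VS_GA4GH", "ONTOLOGY_ENCODED", "MIXED"],
    Layer.VALUE_SET_CHOICE: [
        "FHIR_CODE", "GA4GH_CODE", "SNOMED", "LOINC", "HPO", "NCIT", "CUSTOM",
    ],
}

#: ontology families usable for re-encoding value-set choices
_ONTOLOGY_SYSTEMS = {
    CodeSystem.SNOMED_CT, CodeSystem.LOINC, CodeSystem.HPO, CodeSystem.NCIT,
}


class LayerTable(BaseModel):
    layer: Layer
    #: section id -> category -> identifiers (element/value-set ids, or
    #: "element_id:choice_code" for the choice layer)
    rows: dict[str, dict[str, list[str]]]
    totals: dict[str, int]
    percents: dict[str, int]
    grand_total: int
    #: layer-specific extra figures (e.g. elements carrying terminology codes)
    supplementary: dict[str, int] = {}


def _round_half_up_percent(count: int, total: int) -> int:
    if total == 0:
        return 0
    return int(
        (Decimal(100 * count) / Decimal(total)).quantize(0, rounding=ROUND_HALF_UP)
    )


def value_set_category(vs: ValueSet) -> str:
    """Derive the layer-5 category of a value set from its metadata."""
    if vs.derivation == Derivation.VS:
        systems = {c.binding.system for c in vs.choices}
        return "VS_GA4GH" if systems == {CodeSystem.GA4GH} else "VS_FHIR"
    systems = {c.binding.system for c in vs.choices}
    if systems <= _ONTOLOGY_SYSTEMS:
        return "ONTOLOGY_ENCODED"
    return "MIXED"


def _element_category(el, layer: Layer) -> str:
    if layer == Layer.ALIGNMENT:
        return el.alignment.value
    if layer == Layer.LABELLING:
        return el.label_source.value
    if layer == Layer.TERMINOLOGY_BINDING:
        return el.terminology_source.value
    if layer == Layer.DATA_TYPE:
        return el.datatype_alignment.value
    raise ValueError(layer)


def datatype_aligned_value_sets(registry: ModelRegistry) -> list[str]:
    """Value sets whose encoding is consistent with a coded data type of at
    least one standard, by cross-referencing hosts' data-type alignment.

    A host element that is datatype-aligned with FHIR and/or the Phenopacket
    Schema qualifies directly. A BOOLEAN host with a two-choice value set
    also qualifies: its yes/no set bijects onto the standards' native
    boolean type even though the element's own datatype flag is NEITHER.
    """
    out = []
    for el in registry.iter_elements():
        if not el.value_set_id:
            continue
        vs = registry.value_set(el.value_set_id)
        if el.datatype_alignment != Alignment.NEITHER:
            out.append(vs.id)
        elif el.data_type == DataType.BOOLEAN and len(vs.choices) == 2:
            out.append(vs.id)
    return out


def elements_with_terminology_codes(registry: ModelRegistry) -> list[str]:
    """Ontology-bound elements plus standard-spec elements that additionally
    carry a clinical terminology code (reported as a supplementary figure)."""
    out = []
    for el in registry.iter_elements():
        if el.terminology_source == TerminologySource.ONTOLOGY:
            out.append(el.element_id)
        elif el.terminology_source in (
            TerminologySource.FHIR_SPEC, TerminologySource.GA4GH_SPEC
        ) and any(c.system in _ONTOLOGY_SYSTEMS for c in el.codes):
            out.append(el.element_id)
    return out


def compute_layer(registry: ModelRegistry, layer: Layer) -> LayerTable:
    categories = LAYER_CATEGORIES[layer]
    rows: dict[str, dict[str, list[str]]] = {
        sid: {c: [] for c in categories} for sid in SECTION_IDS
    }
    supplementary: dict[str, int] = {}

    if layer in (
        Layer.ALIGNMENT, Layer.LABELLING, Layer.TERMINOLOGY_BINDING, Layer.DATA_TYPE
    ):
        for el in registry.iter_elements():
            rows[el.section_id][_element_category(el, layer)].append(el.element_id)
        if layer == Layer.TERMINOLOGY_BINDING:
            supplementary["elements_with_terminology_codes"] = len(
                elements_with_terminology_codes(registry)
            )
    elif layer == Layer.VALUE_SET:
        for el in registry.iter_elements():
            if el.value_set_id:
                vs = registry.value_set(el.value_set_id)
                rows[el.section_id][value_set_category(vs)].append(vs.id)
        supplementary["datatype_aligned_value_sets"] = len(
            datatype_aligned_value_sets(registry)
        )
    elif layer == Layer.VALUE_SET_CHOICE:
        # net total: a reused value set is counted once per hosting element
        for el in registry.iter_elements():
            if el.value_set_id:
                vs = registry.value_set(el.value_set_id)
                for choice in vs.choices:
                    rows[el.section_id][choice.source_category.value].append(
                        f"{el.element_id}:{choice.binding.code}"
                    )
    else:
        raise ValueError(f"unknown layer {layer}")

    totals = {
        c: sum(len(rows[sid][c]) for sid in SECTION_IDS) for c in categories
    }
    grand_total = sum(totals.values())
    percents = {
        c: _round_half_up_percent(totals[c], grand_total) for c in categories
    }
    return LayerTable(
        layer=layer, rows=rows, totals=totals, percents=percents,
        grand_total=grand_total, supplementary=supplementary,
    )


def compute_all(registry: ModelRegistry) -> list[LayerTable]:
    return [compute_layer(registry, layer) for layer in Layer]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_report(tables: list[LayerTable], format: str = "MARKDOWN") -> str:
    fmt = format.upper()
    if fmt in ("MARKDOWN", "MD"):
        return _render_markdown(tables)
    if fmt == "CSV":
        return _render_csv(tables)
    if fmt == "JSON":
        return json.dumps(
            [t.model_dump(mode="json") for t in tables], indent=2, sort_keys=True
        )
    raise ValueError(f"unsupported report format: {format!r}")


def _render_markdown(tables: list[LayerTable]) -> str:
    out: list[str] = []
    for t in tables:
        cats = LAYER_CATEGORIES[t.layer]
        out.append(f"## {t.layer.value}")
        out.append("")
        out.append("| Section | " + " | ".join(cats) + " | Σ |")
        out.append("|" + "---|" * (len(cats) + 2))
        for sid in SECTION_IDS:
            counts = [len(t.rows[sid][c]) for c in cats]
            out.append(
                f"| {sid} | " + " | ".join(str(n) for n in counts)
                + f" | {sum(counts)} |"
            )
        out.append(
            "| Sum | " + " | ".join(str(t.totals[c]) for c in cats)
            + f" | {t.grand_total} |"
        )
        out.append(
            "| % | " + " | ".join(f"{t.percents[c]}%" for c in cats) + " |  |"
        )
        for key, value in sorted(t.supplementary.items()):
            out.append("")
            out.append(f"Supplementary — {key}: {value}")
        out.append("")
    return "\n".join(out)


def _render_csv(tables: list[LayerTable]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["layer", "section", "category", "count", "identifiers"])
    for t in tables:
        cats = LAYER_CATEGORIES[t.layer]
        for sid in SECTION_IDS:
            for c in cats:
                ids = t.rows[sid][c]
                writer.writerow(
                    [t.layer.value, sid, c, len(ids), ";".join(ids)]
                )
        for c in cats:
            writer.writerow([t.layer.value, "Sum", c, t.totals[c], ""])
            writer.writerow(
                [t.layer.value, "%", c, t.percents[c], ""]
            )
        writer.writerow([t.layer.value, "GrandTotal", "", t.grand_total, ""])
    return buf.getvalue()
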