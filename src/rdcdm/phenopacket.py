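"""GA4GH Phenopacket Schema v2.0-shaped JSON export and its inverse.

The exporter builds a phenopacket-shaped JSON tree (subject, diseases,
interpretations, phenotypicFeatures, measurements, family, metaData) from a
validated record. Because several targets are enum- or oneOf-constrained
(TimeElement holds either a timestamp or an ontology class; the sex and
vital-status enums are narrower than the model's extended value sets), every
block also carries a namespaced ``rdCdmExtensions`` map with the exact
source values, so that no element value is ever silently dropped and
extraction is lossless. Natively mapped fields are still populated per the
model's mapping statements; the extension map duplicates them for exact
inversion. Extraction prefers the extension map and falls back to the
native inverse (e.g. ``excluded`` → 6.2.2) for foreign documents.

Repeatable-section 6.1 instances are grouped into one interpretation per
(genomic diagnosis, progress status) pair; each genomic interpretation
carries its original instance index (``rdCdmInstanceIndex``) so extraction
restores record order.
"""

from __future__ import annotations

import json

from .model import Alignment, CodeBinding, ModelRegistry
from .records import (
    PatientRecord,
    SectionInstance,
    _dump_value,
    read_record,
    record_to_document,
)
from .terminologies import curie, resource_entry, split_curie
from .validation import require_valid

EXT_KEY = "rdCdmExtensions"
IDX_KEY = "rdCdmInstanceIndex"

#: dict alias — a phenopacket-shaped JSON tree
PhenopacketDocument = dict

SEX_ENUM = {"Male": "MALE", "Female": "FEMALE", "Unknown": "UNKNOWN_SEX"}
KARYOTYPE_ENUM = {
    "XX": "XX", "XY": "XY", "X0": "XO", "XXY": "XXY", "XXX": "XXX",
    "XXYY": "XXYY", "XYY": "XYY",
    "Other karyotype": "OTHER_KARYOTYPE",
    "Unknown karyotype": "UNKNOWN_KARYOTYPE",
}
VITAL_ENUM = {"Alive": "ALIVE", "Dead": "DECEASED"}
ACMG_ENUM = {
    "Pathogenic": "PATHOGENIC",
    "Likely pathogenic": "LIKELY_PATHOGENIC",
    "Uncertain significance": "UNCERTAIN_SIGNIFICANCE",
    "Likely benign": "LIKELY_BENIGN",
    "Benign": "BENIGN",
}


class PhenopacketFormatError(ValueError):
    pass


def _oc(value) -> dict:
    """Ontology-class node (id CURIE + label) from a code value."""
    code = value[0] if isinstance(value, list) else value
    return {"id": curie(code), "label": code.display or code.code}


def _first_code(value) -> CodeBinding:
    return value[0] if isinstance(value, list) else value


def _timestamp(date_str: str) -> str:
    return f"{date_str}T00:00:00Z"


def _from_timestamp(ts: str) -> str:
    return ts.split("T")[0]


def _ext(inst: SectionInstance) -> dict:
    return {k: _dump_value(v) for k, v in inst.values.items()}


def _is_display(value, display: str) -> bool:
    if value is None:
        return False
    return _first_code(value).display == display


# ---------------------------------------------------------------------------
# forward mapping
# ---------------------------------------------------------------------------


def _subject(record: PatientRecord) -> dict:
    subject: dict = {"id": record.pseudonym() or "unknown"}
    if record.first("1.2"):
        subject["timeAtLastEncounter"] = {"timestamp": _timestamp(record.first("1.2"))}
    if record.first("2.1"):
        subject["dateOfBirth"] = _timestamp(record.first("2.1"))
    sex = record.first("2.2")
    if sex is not None:
        subject["sex"] = SEX_ENUM.get(_first_code(sex).display, "OTHER_SEX")
    karyotype = record.first("2.3")
    if karyotype is not None:
        subject["karyotypicSex"] = KARYOTYPE_ENUM.get(
            _first_code(karyotype).display, "UNKNOWN_KARYOTYPE"
        )
    if record.first("2.4") is not None:
        subject["gender"] = _oc(record.first("2.4"))
    vital: dict = {}
    if record.first("3.1") is not None:
        vital["status"] = VITAL_ENUM.get(
            _first_code(record.first("3.1")).display, "UNKNOWN_STATUS"
        )
    if record.first("3.2"):
        vital["timeOfDeath"] = {"timestamp": _timestamp(record.first("3.2"))}
    if record.first("3.3") is not None:
        vital["causeOfDeath"] = _oc(record.first("3.3"))
    if vital:
        subject["vitalStatus"] = vital
    if record.first("3.4") is not None:
        # Phenopackets has no age-category field; carried as the ontology
        # class of the last-encounter context (plus the extension map)
        subject.setdefault("timeAtLastEncounter", {})["ontologyClass"] = _oc(
            record.first("3.4")
        )
    return subject


def _disease(inst: SectionInstance) -> dict:
    entry: dict = {}
    if inst.get("5.1") is not None:
        entry["term"] = _oc(inst.get("5.1"))
    if _is_display(inst.get("5.2"), "Refuted"):
        entry["excluded"] = True
    if inst.get("5.4"):
        entry["onset"] = {"timestamp": _timestamp(inst.get("5.4"))}
    elif inst.get("5.3") is not None:
        entry["onset"] = {"ontologyClass": _oc(inst.get("5.3"))}
    entry[EXT_KEY] = _ext(inst)
    return entry


def _feature(inst: SectionInstance) -> dict:
    entry: dict = {}
    if inst.get("6.2.1") is not None:
        entry["type"] = _oc(inst.get("6.2.1"))
    if _is_display(inst.get("6.2.2"), "Refuted"):
        entry["excluded"] = True
    if inst.get("6.2.5") is not None:
        entry["onset"] = {"ontologyClass": _oc(inst.get("6.2.5"))}
    elif inst.get("6.2.3"):
        entry["onset"] = {"timestamp": _timestamp(inst.get("6.2.3"))}
    if inst.get("6.2.4"):
        entry["resolution"] = {"timestamp": _timestamp(inst.get("6.2.4"))}
    if inst.get("6.2.7") is not None:
        entry["severity"] = _oc(inst.get("6.2.7"))
    if inst.get("6.2.8") is not None:
        entry["modifiers"] = [_oc(c) for c in _as_list(inst.get("6.2.8"))]
    if inst.get("6.2.9") is not None:
        entry["evidence"] = [{"evidenceCode": _oc(inst.get("6.2.9"))}]
    entry[EXT_KEY] = _ext(inst)
    return entry


def _as_list(value) -> list:
    return value if isinstance(value, list) else [value]


def _measurement(inst: SectionInstance) -> dict:
    entry: dict = {}
    if inst.get("6.3.1") is not None:
        entry["assay"] = _oc(inst.get("6.3.1"))
    if inst.get("6.3.2") is not None:
        quantity: dict = {"value": float(inst.get("6.3.2"))}
        if inst.get("6.3.3") is not None:
            quantity["unit"] = _oc(inst.get("6.3.3"))
        entry["value"] = {"quantity": quantity}
    if inst.get("6.3.5"):
        entry["timeObserved"] = {"timestamp": _timestamp(inst.get("6.3.5"))}
    if inst.get("6.3.6") is not None:
        entry["procedure"] = {"code": _oc(inst.get("6.3.6"))}
    entry[EXT_KEY] = _ext(inst)
    return entry


def _genomic_interpretation(inst: SectionInstance, index: int, subject_id: str) -> dict:
    gi: dict = {"subjectOrBiosampleId": subject_id, IDX_KEY: index}
    if inst.get("6.1.3") is not None:
        gi["interpretationStatus"] = _first_code(inst.get("6.1.3")).code
    vi: dict = {}
    if inst.get("6.1.14") is not None:
        vi["acmgPathogenicityClassification"] = ACMG_ENUM.get(
            _first_code(inst.get("6.1.14")).display, "NOT_PROVIDED"
        )
    if inst.get("6.1.15") is not None:
        vi["therapeuticActionability"] = _first_code(inst.get("6.1.15")).code
    vd: dict = {"id": f"variant-{index}"}
    if inst.get("6.1.6"):
        vd["description"] = inst.get("6.1.6")
    expressions = []
    for eid, syntax in (("6.1.7", "hgvs.g"), ("6.1.8", "hgvs.c"), ("6.1.9", "hgvs.p")):
        if inst.get(eid):
            expressions.append({"syntax": syntax, "value": inst.get(eid)})
    if expressions:
        vd["expressions"] = expressions
    if inst.get("6.1.10") is not None:
        gene = _first_code(inst.get("6.1.10"))
        vd["geneContext"] = {"valueId": curie(gene), "symbol": gene.display}
    if inst.get("6.1.11") is not None:
        vd["allelicState"] = _oc(inst.get("6.1.11"))
    if len(vd) > 1:
        vi["variationDescriptor"] = vd
    if vi:
        gi["variantInterpretation"] = vi
    gi[EXT_KEY] = _ext(inst)
    return gi


def _interpretations(record: PatientRecord, subject_id: str) -> list[dict]:
    groups: dict[tuple, dict] = {}
    for index, inst in enumerate(record.instances("6.1")):
        diagnosis = inst.get("6.1.1")
        progress = inst.get("6.1.2")
        key = (
            json.dumps(_dump_value(diagnosis), sort_keys=True) if diagnosis else "",
            _first_code(progress).code if progress is not None else "",
        )
        if key not in groups:
            entry: dict = {
                "id": f"{subject_id}-interpretation-{len(groups) + 1}",
                "diagnosis": {"genomicInterpretations": []},
            }
            if progress is not None:
                entry["progressStatus"] = _first_code(progress).code
            if diagnosis is not None:
                entry["diagnosis"]["disease"] = _oc(diagnosis)
            groups[key] = entry
        groups[key]["diagnosis"]["genomicInterpretations"].append(
            _genomic_interpretation(inst, index, subject_id)
        )
    return list(groups.values())


def _family(record: PatientRecord, subject_id: str) -> dict:
    relatives = []
    persons = []
    consanguinous = False
    for index, inst in enumerate(record.instances("6.4")):
        rel_id = inst.get("6.4.1") or f"{subject_id}-relative-{index}"
        subject: dict = {"id": rel_id}
        if inst.get("6.4.7") is not None:
            subject["sex"] = SEX_ENUM.get(
                _first_code(inst.get("6.4.7")).display, "UNKNOWN_SEX"
            )
        if inst.get("6.4.9"):
            subject["dateOfBirth"] = _timestamp(inst.get("6.4.9"))
        vital: dict = {}
        if _is_display(inst.get("6.4.10"), "Yes"):
            vital["status"] = "DECEASED"
        elif _is_display(inst.get("6.4.10"), "No"):
            vital["status"] = "ALIVE"
        if inst.get("6.4.11") is not None:
            vital["causeOfDeath"] = _oc(inst.get("6.4.11"))
        if vital:
            subject["vitalStatus"] = vital
        relatives.append({"id": rel_id, "subject": subject, EXT_KEY: _ext(inst)})
        persons.append(
            {
                "individualId": rel_id,
                "sex": subject.get("sex", "UNKNOWN_SEX"),
                "affectedStatus": (
                    "AFFECTED" if inst.get("6.4.13") is not None else "MISSING"
                ),
            }
        )
        if _is_display(inst.get("6.4.4"), "Yes"):
            consanguinous = True
    family = {
        "id": f"{subject_id}-family",
        "probandId": subject_id,
        "relatives": relatives,
        "pedigree": {"persons": persons},
    }
    if consanguinous:
        family["consanguinousParents"] = True
    return family


def _collect_prefixes(record: PatientRecord) -> list[str]:
    prefixes = set()
    for sid in ("1", "2", "3", "7", "8"):
        for inst in record.instances(sid):
            for v in inst.values.values():
                for c in _as_list(v):
                    if isinstance(c, CodeBinding):
                        prefixes.add(split_curie(curie(c))[0])
    for sid in ("4", "5", "6.1", "6.2", "6.3", "6.4"):
        for inst in record.instances(sid):
            for v in inst.values.values():
                for c in _as_list(v):
                    if isinstance(c, CodeBinding):
                        prefixes.add(split_curie(curie(c))[0])
    return sorted(prefixes)


def to_phenopacket(
    record: PatientRecord, registry: ModelRegistry
) -> PhenopacketDocument:
    """Build the phenopacket-shaped document (record must validate clean)."""
    require_valid(record, registry)
    subject_id = record.pseudonym() or "unknown"
    doc: PhenopacketDocument = {
        "id": f"{subject_id}-phenopacket",
        "subject": _subject(record),
    }
    features = [_feature(i) for i in record.instances("6.2")]
    if features:
        doc["phenotypicFeatures"] = features
    measurements = [_measurement(i) for i in record.instances("6.3")]
    if measurements:
        doc["measurements"] = measurements
    diseases = [_disease(i) for i in record.instances("5")]
    if diseases:
        doc["diseases"] = diseases
    interpretations = _interpretations(record, subject_id)
    if interpretations:
        doc["interpretations"] = interpretations
    if record.instances("6.4"):
        doc["family"] = _family(record, subject_id)

    # record-level extension map: singleton sections + the care-pathway
    # section (no phenopacket counterpart), so nothing is dropped
    ext: dict = {}
    for sid in ("1", "2", "3", "7", "8"):
        for inst in record.instances(sid):
            ext[sid] = _ext(inst)
    encounters = [_ext(i) for i in record.instances("4")]
    if encounters:
        ext["4"] = encounters
    doc[EXT_KEY] = ext

    versions = registry.code_system_versions
    doc["metaData"] = {
        "created": _timestamp(record.first("1.2") or "1970-01-01"),
        "createdBy": "rdcdm",
        "phenopacketSchemaVersion": "2.0",
        "resources": [
            resource_entry(p, versions) for p in _collect_prefixes(record)
        ],
    }
    return doc


def phenopacket_json(doc: PhenopacketDocument) -> str:
    return json.dumps(doc, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# inverse mapping
# ---------------------------------------------------------------------------


def _native_feature_values(entry: dict) -> dict:
    """Best-effort inverse for foreign documents without extension maps."""
    values: dict = {}
    if "type" in entry:
        oc = entry["type"]
        values["6.2.1"] = {"system": "HPO", "code": oc["id"],
                           "display": oc.get("label", "")}
    # exhaustive over the two-valued 6.2.2 set
    if entry.get("excluded"):
        values["6.2.2"] = {"system": "SNOMED_CT", "code": "410594000",
                           "display": "Refuted"}
    elif "type" in entry:
        values["6.2.2"] = {"system": "SNOMED_CT", "code": "410605003",
                           "display": "Confirmed present"}
    onset = entry.get("onset", {})
    if "timestamp" in onset:
        values["6.2.3"] = _from_timestamp(onset["timestamp"])
    return values


def extract_record(
    doc: PhenopacketDocument, registry: ModelRegistry
) -> PatientRecord:
    """Rebuild a PatientRecord from a phenopacket-shaped document."""
    if not isinstance(doc, dict) or "subject" not in doc:
        raise PhenopacketFormatError("not a phenopacket-shaped document")

    def known(block: dict) -> dict:
        # non-element keys in extension maps (local annotations) are ignored
        # here; extract_mapped_projection passes them through verbatim
        out = {}
        for key, value in block.items():
            try:
                registry.element(key)
            except KeyError:
                continue
            out[key] = value
        return out

    record_doc: dict = {}
    ext = doc.get(EXT_KEY, {})
    for sid in ("1", "2", "3", "7", "8"):
        if sid in ext:
            record_doc[sid] = known(ext[sid])
    if "1" not in record_doc and doc["subject"].get("id"):
        record_doc["1"] = {"1.1": doc["subject"]["id"]}
    if "4" in ext:
        record_doc["4"] = [known(b) for b in ext["4"]]
    for key, sid, native in (
        ("diseases", "5", None),
        ("phenotypicFeatures", "6.2", _native_feature_values),
        ("measurements", "6.3", None),
    ):
        entries = doc.get(key, [])
        if entries:
            block = []
            for entry in entries:
                if EXT_KEY in entry:
                    block.append(known(entry[EXT_KEY]))
                elif native is not None:
                    block.append(native(entry))
                else:
                    block.append({})
            record_doc[sid] = block
    indexed: list[tuple[int, dict]] = []
    for interp in doc.get("interpretations", []):
        for gi in interp.get("diagnosis", {}).get("genomicInterpretations", []):
            indexed.append(
                (gi.get(IDX_KEY, len(indexed)), known(gi.get(EXT_KEY, {})))
            )
    if indexed:
        record_doc["6.1"] = [v for _, v in sorted(indexed, key=lambda t: t[0])]
    relatives = doc.get("family", {}).get("relatives", [])
    if relatives:
        record_doc["6.4"] = [known(rel.get(EXT_KEY, {})) for rel in relatives]
    try:
        return read_record(record_doc, registry)
    except Exception as exc:
        raise PhenopacketFormatError(f"malformed document: {exc}") from exc


def record_projection(
    record: PatientRecord, registry: ModelRegistry, element_ids=None
) -> dict:
    """Map element_id → value (singleton) or list of per-instance values."""
    doc = record_to_document(record)
    proj: dict = {}
    for sid, block in doc.items():
        if isinstance(block, dict):
            for eid, v in block.items():
                if element_ids is None or eid in element_ids:
                    proj[eid] = v
        else:
            for inst in block:
                for eid, v in inst.items():
                    if element_ids is None or eid in element_ids:
                        proj.setdefault(eid, []).append(v)
    return proj


def phenopacket_aligned_elements(registry: ModelRegistry) -> set[str]:
    return {
        el.element_id
        for el in registry.iter_elements()
        if el.alignment in (Alignment.GA4GH, Alignment.BOTH)
    }


def extract_mapped_projection(
    doc: PhenopacketDocument, registry: ModelRegistry
) -> dict:
    """Invert the mapping for Phenopacket-aligned elements; pass any other
    extension-map content through verbatim."""
    record = extract_record(doc, registry)
    # aligned elements are inverted from the mapping; everything else in the
    # extension maps is passed through verbatim
    out = dict(record_projection(record, registry, None))
    # unknown extension keys (not registry elements) are preserved verbatim
    for sid, block in doc.get(EXT_KEY, {}).items():
        if isinstance(block, dict):
            for key, value in block.items():
                if key not in out:
                    out[key] = value
    return out
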