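"""HL7 FHIR R4 (v4.0.1)-shaped resource JSON export.

One Patient per record; one Encounter per section-4 instance; one Condition
per section-5 instance; one FamilyMemberHistory per section-6.4 instance;
one Consent per record; Observations for karyotypic sex (2.3), age category
(3.4), gestation (3.5), undiagnosed flag (3.6), disability (8.1), each
phenotypic finding (6.2), measurement (6.3) and variant (6.1, genomics-style
component Observation). Elements with no FHIR expression in the registry
(the Phenopacket-only and neither-aligned ones) are listed in an
``unmapped`` manifest rather than silently dropped. "Suggestion"-flagged and
partial mappings use namespaced extension URLs (urn:rd-cdm:extension:<id>).

Output is a flat resource array (no Bundle transaction semantics); custom
codes are emitted with system "rd_cdm" and their bare code (e.g.
``rd_specialist_center``).
"""

from __future__ import annotations

import json

from pydantic import BaseModel

from .model import CodeBinding, CodeSystem, ModelRegistry, CUSTOM_CODE_PREFIX
from .records import PatientRecord, SectionInstance, _dump_value
from .validation import Severity, ValidationIssue, require_valid

ALLOWED_RESOURCE_TYPES = {
    "Patient", "Encounter", "Condition", "Observation",
    "FamilyMemberHistory", "Consent",
}

EXT_URL = "urn:rd-cdm:extension:"

SYSTEM_URI = {
    CodeSystem.SNOMED_CT: "http://snomed.info/sct",
    CodeSystem.LOINC: "http://loinc.org",
    CodeSystem.HPO: "http://purl.obolibrary.org/obo/hp.owl",
    CodeSystem.NCIT: "http://purl.obolibrary.org/obo/ncit.owl",
    CodeSystem.ICD10: "http://hl7.org/fhir/sid/icd-10",
    CodeSystem.ICD11: "http://id.who.int/icd/release/11/mms",
    CodeSystem.ORDO: "http://www.orpha.net/ORDO",
    CodeSystem.MONDO: "http://purl.obolibrary.org/obo/mondo.owl",
    CodeSystem.OMIM_P: "https://www.omim.org",
    CodeSystem.OMIM_G: "https://www.omim.org",
    CodeSystem.HGNC: "http://www.genenames.org",
    CodeSystem.HGVS: "http://varnomen.hgvs.org",
    CodeSystem.NCBITAXON: "http://purl.obolibrary.org/obo/ncbitaxon.owl",
    CodeSystem.UO: "http://purl.obolibrary.org/obo/uo.owl",
    CodeSystem.ECO: "http://purl.obolibrary.org/obo/eco.owl",
    CodeSystem.ISO3166: "urn:iso:std:iso:3166",
    CodeSystem.ICF: "http://hl7.org/fhir/sid/icf",
    CodeSystem.GA4GH: "https://phenopacket-schema.readthedocs.io",
    CodeSystem.HL7FHIR: "http://hl7.org/fhir",
    CodeSystem.CUSTOM: "rd_cdm",
}

GENDER_MAP = {
    "Male gender": "male", "Female gender": "female",
    "Non-binary gender": "other", "Other gender": "other",
    "Unknown": "unknown",
}


class FhirResourceSet(BaseModel):
    resources: list[dict]
    #: populated element values with no FHIR expression in the registry
    unmapped: list[dict]

    def by_type(self, resource_type: str) -> list[dict]:
        return [r for r in self.resources if r.get("resourceType") == resource_type]


def _coding(binding: CodeBinding) -> dict:
    code = binding.code
    if binding.system == CodeSystem.CUSTOM and code.startswith(CUSTOM_CODE_PREFIX):
        code = code[len(CUSTOM_CODE_PREFIX):]
    out = {"system": SYSTEM_URI[binding.system], "code": code}
    if binding.display:
        out["display"] = binding.display
    return out


def _codeable(value) -> dict:
    codes = value if isinstance(value, list) else [value]
    return {"coding": [_coding(c) for c in codes]}


def _ext(eid: str, value) -> dict:
    dumped = _dump_value(value)
    entry: dict = {"url": EXT_URL + eid}
    if isinstance(dumped, str):
        entry["valueString"] = dumped
    elif isinstance(dumped, bool):
        entry["valueBoolean"] = dumped
    elif isinstance(dumped, int):
        entry["valueInteger"] = dumped
    else:
        entry["valueCodeableConcept"] = _codeable(value)
    return entry


def _code_of(value) -> str:
    code = value[0] if isinstance(value, list) else value
    return code.code


def _display_of(value) -> str:
    code = value[0] if isinstance(value, list) else value
    return code.display


def _element_code_concept(registry: ModelRegistry, eid: str) -> dict:
    el = registry.element(eid)
    if el.codes:
        return {"coding": [_coding(c) for c in el.codes]}
    return {"text": el.label}


def _observation(registry, eid: str, pid: str, suffix: str) -> dict:
    return {
        "resourceType": "Observation",
        "id": f"{pid}-obs-{suffix}",
        "status": "final",
        "code": _element_code_concept(registry, eid),
        "subject": {"reference": f"Patient/{pid}"},
    }


def _component(registry, inst: SectionInstance, eid: str) -> dict | None:
    value = inst.get(eid)
    if value is None:
        return None
    comp = {"code": _element_code_concept(registry, eid)}
    el = registry.element(eid)
    if el.data_type.value == "CODE":
        comp["valueCodeableConcept"] = _codeable(value)
    elif isinstance(value, bool):
        comp["valueBoolean"] = value
    elif isinstance(value, int):
        comp["valueInteger"] = value
    else:
        comp["valueString"] = value
    return comp


def to_fhir(record: PatientRecord, registry: ModelRegistry) -> FhirResourceSet:
    """Convert a validation-clean record to a FHIR R4 resource array."""
    require_valid(record, registry)
    pid = record.pseudonym() or "unknown"
    subject_ref = {"reference": f"Patient/{pid}"}
    resources: list[dict] = []

    # ----- Patient ---------------------------------------------------------
    patient: dict = {
        "resourceType": "Patient",
        "id": pid,
        "identifier": [{"value": pid}],
    }
    if record.first("2.1"):
        patient["birthDate"] = record.first("2.1")
    gender = record.first("2.4")
    if gender is not None:
        patient["gender"] = GENDER_MAP.get(_display_of(gender), "other")
    if record.first("3.2"):
        patient["deceasedDateTime"] = record.first("3.2")
    elif record.first("3.1") is not None:
        display = _display_of(record.first("3.1"))
        if display == "Dead":
            patient["deceasedBoolean"] = True
        elif display == "Alive":
            patient["deceasedBoolean"] = False
        # Lost to follow-up / Unknown: boolean cannot encode it -> extension
    extensions = []
    if record.first("2.5") is not None:
        extensions.append(
            {
                "url": "http://hl7.org/fhir/StructureDefinition/patient-birthPlace",
                "valueAddress": {"country": _code_of(record.first("2.5"))},
            }
        )
    if record.first("3.1") is not None:
        extensions.append(_ext("3.1", record.first("3.1")))
    if record.first("3.3") is not None:
        extensions.append(_ext("3.3", record.first("3.3")))  # Suggestion-flagged
    if record.first("1.2"):
        extensions.append(_ext("1.2", record.first("1.2")))
    if extensions:
        patient["extension"] = extensions
    resources.append(patient)

    # ----- simple Observations --------------------------------------------
    for eid, suffix in (("2.3", "karyotypic-sex"), ("3.4", "age-category")):
        value = record.first(eid)
        if value is not None:
            obs = _observation(registry, eid, pid, suffix)
            obs["valueCodeableConcept"] = _codeable(value)
            resources.append(obs)
    if record.first("3.5") is not None:
        obs = _observation(registry, "3.5", pid, "gestation")
        obs["valueString"] = record.first("3.5")
        resources.append(obs)
    if record.first("3.6") is not None:
        obs = _observation(registry, "3.6", pid, "undiagnosed")
        obs["valueBoolean"] = record.first("3.6")
        resources.append(obs)
    if record.first("8.1") is not None:
        obs = {
            "resourceType": "Observation",
            "id": f"{pid}-obs-icf",
            "status": "final",
            "code": {"coding": [{"system": "rd_cdm", "code": "icf_score"}]},
            "subject": subject_ref,
            "valueCodeableConcept": _codeable(record.first("8.1")),
        }
        resources.append(obs)

    # ----- Encounters ------------------------------------------------------
    for idx, inst in enumerate(record.instances("4")):
        enc: dict = {
            "resourceType": "Encounter",
            "id": f"{pid}-encounter-{idx}",
            "subject": subject_ref,
        }
        if inst.get("4.3") is not None:
            enc["status"] = _code_of(inst.get("4.3"))
        if inst.get("4.4") is not None:
            enc["class"] = _coding(inst.get("4.4"))
        period = {}
        if inst.get("4.1"):
            period["start"] = inst.get("4.1")
        if inst.get("4.2"):
            period["end"] = inst.get("4.2")
        if period:
            enc["period"] = period
        resources.append(enc)

    # ----- Conditions ------------------------------------------------------
    for idx, inst in enumerate(record.instances("5")):
        cond: dict = {
            "resourceType": "Condition",
            "id": f"{pid}-condition-{idx}",
            "subject": subject_ref,
        }
        if inst.get("5.1") is not None:
            cond["code"] = _codeable(inst.get("5.1"))
        if inst.get("5.2") is not None:
            cond["verificationStatus"] = _codeable(inst.get("5.2"))
        if inst.get("5.4"):
            cond["onsetDateTime"] = inst.get("5.4")
        if inst.get("5.6"):
            cond["recordedDate"] = inst.get("5.6")
        if inst.get("5.7") is not None:
            cond["bodySite"] = [_codeable(inst.get("5.7"))]
        if inst.get("5.8") is not None:
            cond["clinicalStatus"] = _codeable(inst.get("5.8"))
        if inst.get("5.9") is not None:
            cond["severity"] = _codeable(inst.get("5.9"))
        extensions = [
            _ext(eid, inst.get(eid))
            for eid in ("5.3", "5.5")
            if inst.get(eid) is not None
        ]
        if extensions:
            cond["extension"] = extensions
        resources.append(cond)

    # ----- genomic Observations (one per 6.1 instance) ----------------------
    for idx, inst in enumerate(record.instances("6.1")):
        obs = {
            "resourceType": "Observation",
            "id": f"{pid}-variant-{idx}",
            "status": "final",
            "code": {
                "coding": [{"system": "http://loinc.org", "code": "69548-6",
                            "display": "Genetic variant assessment"}]
            },
            "subject": subject_ref,
        }
        if inst.get("6.1.4") is not None:
            obs["method"] = _codeable(inst.get("6.1.4"))
        if inst.get("6.1.6") is not None:
            obs["valueString"] = inst.get("6.1.6")
        components = []
        for eid in ("6.1.1", "6.1.5", "6.1.7", "6.1.8", "6.1.9", "6.1.10",
                    "6.1.11", "6.1.12", "6.1.13", "6.1.14", "6.1.16"):
            comp = _component(registry, inst, eid)
            if comp is not None:
                components.append(comp)
        if components:
            obs["component"] = components
        resources.append(obs)

    # ----- phenotype Observations ------------------------------------------
    for idx, inst in enumerate(record.instances("6.2")):
        obs = {
            "resourceType": "Observation",
            "id": f"{pid}-phenotype-{idx}",
            "status": "final",
            "subject": subject_ref,
        }
        if inst.get("6.2.1") is not None:
            obs["code"] = _codeable(inst.get("6.2.1"))
        else:
            obs["code"] = _element_code_concept(registry, "6.2.1")
        if inst.get("6.2.2") is not None:
            obs["valueCodeableConcept"] = _codeable(inst.get("6.2.2"))
        if inst.get("6.2.3"):
            obs["effectiveDateTime"] = inst.get("6.2.3")
        components = []
        for eid in ("6.2.5", "6.2.6", "6.2.7", "6.2.8", "6.2.9"):
            comp = _component(registry, inst, eid)
            if comp is not None:
                components.append(comp)
        if components:
            obs["component"] = components
        if inst.get("6.2.4"):
            obs["extension"] = [_ext("6.2.4", inst.get("6.2.4"))]
        resources.append(obs)

    # ----- measurement Observations ----------------------------------------
    for idx, inst in enumerate(record.instances("6.3")):
        obs = {
            "resourceType": "Observation",
            "id": f"{pid}-measurement-{idx}",
            "status": "final",
            "subject": subject_ref,
        }
        if inst.get("6.3.1") is not None:
            obs["code"] = _codeable(inst.get("6.3.1"))
        else:
            obs["code"] = _element_code_concept(registry, "6.3.1")
        if inst.get("6.3.2") is not None:
            quantity: dict = {"value": float(inst.get("6.3.2"))}
            if inst.get("6.3.3") is not None:
                quantity["unit"] = _display_of(inst.get("6.3.3"))
                quantity["system"] = SYSTEM_URI[CodeSystem.UO]
                quantity["code"] = _code_of(inst.get("6.3.3"))
            obs["valueQuantity"] = quantity
        if inst.get("6.3.4") is not None:
            obs["interpretation"] = [_codeable(inst.get("6.3.4"))]
        if inst.get("6.3.5"):
            obs["effectiveDateTime"] = inst.get("6.3.5")
        comp = _component(registry, inst, "6.3.6")
        if comp is not None:
            obs["component"] = [comp]
        resources.append(obs)

    # ----- FamilyMemberHistory ----------------------------------------------
    for idx, inst in enumerate(record.instances("6.4")):
        fmh: dict = {
            "resourceType": "FamilyMemberHistory",
            "id": f"{pid}-family-{idx}",
            "patient": subject_ref,
            "status": (
                _code_of(inst.get("6.4.6"))
                if inst.get("6.4.6") is not None else "completed"
            ),
        }
        if inst.get("6.4.1") is not None:
            fmh["name"] = inst.get("6.4.1")
        if inst.get("6.4.5") is not None:
            fmh["relationship"] = _codeable(inst.get("6.4.5"))
        if inst.get("6.4.7") is not None:
            fmh["sex"] = _codeable(inst.get("6.4.7"))
        if inst.get("6.4.9"):
            fmh["bornDate"] = inst.get("6.4.9")
        if inst.get("6.4.8") is not None:
            fmh["ageAge"] = {
                "value": inst.get("6.4.8"), "unit": "years",
                "system": "http://unitsofmeasure.org", "code": "a",
            }
        deceased = inst.get("6.4.10")
        if deceased is not None:
            display = _display_of(deceased)
            if display == "Yes":
                fmh["deceasedBoolean"] = True
            elif display == "No":
                fmh["deceasedBoolean"] = False
            # Unknown: a two-valued boolean cannot encode it -> omitted
        conditions = []
        if inst.get("6.4.13") is not None:
            conditions.append({"code": _codeable(inst.get("6.4.13"))})
        if inst.get("6.4.11") is not None:
            conditions.append(
                {"code": _codeable(inst.get("6.4.11")), "contributedToDeath": True}
            )
        if conditions:
            fmh["condition"] = conditions
        if inst.get("6.4.12") is not None:
            fmh["extension"] = [
                {
                    "url": EXT_URL + "6.4.12",
                    "valueAge": {
                        "value": inst.get("6.4.12"), "unit": "years",
                        "system": "http://unitsofmeasure.org", "code": "a",
                    },
                }
            ]
        resources.append(fmh)

    # ----- Consent ----------------------------------------------------------
    sec7 = record.instances("7")
    if sec7:
        inst = sec7[0]
        consent: dict = {
            "resourceType": "Consent",
            "id": f"{pid}-consent",
            "patient": subject_ref,
            "scope": {"coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/consentscope",
                "code": "research",
            }]},
        }
        if inst.get("7.1") is not None:
            consent["status"] = _code_of(inst.get("7.1"))
        if inst.get("7.2"):
            consent["dateTime"] = inst.get("7.2")
        if inst.get("7.3") is not None:
            consent["policy"] = [{"authority": inst.get("7.3")}]
        provisions = []
        for eid in ("7.4", "7.5"):
            value = inst.get(eid)
            if value is None:
                continue
            display = _display_of(value)
            prov = {
                "type": "permit" if display == "Yes" else "deny",
                "code": [_element_code_concept(registry, eid)],
                "extension": [_ext(eid, value)],
            }
            provisions.append(prov)
        if provisions:
            consent["provision"] = {"provision": provisions}
        resources.append(consent)

    # ----- unmapped manifest -------------------------------------------------
    unmapped: list[dict] = []
    for el in registry.iter_elements():
        if el.fhir_expression is not None:
            continue
        if el.element_id == "8.1":
            continue  # emitted as the rd_cdm/icf_score Observation
        for idx, inst in enumerate(record.instances(el.section_id)):
            value = inst.get(el.element_id)
            if value is not None:
                unmapped.append(
                    {
                        "element_id": el.element_id,
                        "section_id": el.section_id,
                        "instance_index": idx,
                        "value": _dump_value(value),
                    }
                )
    return FhirResourceSet(resources=resources, unmapped=unmapped)


def fhir_json(resource_set: FhirResourceSet) -> str:
    return json.dumps(
        resource_set.model_dump(mode="json"), indent=2, sort_keys=True
    )


# ---------------------------------------------------------------------------
# structural shape check
# ---------------------------------------------------------------------------


def _iter_codings(node):
    if isinstance(node, dict):
        for key, value in node.items():
            if key == "coding" and isinstance(value, list):
                yield from value
            else:
                yield from _iter_codings(value)
    elif isinstance(node, list):
        for item in node:
            yield from _iter_codings(item)


def check_fhir_shape(resource_set: FhirResourceSet) -> list[ValidationIssue]:
    """Structural checks only; not a full FHIR profile validator."""
    issues: list[ValidationIssue] = []

    def err(target, rule, msg):
        issues.append(ValidationIssue(
            target=target, severity=Severity.ERROR, rule_id=rule, message=msg,
        ))

    patients = resource_set.by_type("Patient")
    if len(patients) != 1:
        err("Patient", "fhir_patient_count",
            f"expected exactly one Patient, found {len(patients)}")
    patient_refs = {f"Patient/{p.get('id')}" for p in patients}
    for res in resource_set.resources:
        rtype = res.get("resourceType", "")
        rid = res.get("id", "?")
        if rtype not in ALLOWED_RESOURCE_TYPES:
            err(rid, "fhir_resource_type", f"illegal resourceType {rtype!r}")
            continue
        if rtype != "Patient":
            ref = (res.get("subject") or res.get("patient") or {}).get("reference")
            if ref not in patient_refs:
                err(rid, "fhir_reference",
                    f"{rtype} does not reference the record's Patient")
        for coding in _iter_codings(res):
            if not coding.get("system") or not coding.get("code"):
                err(rid, "fhir_coding",
                    f"coding lacking system or code: {coding!r}")
    return issues
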