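"""Patient records: section instances, cardinality profiles, JSON I/O.

Record JSON layout (keys are section ids; singleton sections hold one
object, repeatable sections a list of objects; inner keys are element ids)::

    {
      "1":   {"1.1": "P-0001", "1.2": "2021-03-02"},
      "5":   [{"5.1": [{"system": "ORDO", "code": "..."}], "5.4": "2019-06-01"}],
      ...
    }

Typed values: DATE → ISO-8601 string, STRING → string, INTEGER → int,
BOOLEAN → bool, CODE → a code object ``{"system", "code", "display"}`` or,
for multi-coded elements (5.1, 6.1.1, 6.4.13), a list of code objects.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, model_validator

from .model import (
    Cardinality,
    CodeBinding,
    DataType,
    DEFAULT_CARDINALITIES,
    ModelRegistry,
    REPEATABLE_SECTIONS,
    SECTION_IDS,
    SINGLETON_SECTIONS,
)

ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

CodeValue = Union[CodeBinding, list]
Value = Union[str, int, bool, CodeBinding, list]


class RecordParseError(ValueError):
    """Structural problem in a record document; carries a JSON pointer."""

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(f"{pointer}: {message}" if pointer else message)
        self.pointer = pointer


class SectionInstance(BaseModel):
    section_id: str
    values: dict[str, Value] = {}

    @model_validator(mode="after")
    def _keys_belong(self) -> "SectionInstance":
        for eid in self.values:
            sec = eid.rsplit(".", 1)[0]
            if sec != self.section_id:
                raise ValueError(
                    f"element {eid} does not belong to section {self.section_id}"
                )
        return self

    def get(self, element_id: str):
        return self.values.get(element_id)


class PatientRecord(BaseModel):
    singletons: dict[str, SectionInstance] = {}
    repeats: dict[str, list[SectionInstance]] = {}

    @model_validator(mode="after")
    def _structure(self) -> "PatientRecord":
        for sid in self.singletons:
            if sid not in SINGLETON_SECTIONS:
                raise ValueError(f"section {sid} is not a singleton section")
        for sid in self.repeats:
            if sid not in REPEATABLE_SECTIONS:
                raise ValueError(f"section {sid} is not a repeatable section")
        sec1 = self.singletons.get("1")
        if sec1 is not None and "1.1" not in sec1.values:
            raise ValueError("pseudonym (1.1) must always be captured "
                             "when section 1 is present")
        return self

    # -- queries ----------------------------------------------------------
    def instances(self, section_id: str) -> list[SectionInstance]:
        if section_id in SINGLETON_SECTIONS:
            inst = self.singletons.get(section_id)
            return [inst] if inst is not None else []
        return list(self.repeats.get(section_id, []))

    def first(self, element_id: str):
        """First populated value of an element, or None."""
        for v in self.all_values(element_id):
            return v
        return None

    def all_values(self, element_id: str) -> list:
        sid = element_id.rsplit(".", 1)[0]
        out = []
        for inst in self.instances(sid):
            if element_id in inst.values:
                out.append(inst.values[element_id])
        return out

    def pseudonym(self) -> Optional[str]:
        return self.first("1.1")


class CardinalityProfile(BaseModel):
    name: str = "custom"
    cardinalities: dict[str, Cardinality]

    @model_validator(mode="after")
    def _covers_all(self) -> "CardinalityProfile":
        missing = [s for s in SECTION_IDS if s not in self.cardinalities]
        if missing:
            raise ValueError(f"profile must cover all 11 sections; missing {missing}")
        return self

    @classmethod
    def default(cls) -> "CardinalityProfile":
        return cls(name="default", cardinalities=dict(DEFAULT_CARDINALITIES))

    @classmethod
    def strict(cls) -> "CardinalityProfile":
        """Default profile with the patient-level sections 2 and 3 required."""
        cards = dict(DEFAULT_CARDINALITIES)
        cards["2"] = Cardinality.ONE_ONE
        cards["3"] = Cardinality.ONE_ONE
        return cls(name="strict", cardinalities=cards)

    @classmethod
    def named(cls, name: str) -> "CardinalityProfile":
        if name == "default":
            return cls.default()
        if name == "strict":
            return cls.strict()
        raise KeyError(f"unknown profile name: {name!r}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CardinalityProfile":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(
            name=doc.get("name", Path(path).stem),
            cardinalities={k: Cardinality(v) for k, v in doc["cardinalities"].items()},
        )


# ---------------------------------------------------------------------------
# JSON (de)serialisation with registry-driven structural typing
# ---------------------------------------------------------------------------


def _parse_code(raw, ptr: str) -> CodeBinding:
    if not isinstance(raw, dict) or "system" not in raw or "code" not in raw:
        raise RecordParseError(
            "CODE value must be an object with 'system' and 'code'", ptr
        )
    try:
        return CodeBinding.model_validate(raw)
    except Exception as exc:
        raise RecordParseError(f"invalid code object: {exc}", ptr) from exc


def _parse_value(raw, data_type: DataType, ptr: str):
    if data_type == DataType.CODE:
        if isinstance(raw, list):
            return [_parse_code(item, f"{ptr}/{i}") for i, item in enumerate(raw)]
        return _parse_code(raw, ptr)
    if data_type == DataType.DATE:
        if not isinstance(raw, str):
            raise RecordParseError("DATE value must be an ISO-8601 string", ptr)
        return raw
    if data_type == DataType.STRING:
        if not isinstance(raw, str):
            raise RecordParseError("STRING value must be a string", ptr)
        return raw
    if data_type == DataType.INTEGER:
        if not isinstance(raw, int) or isinstance(raw, bool):
            raise RecordParseError("INTEGER value must be an integer", ptr)
        return raw
    if data_type == DataType.BOOLEAN:
        if not isinstance(raw, bool):
            raise RecordParseError("BOOLEAN value must be true or false", ptr)
        return raw
    raise RecordParseError(f"unhandled data type {data_type}", ptr)


def _parse_instance(
    sid: str, raw: dict, registry: ModelRegistry, ptr: str
) -> SectionInstance:
    if not isinstance(raw, dict):
        raise RecordParseError("section instance must be an object", ptr)
    values = {}
    for eid, v in raw.items():
        eptr = f"{ptr}/{eid}"
        try:
            el = registry.element(eid)
        except KeyError:
            raise RecordParseError(f"unknown element id {eid!r}", eptr) from None
        if el.section_id != sid:
            raise RecordParseError(
                f"element {eid} does not belong to section {sid}", eptr
            )
        values[eid] = _parse_value(v, el.data_type, eptr)
    return SectionInstance(section_id=sid, values=values)


def read_record(
    source: Union[str, Path, dict], registry: ModelRegistry
) -> PatientRecord:
    """Parse a record JSON document, checking structure and value typing."""
    if isinstance(source, Path):
        doc = json.loads(source.read_text(encoding="utf-8"))
    elif isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith("{"):
            doc = json.loads(source)
        else:
            doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = source
    if not isinstance(doc, dict):
        raise RecordParseError("record document must be a JSON object", "")
    singletons: dict[str, SectionInstance] = {}
    repeats: dict[str, list[SectionInstance]] = {}
    for sid, block in doc.items():
        ptr = f"/{sid}"
        if sid in SINGLETON_SECTIONS:
            singletons[sid] = _parse_instance(sid, block, registry, ptr)
        elif sid in REPEATABLE_SECTIONS:
            if not isinstance(block, list):
                raise RecordParseError(
                    f"repeatable section {sid} must hold a list", ptr
                )
            repeats[sid] = [
                _parse_instance(sid, item, registry, f"{ptr}/{i}")
                for i, item in enumerate(block)
            ]
        else:
            raise RecordParseError(f"unknown section id {sid!r}", ptr)
    try:
        return PatientRecord(singletons=singletons, repeats=repeats)
    except Exception as exc:
        raise RecordParseError(str(exc), "") from exc


def _dump_value(value):
    if isinstance(value, CodeBinding):
        return value.model_dump(mode="json")
    if isinstance(value, list):
        return [_dump_value(v) for v in value]
    return value


def record_to_document(record: PatientRecord) -> dict:
    doc: dict = {}
    for sid in SECTION_IDS:
        if sid in record.singletons:
            doc[sid] = {
                k: _dump_value(v) for k, v in record.singletons[sid].values.items()
            }
        elif sid in record.repeats:
            doc[sid] = [
                {k: _dump_value(v) for k, v in inst.values.items()}
                for inst in record.repeats[sid]
            ]
    return doc


def write_record(record: PatientRecord) -> str:
    """Serialise a record to canonical JSON (inverse of read_record)."""
    return json.dumps(record_to_document(record), indent=2, sort_keys=True)


def record_schema(registry: ModelRegistry) -> dict:
    """JSON Schema (2020-12) for record documents of this registry."""
    type_map = {
        DataType.DATE: {"type": "string", "pattern": ISO_DATE_RE.pattern},
        DataType.STRING: {"type": "string"},
        DataType.INTEGER: {"type": "integer"},
        DataType.BOOLEAN: {"type": "boolean"},
    }
    code_schema = {
        "type": "object",
        "required": ["system", "code"],
        "properties": {
            "system": {"type": "string"},
            "code": {"type": "string", "minLength": 1},
            "display": {"type": "string"},
            "version": {"type": "string"},
        },
    }
    sections = {}
    for sec in registry.sections:
        props = {}
        for el in sec.elements:
            if el.data_type == DataType.CODE:
                props[el.element_id] = {
                    "anyOf": [code_schema, {"type": "array", "items": code_schema}]
                }
            else:
                props[el.element_id] = type_map[el.data_type]
        inst = {"type": "object", "properties": props, "additionalProperties": False}
        if sec.id == "1":
            inst = {**inst, "required": ["1.1"]}
        if sec.id in SINGLETON_SECTIONS:
            sections[sec.id] = inst
        else:
            sections[sec.id] = {"type": "array", "items": inst}
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": f"RD-CDM {registry.version} patient record",
        "type": "object",
        "properties": sections,
        "additionalProperties": False,
    }
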