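"""Load/export the registry as JSON (schema-checked) and Fig.-2-style CSV."""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Union

from pydantic import ValidationError

from .model import ModelRegistry
from .terminologies import curie


class RegistryError(ValueError):
    """Registry document violates the schema or the model invariants.

    ``pointer`` holds the JSON pointer of the first failing location.
    """

    def __init__(self, message: str, pointer: str = ""):
        super().__init__(message)
        self.pointer = pointer


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc)


def registry_schema() -> dict:
    """JSON Schema (2020-12 dialect) for registry documents."""
    schema = ModelRegistry.model_json_schema()
    schema["$schema"] = "https://json-schema.org/draft/2020-12/schema"
    return schema


def load_registry(source: Union[str, Path, dict]) -> ModelRegistry:
    """Parse a registry from a JSON string, file path, or parsed document."""
    if isinstance(source, Path):
        doc = json.loads(source.read_text(encoding="utf-8"))
    elif isinstance(source, str):
        stripped = source.lstrip()
        if stripped.startswith("{"):
            doc = json.loads(source)
        else:
            doc = json.loads(Path(source).read_text(encoding="utf-8"))
    elif isinstance(source, dict):
        doc = source
    else:
        raise TypeError(f"unsupported registry source: {type(source)!r}")
    try:
        return ModelRegistry.model_validate(doc)
    except ValidationError as exc:
        first = exc.errors()[0]
        ptr = _pointer(tuple(first["loc"]))
        raise RegistryError(
            f"registry schema violation at {ptr}: {first['msg']}", pointer=ptr
        ) from exc


def export_registry(registry: ModelRegistry, format: str = "JSON") -> str:
    """Serialise the registry to JSON (round-trippable) or Fig.-2 CSV."""
    fmt = format.upper()
    if fmt == "JSON":
        return json.dumps(
            registry.model_dump(mode="json"), indent=2, sort_keys=True
        )
    if fmt == "CSV":
        return _to_csv(registry)
    raise ValueError(f"unsupported registry export format: {format!r}")


CSV_COLUMNS = [
    "Data Element",
    "Code(s)",
    "Terminology",
    "Data Type",
    "Data Specification",
    "Concepts Display",
    "Concepts Code",
    "Concepts Terminology",
    "FHIR Expression v4.0.1",
    "GA4GH Phenopacket Schema Element v2.0",
    "Description",
]

_NA = "n/a"


def _to_csv(registry: ModelRegistry) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for el in registry.iter_elements():
        vs = registry.value_set(el.value_set_id) if el.value_set_id else None
        codes = "; ".join(curie(c) for c in el.codes) or _NA
        systems = "; ".join(dict.fromkeys(c.system.value for c in el.codes)) or _NA
        if vs is not None:
            concepts_display = "; ".join(c.display for c in vs.choices)
            concepts_code = "; ".join(curie(c.binding) for c in vs.choices)
            concepts_term = "; ".join(
                dict.fromkeys(c.binding.system.value for c in vs.choices)
            )
        else:
            concepts_display = concepts_code = concepts_term = _NA
        writer.writerow(
            [
                f"{el.element_id} {el.label}",
                codes,
                systems,
                el.data_type.value,
                el.data_specification or _NA,
                concepts_display,
                concepts_code,
                concepts_term,
                el.fhir_expression or _NA,
                el.phenopacket_element or _NA,
                el.description or _NA,
            ]
        )
    return buf.getvalue()
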