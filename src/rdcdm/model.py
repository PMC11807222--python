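"""Typed core of the rare disease common data model (RD-CDM).

The model organises 78 data elements into eleven sections (1, 2, 3, 4, 5,
6.1-6.4, 7, 8) mirroring the ERDRI-CDS section layout. Each element carries
ontology/terminology bindings (SNOMED CT, LOINC, HPO, NCIT, ...), a data
type, an optional closed value set, and mapping expressions into HL7 FHIR
R4 (v4.0.1) resources and the GA4GH Phenopacket Schema v2.0.

Alignment with the two target standards is *derived* from the mapping
expressions, never stored, so a registry document cannot contradict itself.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

CUSTOM_CODE_PREFIX = "rd_cdm:"


class CodeSystem(str, enum.Enum):
    SNOMED_CT = "SNOMED_CT"
    LOINC = "LOINC"
    HPO = "HPO"
    NCIT = "NCIT"
    ICD10 = "ICD10"
    ICD11 = "ICD11"
    ORDO = "ORDO"
    MONDO = "MONDO"
    OMIM_P = "OMIM_P"
    OMIM_G = "OMIM_G"
    HGNC = "HGNC"
    HGVS = "HGVS"
    NCBITAXON = "NCBITaxon"
    UO = "UO"
    ECO = "ECO"
    ISO3166 = "ISO3166"
    ICF = "ICF"
    GA4GH = "GA4GH"
    HL7FHIR = "HL7FHIR"
    CUSTOM = "CUSTOM"


class ChoiceSource(str, enum.Enum):
    """Provenance of a single value-set choice's code."""

    FHIR_CODE = "FHIR_CODE"
    GA4GH_CODE = "GA4GH_CODE"
    SNOMED = "SNOMED"
    LOINC = "LOINC"
    HPO = "HPO"
    NCIT = "NCIT"
    CUSTOM = "CUSTOM"


#: choice source category -> code system it must bind to
CHOICE_SOURCE_SYSTEM = {
    ChoiceSource.FHIR_CODE: CodeSystem.HL7FHIR,
    ChoiceSource.GA4GH_CODE: CodeSystem.GA4GH,
    ChoiceSource.SNOMED: CodeSystem.SNOMED_CT,
    ChoiceSource.LOINC: CodeSystem.LOINC,
    ChoiceSource.HPO: CodeSystem.HPO,
    ChoiceSource.NCIT: CodeSystem.NCIT,
    ChoiceSource.CUSTOM: CodeSystem.CUSTOM,
}


class Derivation(str, enum.Enum):
    """How a value set relates to the source standards.

    VS: adopted wholesale (including codes) from HL7 FHIR or the
    Phenopacket Schema. VSe: extended by at least one choice. VSc: at least
    one choice re-encoded with a SNOMED CT, LOINC, HPO, or NCIT code.
    """

    VS = "VS"
    VSE = "VSe"
    VSC = "VSc"
    VSE_VSC = "VSe_VSc"


class SourceStandard(str, enum.Enum):
    FHIR = "FHIR"
    GA4GH = "GA4GH"
    MIXED = "MIXED"
    NONE = "NONE"


class DataType(str, enum.Enum):
    CODE = "CODE"
    DATE = "DATE"
    STRING = "STRING"
    INTEGER = "INTEGER"
    BOOLEAN = "BOOLEAN"


class LabelSource(str, enum.Enum):
    ERDRI_CDS = "ERDRI_CDS"
    STANDARD = "STANDARD"  # HL7 FHIR or Phenopacket Schema label
    CUSTOM = "CUSTOM"


class TerminologySource(str, enum.Enum):
    FHIR_SPEC = "FHIR_SPEC"
    GA4GH_SPEC = "GA4GH_SPEC"
    ONTOLOGY = "ONTOLOGY"  # SNOMED CT, LOINC, NCIT or HPO
    CUSTOM = "CUSTOM"


class Alignment(str, enum.Enum):
    FHIR = "FHIR"
    GA4GH = "GA4GH"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


class Cardinality(str, enum.Enum):
    ONE_ONE = "1..1"
    ZERO_ONE = "0..1"
    ZERO_MANY = "0..n"


class CodeBinding(BaseModel):
    """One code from one code system, e.g. SNOMED CT 422549004."""

    model_config = ConfigDict(frozen=True)

    system: CodeSystem
    code: str
    display: str = ""
    version: str = ""

    @field_validator("code")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("code must be non-empty")
        return v

    @model_validator(mode="after")
    def _custom_namespaced(self) -> "CodeBinding":
        if self.system == CodeSystem.CUSTOM and not self.code.startswith(
            CUSTOM_CODE_PREFIX
        ):
            raise ValueError(
                f"custom codes must be namespaced with {CUSTOM_CODE_PREFIX!r}"
            )
        return self


class ValueSetChoice(BaseModel):
    model_config = ConfigDict(frozen=True)

    display: str
    binding: CodeBinding
    source_category: ChoiceSource
    #: the source material names some members without printing their concrete
    #: ontology code; such choices carry a synthetic code and placeholder=True
    placeholder: bool = False

    @model_validator(mode="after")
    def _source_consistent(self) -> "ValueSetChoice":
        expected = CHOICE_SOURCE_SYSTEM[self.source_category]
        if self.binding.system != expected:
            raise ValueError(
                f"choice source {self.source_category.value} requires code "
                f"system {expected.value}, got {self.binding.system.value}"
            )
        return self


class ValueSet(BaseModel):
    id: str
    name: str
    choices: list[ValueSetChoice]
    derivation: Derivation
    source_standard: SourceStandard

    @model_validator(mode="after")
    def _invariants(self) -> "ValueSet":
        if not self.choices:
            raise ValueError(f"value set {self.id} has no choices")
        if self.derivation == Derivation.VS:
            bad = [
                c.display
                for c in self.choices
                if c.source_category
                not in (ChoiceSource.FHIR_CODE, ChoiceSource.GA4GH_CODE)
            ]
            if bad:
                raise ValueError(
                    f"directly derived value set {self.id} has non-standard "
                    f"choices: {bad}"
                )
        return self

    def find(self, code: str) -> Optional[ValueSetChoice]:
        for c in self.choices:
            if c.binding.code == code:
                return c
        return None


class DataElement(BaseModel):
    element_id: str
    section_id: str
    label: str
    label_source: LabelSource
    codes: list[CodeBinding] = []
    data_type: DataType
    data_specification: str = ""
    value_set_id: Optional[str] = None
    #: FHIR R4 element path; brackets mark partial/indirect mappings and a
    #: "Suggestion" marker flags proposed extensions
    fhir_expression: Optional[str] = None
    phenopacket_element: Optional[str] = None
    terminology_source: TerminologySource
    datatype_alignment: Alignment
    description: str = ""

    @model_validator(mode="after")
    def _invariants(self) -> "DataElement":
        if not self.codes and self.terminology_source != TerminologySource.CUSTOM:
            raise ValueError(
                f"element {self.element_id}: codes may be empty only for "
                "custom terminology bindings"
            )
        return self

    @property
    def alignment(self) -> Alignment:
        """Standard alignment, recomputed from the mapping expressions.

        An element counts as aligned when it is directly or indirectly
        (bracketed partial mapping) expressed with an element of the
        standard.
        """
        fhir = bool(self.fhir_expression)
        pheno = bool(self.phenopacket_element)
        if fhir and pheno:
            return Alignment.BOTH
        if fhir:
            return Alignment.FHIR
        if pheno:
            return Alignment.GA4GH
        return Alignment.NEITHER

    @property
    def fhir_suggestion(self) -> bool:
        return bool(self.fhir_expression) and "Suggestion" in self.fhir_expression


#: default recommended cardinalities per section
DEFAULT_CARDINALITIES = {
    "1": Cardinality.ONE_ONE,
    "2": Cardinality.ZERO_ONE,
    "3": Cardinality.ZERO_ONE,
    "4": Cardinality.ZERO_MANY,
    "5": Cardinality.ZERO_MANY,
    "6.1": Cardinality.ZERO_MANY,
    "6.2": Cardinality.ZERO_MANY,
    "6.3": Cardinality.ZERO_MANY,
    "6.4": Cardinality.ZERO_MANY,
    "7": Cardinality.ONE_ONE,
    "8": Cardinality.ZERO_ONE,
}

SECTION_IDS = tuple(DEFAULT_CARDINALITIES)
REPEATABLE_SECTIONS = ("4", "5", "6.1", "6.2", "6.3", "6.4")
SINGLETON_SECTIONS = ("1", "2", "3", "7", "8")


class Section(BaseModel):
    id: str
    name: str
    elements: list[DataElement]
    recommended_cardinality: Cardinality

    @model_validator(mode="after")
    def _prefixed(self) -> "Section":
        for el in self.elements:
            if not el.element_id.startswith(self.id + "."):
                raise ValueError(
                    f"element {el.element_id} does not belong to section {self.id}"
                )
            if el.section_id != self.id:
                raise ValueError(
                    f"element {el.element_id} carries section_id "
                    f"{el.section_id!r} inside section {self.id!r}"
                )
        return self


class ModelRegistry(BaseModel):
    version: str
    sections: list[Section]
    value_sets: list[ValueSet]
    #: pinned code-system versions, stored as metadata (not enforced)
    code_system_versions: dict[str, str] = {}

    @model_validator(mode="after")
    def _invariants(self) -> "ModelRegistry":
        seen: set[str] = set()
        for el in self.iter_elements():
            if el.element_id in seen:
                raise ValueError(f"duplicate element id {el.element_id}")
            seen.add(el.element_id)
        vs_ids = [v.id for v in self.value_sets]
        if len(vs_ids) != len(set(vs_ids)):
            raise ValueError("duplicate value set id")
        vs_set = set(vs_ids)
        for el in self.iter_elements():
            if el.value_set_id is not None and el.value_set_id not in vs_set:
                raise ValueError(
                    f"element {el.element_id} references unknown value set "
                    f"{el.value_set_id}"
                )
        return self

    # -- queries ----------------------------------------------------------
    def iter_elements(self):
        for sec in self.sections:
            yield from sec.elements

    @property
    def elements(self) -> list[DataElement]:
        return list(self.iter_elements())

    def element(self, element_id: str) -> DataElement:
        for el in self.iter_elements():
            if el.element_id == element_id:
                return el
        raise KeyError(f"unknown element id: {element_id}")

    def section(self, section_id: str) -> Section:
        for sec in self.sections:
            if sec.id == section_id:
                return sec
        raise KeyError(f"unknown section id: {section_id}")

    def value_set(self, vs_id: str) -> ValueSet:
        for vs in self.value_sets:
            if vs.id == vs_id:
                return vs
        raise KeyError(f"unknown value set id: {vs_id}")

    def list_value_sets(self) -> list[ValueSet]:
        return list(self.value_sets)

    def element_value_set(self, element_id: str) -> Optional[ValueSet]:
        el = self.element(element_id)
        if el.value_set_id is None:
            return None
        return self.value_set(el.value_set_id)
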