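"""CURIE rendering and ontology-resource metadata for the code systems.

HPO, MONDO and custom codes are stored already prefixed (``HP:``, ``MONDO:``,
``rd_cdm:``); all other systems store bare codes and receive their prefix
here.
"""

from __future__ import annotations

from .model import CodeBinding, CodeSystem

#: systems whose stored codes already carry their CURIE prefix
_PREFIXED = {CodeSystem.HPO, CodeSystem.MONDO, CodeSystem.CUSTOM}

CURIE_PREFIX = {
    CodeSystem.SNOMED_CT: "SNOMEDCT",
    CodeSystem.LOINC: "LOINC",
    CodeSystem.HPO: "HP",
    CodeSystem.NCIT: "NCIT",
    CodeSystem.ICD10: "ICD10",
    CodeSystem.ICD11: "ICD11",
    CodeSystem.ORDO: "ORPHA",
    CodeSystem.MONDO: "MONDO",
    CodeSystem.OMIM_P: "OMIM",
    CodeSystem.OMIM_G: "OMIM",
    CodeSystem.HGNC: "HGNC",
    CodeSystem.HGVS: "HGVS",
    CodeSystem.NCBITAXON: "NCBITaxon",
    CodeSystem.UO: "UO",
    CodeSystem.ECO: "ECO",
    CodeSystem.ISO3166: "ISO3166",
    CodeSystem.ICF: "ICF",
    CodeSystem.GA4GH: "GA4GH",
    CodeSystem.HL7FHIR: "HL7FHIR",
    CodeSystem.CUSTOM: "rd_cdm",
}

#: CURIE prefix -> (resource id, name, url, iri prefix) for metaData blocks
RESOURCE_INFO = {
    "SNOMEDCT": ("snomedct", "SNOMED Clinical Terms",
                 "http://snomed.info/sct", "http://snomed.info/id/"),
    "LOINC": ("loinc", "Logical Observation Identifiers Names and Codes",
              "http://loinc.org", "http://loinc.org/"),
    "HP": ("hp", "Human Phenotype Ontology",
           "http://purl.obolibrary.org/obo/hp.owl",
           "http://purl.obolibrary.org/obo/HP_"),
    "NCIT": ("ncit", "NCI Thesaurus",
             "http://purl.obolibrary.org/obo/ncit.owl",
             "http://purl.obolibrary.org/obo/NCIT_"),
    "ICD10": ("icd10", "International Classification of Diseases, 10th Revision",
              "https://icd.who.int/browse10", "https://icd.who.int/browse10/"),
    "ICD11": ("icd11", "International Classification of Diseases, 11th Revision",
              "https://icd.who.int/browse11", "https://icd.who.int/browse11/"),
    "ORPHA": ("orpha", "Orphanet Rare Disease Ontology",
              "http://www.orpha.net", "http://www.orpha.net/ORDO/Orphanet_"),
    "MONDO": ("mondo", "Mondo Disease Ontology",
              "http://purl.obolibrary.org/obo/mondo.owl",
              "http://purl.obolibrary.org/obo/MONDO_"),
    "OMIM": ("omim", "Online Mendelian Inheritance in Man",
             "https://www.omim.org", "https://www.omim.org/entry/"),
    "HGNC": ("hgnc", "HUGO Gene Nomenclature Committee",
             "https://www.genenames.org", "https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/"),
    "HGVS": ("hgvs", "Human Genome Variation Society nomenclature",
             "https://varnomen.hgvs.org", "https://varnomen.hgvs.org/"),
    "NCBITaxon": ("ncbitaxon", "NCBI organismal classification",
                  "http://purl.obolibrary.org/obo/ncbitaxon.owl",
                  "http://purl.obolibrary.org/obo/NCBITaxon_"),
    "UO": ("uo", "Units of measurement ontology",
           "http://purl.obolibrary.org/obo/uo.owl",
           "http://purl.obolibrary.org/obo/UO_"),
    "ECO": ("eco", "Evidence and Conclusion Ontology",
            "http://purl.obolibrary.org/obo/eco.owl",
            "http://purl.obolibrary.org/obo/ECO_"),
    "ISO3166": ("iso3166", "ISO 3166 country codes",
                "https://www.iso.org/iso-3166-country-codes.html",
                "urn:iso:std:iso:3166#"),
    "ICF": ("icf", "International Classification of Functioning, Disability and Health",
            "https://icd.who.int/dev11/l-icf/en", "https://icd.who.int/dev11/l-icf/en#"),
    "GA4GH": ("ga4gh", "GA4GH Phenopacket Schema",
              "https://phenopacket-schema.readthedocs.io",
              "https://phenopacket-schema.readthedocs.io/#"),
    "HL7FHIR": ("hl7fhir", "HL7 FHIR R4",
                "http://hl7.org/fhir", "http://hl7.org/fhir/"),
    "rd_cdm": ("rd_cdm", "RD-CDM custom code system",
               "urn:rd-cdm:codes", "urn:rd-cdm:codes#"),
}

#: code-system version keys in ModelRegistry.code_system_versions per prefix
_VERSION_KEY = {
    "SNOMEDCT": "SNOMED_CT",
    "LOINC": "LOINC",
    "HP": "HPO",
    "NCIT": "NCIT",
    "GA4GH": "GA4GH",
    "HL7FHIR": "HL7FHIR",
}


def curie(binding: CodeBinding) -> str:
    """Render a CodeBinding as a CURIE, e.g. SNOMEDCT:422549004."""
    if binding.system in _PREFIXED and ":" in binding.code:
        return binding.code
    return f"{CURIE_PREFIX[binding.system]}:{binding.code}"


def split_curie(value: str) -> tuple[str, str]:
    prefix, _, code = value.partition(":")
    if not code:
        raise ValueError(f"not a CURIE: {value!r}")
    return prefix, code


def binding_from_curie(value: str, display: str = "") -> CodeBinding:
    """Inverse of :func:`curie` (OMIM resolves to OMIM_G)."""
    prefix, code = split_curie(value)
    if prefix == "HP":
        return CodeBinding(system=CodeSystem.HPO, code=value, display=display)
    if prefix == "MONDO":
        return CodeBinding(system=CodeSystem.MONDO, code=value, display=display)
    if prefix == "rd_cdm":
        return CodeBinding(system=CodeSystem.CUSTOM, code=value, display=display)
    for system, pfx in CURIE_PREFIX.items():
        if pfx == prefix:
            return CodeBinding(system=system, code=code, display=display)
    raise ValueError(f"unknown CURIE prefix: {prefix!r}")


def resource_entry(prefix: str, versions: dict[str, str]) -> dict:
    rid, name, url, iri = RESOURCE_INFO[prefix]
    return {
        "id": rid,
        "name": name,
        "url": url,
        "version": versions.get(_VERSION_KEY.get(prefix, ""), "unversioned"),
        "namespacePrefix": prefix,
        "iriPrefix": iri,
    }
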