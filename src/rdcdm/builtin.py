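"""Bundled RD-CDM v2.0.0 registry fixture.

The fixture transcribes the published model definition: 78 data elements in
eleven sections, 39 value sets and a net total of 227 value-set choices
(value-set reuse counted once per hosting element, e.g. the natural family
member set used by both 6.4.3 and 6.4.5).

Codes printed in the source model (e.g. SNOMED CT 422549004 for the
patient-related identification code, LOINC 77602-1 for research study
consent, the HPO onset and severity subtrees, the GA4GH enumeration names
and the HL7 FHIR R4 code lists) are transcribed as-is. Member codes the
source does not print are shipped as clearly synthetic ``x-`` codes with
``placeholder=True``; their code-system attribution and per-section counts
are preserved exactly.
"""

from __future__ import annotations

from functools import lru_cache

from .model import (
    Alignment,
    ChoiceSource,
    CodeBinding,
    CodeSystem,
    DataElement,
    DataType,
    Derivation,
    LabelSource,
    ModelRegistry,
    Section,
    SourceStandard,
    TerminologySource,
    ValueSet,
    ValueSetChoice,
)

REGISTRY_VERSION = "2.0.0"

#: pinned code-system versions (metadata only, not enforced at validation)
CODE_SYSTEM_VERSIONS = {
    "SNOMED_CT": "2024-10-01",
    "LOINC": "2.7.8",
    "NCIT": "24.04e",
    "HPO": "2024-08-13",
    "HL7FHIR": "4.0.1",
    "GA4GH": "2.0",
}


def _b(system: CodeSystem, code: str, display: str = "") -> CodeBinding:
    return CodeBinding(
        system=system,
        code=code,
        display=display,
        version=CODE_SYSTEM_VERSIONS.get(system.value, ""),
    )


def _choice(
    display: str,
    source: ChoiceSource,
    code: str | None = None,
    placeholder: bool = False,
) -> ValueSetChoice:
    system = {
        ChoiceSource.FHIR_CODE: CodeSystem.HL7FHIR,
        ChoiceSource.GA4GH_CODE: CodeSystem.GA4GH,
        ChoiceSource.SNOMED: CodeSystem.SNOMED_CT,
        ChoiceSource.LOINC: CodeSystem.LOINC,
        ChoiceSource.HPO: CodeSystem.HPO,
        ChoiceSource.NCIT: CodeSystem.NCIT,
        ChoiceSource.CUSTOM: CodeSystem.CUSTOM,
    }[source]
    if code is None:
        # synthetic, clearly non-real code for members the source does not print
        code = "x-" + display.lower().replace(" ", "-").replace("/", "-")
        placeholder = True
    return ValueSetChoice(
        display=display,
        binding=_b(system, code, display),
        source_category=source,
        placeholder=placeholder,
    )


def _fhir_choices(*pairs: tuple[str, str]) -> list[ValueSetChoice]:
    return [_choice(d, ChoiceSource.FHIR_CODE, c) for c, d in pairs]


def _snomed_yes_no_unknown() -> list[ValueSetChoice]:
    return [
        _choice("Yes", ChoiceSource.SNOMED, "373066001"),
        _choice("No", ChoiceSource.SNOMED, "373067005"),
        _choice("Unknown", ChoiceSource.SNOMED, "261665006"),
    ]


_NATURAL_FAMILY_MEMBERS = [
    ("Mother", "72705000"),
    ("Father", "66839005"),
    ("Sister", None),
    ("Brother", None),
    ("Daughter", None),
    ("Son", None),
    ("Maternal grandmother", None),
    ("Maternal grandfather", None),
    ("Paternal grandmother", None),
    ("Paternal grandfather", None),
    ("Aunt", None),
    ("Uncle", None),
    ("Cousin", None),
    ("Half-sibling", None),
]


def _family_member_choices() -> list[ValueSetChoice]:
    return [_choice(d, ChoiceSource.SNOMED, c) for d, c in _NATURAL_FAMILY_MEMBERS]


def _value_sets() -> list[ValueSet]:
    vs: list[ValueSet] = []

    def add(vs_id, name, choices, derivation, source):
        vs.append(
            ValueSet(
                id=vs_id,
                name=name,
                choices=choices,
                derivation=derivation,
                source_standard=source,
            )
        )

    # --- section 2 -------------------------------------------------------
    add(
        "vs_2_2",
        "Sex at Birth",
        [
            _choice("Male", ChoiceSource.SNOMED, "248153007"),
            _choice("Female", ChoiceSource.SNOMED, "248152002"),
            _choice("Indeterminate sex", ChoiceSource.SNOMED),
            _choice("Intersex", ChoiceSource.SNOMED),
            _choice("Not recorded", ChoiceSource.SNOMED),
            _choice("Declined to state", ChoiceSource.SNOMED),
            _choice("Unknown", ChoiceSource.SNOMED, "261665006"),
        ],
        Derivation.VSE_VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_2_3",
        "Karyotypic Sex",
        [
            _choice("XX", ChoiceSource.SNOMED),
            _choice("XY", ChoiceSource.SNOMED),
            _choice("X0", ChoiceSource.SNOMED),
            _choice("XXY", ChoiceSource.SNOMED),
            _choice("XXX", ChoiceSource.SNOMED),
            _choice("XXYY", ChoiceSource.SNOMED),
            _choice("XYY", ChoiceSource.SNOMED),
            _choice("Other karyotype", ChoiceSource.SNOMED),
            _choice("Unknown karyotype", ChoiceSource.SNOMED),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_2_4",
        "Gender",
        [
            _choice("Male gender", ChoiceSource.SNOMED),
            _choice("Female gender", ChoiceSource.SNOMED),
            _choice("Non-binary gender", ChoiceSource.SNOMED),
            _choice("Other gender", ChoiceSource.SNOMED),
            _choice("Unknown", ChoiceSource.SNOMED, "261665006"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )

    # --- section 3 -------------------------------------------------------
    add(
        "vs_3_1",
        "Vital Status",
        [
            _choice("Alive", ChoiceSource.SNOMED, "438949009"),
            _choice("Dead", ChoiceSource.SNOMED, "419099009"),
            _choice("Lost to follow-up", ChoiceSource.SNOMED),
            _choice("Unknown", ChoiceSource.SNOMED, "261665006"),
        ],
        Derivation.VSE_VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_3_4",
        "Age Category",
        [
            _choice(d, ChoiceSource.SNOMED)
            for d in (
                "Neonatal period",
                "Infancy",
                "Toddler",
                "Childhood",
                "Adolescence",
                "Young adulthood",
                "Middle adulthood",
                "Late adulthood",
                "Unknown age category",
            )
        ],
        Derivation.VSE,
        SourceStandard.NONE,
    )
    add(
        "vs_3_6",
        "Undiagnosed RD Case",
        [
            _choice("Yes", ChoiceSource.SNOMED, "373066001"),
            _choice("No", ChoiceSource.SNOMED, "373067005"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )

    # --- section 4 -------------------------------------------------------
    add(
        "vs_4_3",
        "Encounter Status",
        _fhir_choices(
            ("planned", "Planned"),
            ("arrived", "Arrived"),
            ("triaged", "Triaged"),
            ("in-progress", "In Progress"),
            ("onleave", "On Leave"),
            ("finished", "Finished"),
            ("cancelled", "Cancelled"),
            ("entered-in-error", "Entered in Error"),
            ("unknown", "Unknown"),
        ),
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_4_4",
        "Encounter Class",
        _fhir_choices(
            ("AMB", "Ambulatory"),
            ("IMP", "Inpatient encounter"),
            ("EMER", "Emergency"),
            ("HH", "Home health"),
            ("VR", "Virtual"),
            ("OBSENC", "Observation encounter"),
        )
        + [
            _choice("Specialist clinic encounter", ChoiceSource.SNOMED),
            _choice(
                "RD Specialist Center",
                ChoiceSource.CUSTOM,
                "rd_cdm:rd_specialist_center",
            ),
        ],
        Derivation.VSE_VSC,
        SourceStandard.MIXED,
    )

    # --- section 5 -------------------------------------------------------
    add(
        "vs_5_2",
        "Disease Verification Status",
        _fhir_choices(
            ("unconfirmed", "Unconfirmed"),
            ("provisional", "Provisional"),
            ("differential", "Differential"),
            ("confirmed", "Confirmed"),
            ("refuted", "Refuted"),
            ("entered-in-error", "Entered in Error"),
        ),
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_5_3",
        "Age at Disease Onset",
        [
            _choice(d, ChoiceSource.SNOMED)
            for d in (
                "Antenatal onset",
                "Congenital onset",
                "Neonatal onset",
                "Onset in childhood",
                "Onset in adolescence",
                "Onset in adulthood",
            )
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_5_5",
        "Age at Diagnosis",
        [
            _choice(d, ChoiceSource.SNOMED)
            for d in (
                "Diagnosis at birth",
                "Diagnosis in childhood",
                "Diagnosis in adolescence",
                "Diagnosis in adulthood",
                "Unknown age at diagnosis",
            )
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_5_7",
        "Body Site",
        [
            _choice(
                "Body structure (example binding)",
                ChoiceSource.FHIR_CODE,
                None,
            )
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_5_8",
        "Disease Clinical Status",
        _fhir_choices(
            ("active", "Active"),
            ("recurrence", "Recurrence"),
            ("relapse", "Relapse"),
            ("inactive", "Inactive"),
            ("remission", "Remission"),
            ("resolved", "Resolved"),
        ),
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_5_9",
        "Disease Severity",
        _fhir_choices(
            ("24484000", "Severe"),
            ("6736007", "Moderate"),
            ("255604002", "Mild"),
        ),
        Derivation.VS,
        SourceStandard.FHIR,
    )

    # --- section 6.1 -----------------------------------------------------
    add(
        "vs_6_1_2",
        "Progress Status of Interpretation",
        [
            _choice(c, ChoiceSource.GA4GH_CODE, c)
            for c in (
                "UNKNOWN_PROGRESS",
                "IN_PROGRESS",
                "COMPLETED",
                "SOLVED",
                "UNSOLVED",
            )
        ],
        Derivation.VS,
        SourceStandard.GA4GH,
    )
    add(
        "vs_6_1_3",
        "Interpretation Status",
        [
            _choice(c, ChoiceSource.GA4GH_CODE, c)
            for c in (
                "UNKNOWN_STATUS",
                "REJECTED",
                "CANDIDATE",
                "CONTRIBUTORY",
                "CAUSATIVE",
            )
        ],
        Derivation.VS,
        SourceStandard.GA4GH,
    )
    add(
        "vs_6_1_4",
        "Genomic Analysis Method",
        [
            _choice(d, ChoiceSource.FHIR_CODE, None)
            for d in (
                "Karyotyping",
                "FISH",
                "PCR",
                "Sanger sequencing",
                "Gene panel sequencing",
                "Exome sequencing",
                "Genome sequencing",
                "Microarray",
                "MLPA",
                "Methylation analysis",
                "RNA sequencing",
            )
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_6_1_5",
        "Reference Genome",
        [
            _choice(d, ChoiceSource.FHIR_CODE, None)
            for d in ("GRCh38", "GRCh37", "NCBI36", "hg19", "hg18", "Other assembly")
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_6_1_11",
        "Zygosity",
        [
            _choice("Homozygous", ChoiceSource.LOINC, "LA6705-3"),
            _choice("Heterozygous", ChoiceSource.LOINC, "LA6706-1"),
            _choice("Hemizygous", ChoiceSource.LOINC, "LA6707-9"),
            _choice("Compound heterozygous", ChoiceSource.LOINC),
            _choice("Heteroplasmic", ChoiceSource.LOINC, "LA6703-8"),
            _choice("Homoplasmic", ChoiceSource.LOINC, "LA6704-6"),
            _choice("Mosaic", ChoiceSource.LOINC),
            _choice("Unknown zygosity", ChoiceSource.LOINC),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_1_12",
        "Genomic Source Class",
        [
            _choice(d, ChoiceSource.FHIR_CODE, None)
            for d in ("Germline", "Somatic", "Fetal", "Mixed", "De novo")
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_6_1_13",
        "DNA Change Type",
        [
            _choice(d, ChoiceSource.FHIR_CODE, None)
            for d in (
                "Wild type",
                "Deletion",
                "Duplication",
                "Insertion",
                "Insertion/Deletion",
                "Inversion",
                "Substitution",
            )
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )
    add(
        "vs_6_1_14",
        "Clinical Significance (ACMG)",
        [
            _choice("Pathogenic", ChoiceSource.LOINC, "LA6668-3"),
            _choice("Likely pathogenic", ChoiceSource.LOINC, "LA26332-9"),
            _choice("Uncertain significance", ChoiceSource.LOINC, "LA26333-7"),
            _choice("Likely benign", ChoiceSource.LOINC, "LA26334-5"),
            _choice("Benign", ChoiceSource.LOINC, "LA6675-8"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_1_15",
        "Therapeutic Actionability",
        [
            _choice(c, ChoiceSource.GA4GH_CODE, c)
            for c in ("UNKNOWN_ACTIONABILITY", "NOT_ACTIONABLE", "ACTIONABLE")
        ],
        Derivation.VS,
        SourceStandard.GA4GH,
    )
    add(
        "vs_6_1_16",
        "Clinical Annotation Level of Evidence",
        [
            _choice(d, ChoiceSource.FHIR_CODE, None)
            for d in (
                "Level 1A",
                "Level 1B",
                "Level 2A",
                "Level 2B",
                "Level 3",
                "Level 4",
                "Criteria provided",
                "No assertion",
            )
        ],
        Derivation.VS,
        SourceStandard.FHIR,
    )

    # --- section 6.2 -----------------------------------------------------
    add(
        "vs_6_2_2",
        "Phenotypic Finding Status",
        [
            _choice("Confirmed present", ChoiceSource.SNOMED, "410605003"),
            _choice("Refuted", ChoiceSource.SNOMED, "410594000"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_2_5",
        "Phenotype Onset Category",
        [
            _choice("Antenatal onset", ChoiceSource.HPO, "HP:0030674"),
            _choice("Embryonal onset", ChoiceSource.HPO, "HP:0011460"),
            _choice("Fetal onset", ChoiceSource.HPO, "HP:0011461"),
            _choice("Congenital onset", ChoiceSource.HPO, "HP:0003577"),
            _choice("Neonatal onset", ChoiceSource.HPO, "HP:0003623"),
            _choice("Infantile onset", ChoiceSource.HPO, "HP:0003593"),
            _choice("Childhood onset", ChoiceSource.HPO, "HP:0011463"),
            _choice("Juvenile onset", ChoiceSource.HPO, "HP:0003621"),
            _choice("Adult onset", ChoiceSource.HPO, "HP:0003581"),
            _choice("Late onset", ChoiceSource.HPO, "HP:0003584"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_2_6",
        "Temporal Pattern",
        [
            _choice("Acute", ChoiceSource.HPO, "HP:0011009"),
            _choice("Chronic", ChoiceSource.HPO, "HP:0011010"),
            _choice("Subacute", ChoiceSource.HPO, "HP:0011011"),
            _choice("Insidious onset", ChoiceSource.HPO, "HP:0003587"),
            _choice("Progressive", ChoiceSource.HPO, "HP:0003676"),
            _choice("Nonprogressive", ChoiceSource.HPO, "HP:0003680"),
            _choice("Episodic", ChoiceSource.HPO),
            _choice("Transient", ChoiceSource.HPO),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_2_7",
        "Phenotype Severity",
        [
            _choice("Borderline", ChoiceSource.HPO, "HP:0012827"),
            _choice("Mild", ChoiceSource.HPO, "HP:0012825"),
            _choice("Moderate", ChoiceSource.HPO, "HP:0012826"),
            _choice("Severe", ChoiceSource.HPO, "HP:0012828"),
            _choice("Profound", ChoiceSource.HPO, "HP:0012829"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )

    # --- section 6.4 -----------------------------------------------------
    add(
        "vs_6_4_2",
        "Propositus",
        _snomed_yes_no_unknown(),
        Derivation.VSE,
        SourceStandard.NONE,
    )
    add(
        "vs_6_4_3",
        "Natural Family Member (relationship to index case)",
        _family_member_choices(),
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_4_4",
        "Consanguinity",
        _snomed_yes_no_unknown(),
        Derivation.VSE,
        SourceStandard.NONE,
    )
    add(
        "vs_6_4_5",
        "Natural Family Member (family member relationship)",
        _family_member_choices(),
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_4_7",
        "Family Member Sex",
        [
            _choice("Male", ChoiceSource.SNOMED, "248153007"),
            _choice("Female", ChoiceSource.SNOMED, "248152002"),
            _choice("Unknown", ChoiceSource.SNOMED, "261665006"),
        ],
        Derivation.VSC,
        SourceStandard.NONE,
    )
    add(
        "vs_6_4_10",
        "Family Member Deceased",
        _snomed_yes_no_unknown(),
        Derivation.VSE_VSC,
        SourceStandard.NONE,
    )

    # --- section 7 -------------------------------------------------------
    add(
        "vs_7_1",
        "Consent Status",
        _fhir_choices(
            ("draft", "Pending"),
            ("proposed", "Proposed"),
            ("active", "Active"),
            ("rejected", "Rejected"),
            ("inactive", "Inactive"),
            ("entered-in-error", "Entered in Error"),
        ),
        Derivation.VS,
        SourceStandard.FHIR,
    )
    for vs_id, name in (
        ("vs_7_4", "Agreement to Be Contacted for Research"),
        ("vs_7_5", "Consent to Reuse of Data"),
        ("vs_7_6", "Biological Sample Available"),
    ):
        add(vs_id, name, _snomed_yes_no_unknown(), Derivation.VSE, SourceStandard.NONE)

    return vs


# ---------------------------------------------------------------------------
# data elements
# ---------------------------------------------------------------------------

_SCT = CodeSystem.SNOMED_CT
_L = LabelSource
_T = TerminologySource
_A = Alignment
_D = DataType


def _el(
    element_id: str,
    label: str,
    label_source: LabelSource,
    codes: list[CodeBinding],
    data_type: DataType,
    terminology_source: TerminologySource,
    datatype_alignment: Alignment,
    *,
    spec: str = "",
    vs: str | None = None,
    fhir: str | None = None,
    pheno: str | None = None,
    desc: str = "",
) -> DataElement:
    section_id = element_id.rsplit(".", 1)[0]
    return DataElement(
        element_id=element_id,
        section_id=section_id,
        label=label,
        label_source=label_source,
        codes=codes,
        data_type=data_type,
        data_specification=spec,
        value_set_id=vs,
        fhir_expression=fhir,
        phenopacket_element=pheno,
        terminology_source=terminology_source,
        datatype_alignment=datatype_alignment,
        description=desc,
    )


def _x(slug: str, display: str, system: CodeSystem = _SCT) -> CodeBinding:
    """Synthetic stand-in code for an element binding the source does not print."""
    return _b(system, "x-" + slug, display)


def _elements() -> dict[str, list[DataElement]]:
    fhir_b = lambda path: _b(CodeSystem.HL7FHIR, path, path)  # noqa: E731
    ga4gh_b = lambda path: _b(CodeSystem.GA4GH, path, path)  # noqa: E731

    s1 = [
        _el(
            "1.1",
            "Pseudonym",
            _L.ERDRI_CDS,
            [_b(_SCT, "422549004", "Patient-related Identification code")],
            _D.STRING,
            _T.ONTOLOGY,
            _A.FHIR,
            fhir="Patient.identifier",
            pheno="Individual.id",
            desc="Locally assigned patient pseudonym; must always be captured.",
        ),
        _el(
            "1.2",
            "Date of Admission",
            _L.CUSTOM,
            [_x("date-of-admission", "Date of admission")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Encounter.period.start",
            pheno="Individual.time_at_last_encounter",
            desc="Date of data capture or admission for the record.",
        ),
    ]

    s2 = [
        _el(
            "2.1",
            "Date of Birth",
            _L.ERDRI_CDS,
            [_b(_SCT, "184099003", "Date of birth")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Patient.birthDate",
            pheno="Individual.date_of_birth",
        ),
        _el(
            "2.2",
            "Sex at Birth",
            _L.ERDRI_CDS,
            [_x("sex-at-birth", "Sex at birth")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_2_2",
            fhir="(Patient.gender)",
            pheno="Individual.sex",
        ),
        _el(
            "2.3",
            "Karyotypic Sex",
            _L.STANDARD,
            [_x("karyotypic-sex", "Karyotypic sex")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.GA4GH,
            vs="vs_2_3",
            fhir="(Observation.valueCodeableConcept)",
            pheno="Individual.karyotypic_sex",
        ),
        _el(
            "2.4",
            "Gender",
            _L.STANDARD,
            [_x("gender", "Gender")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_2_4",
            fhir="Patient.gender",
            pheno="Individual.gender",
        ),
        _el(
            "2.5",
            "Country of Birth",
            _L.CUSTOM,
            [_x("country-of-birth", "Country of birth")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            spec="ISO3166 2- or 3-letter country code",
            fhir="Patient.extension['patient-birthPlace']",
        ),
    ]

    s3 = [
        _el(
            "3.1",
            "Vital Status",
            _L.CUSTOM,
            [_x("vital-status", "General clinical state")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_3_1",
            fhir="(Patient.deceased)",
            pheno="Individual.vital_status.status",
            desc="ERDRI-CDS value set extended with Unknown.",
        ),
        _el(
            "3.2",
            "Time of Death",
            _L.CUSTOM,
            [_x("time-of-death", "Time of death")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Patient.deceasedDateTime",
            pheno="Individual.vital_status.time_of_death",
        ),
        _el(
            "3.3",
            "Cause of Death",
            _L.CUSTOM,
            [_x("cause-of-death", "Cause of death")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ICD-10 code",
            fhir="Patient.extension['patient-causeOfDeath'] (Suggestion)",
            pheno="Individual.vital_status.cause_of_death",
        ),
        _el(
            "3.4",
            "Age Category",
            _L.CUSTOM,
            [_x("age-category", "Age category")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            vs="vs_3_4",
            fhir="Observation.valueCodeableConcept",
            pheno="(Individual.time_at_last_encounter.ontology_class)",
            desc="Extensional SNOMED CT-based value set for the periods of life.",
        ),
        _el(
            "3.5",
            "Length of Gestation at Birth",
            _L.CUSTOM,
            [_x("length-of-gestation", "Length of gestation at birth")],
            _D.STRING,
            _T.ONTOLOGY,
            _A.NEITHER,
            spec="'XX+X' for completed weeks and days",
            fhir="Observation.valueString",
        ),
        _el(
            "3.6",
            "Undiagnosed RD Case",
            _L.CUSTOM,
            [_b(CodeSystem.ORDO, "616874",
                "Rare disorder without a determined diagnosis after full investigation")],
            _D.BOOLEAN,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_3_6",
            fhir="(Observation.value)",
            pheno="(Interpretation.progress_status)",
            desc="Boolean flag for cases without an established RD diagnosis.",
        ),
    ]

    s4 = [
        _el(
            "4.1",
            "Encounter Start",
            _L.STANDARD,
            [fhir_b("Encounter.period.start")],
            _D.DATE,
            _T.FHIR_SPEC,
            _A.FHIR,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Encounter.period.start",
        ),
        _el(
            "4.2",
            "Encounter End",
            _L.STANDARD,
            [fhir_b("Encounter.period.end")],
            _D.DATE,
            _T.FHIR_SPEC,
            _A.FHIR,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Encounter.period.end",
        ),
        _el(
            "4.3",
            "Encounter Status",
            _L.STANDARD,
            [_x("encounter-status", "Encounter status")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            vs="vs_4_3",
            fhir="Encounter.status",
        ),
        _el(
            "4.4",
            "Type of Encounter",
            _L.STANDARD,
            [fhir_b("Encounter.class")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_4_4",
            fhir="Encounter.class",
            desc="HL7 FHIR value set enhanced with the custom choice "
            "rd_specialist_center required by the ERDRI-CDS.",
        ),
    ]

    s5 = [
        _el(
            "5.1",
            "Disease",
            _L.CUSTOM,
            [_b(_SCT, "64572001", "Disease")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="multi-coding with ORDO, ICD-10, ICD-11, MONDO, OMIM_g, OMIM_p",
            fhir="Condition.code",
            pheno="Disease.term",
        ),
        _el(
            "5.2",
            "Verification Status",
            _L.STANDARD,
            [_x("verification-status", "Verification status")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_2",
            fhir="Condition.verificationStatus",
            pheno="(Disease.excluded)",
        ),
        _el(
            "5.3",
            "Age at Onset",
            _L.ERDRI_CDS,
            [_b(_SCT, "445518008", "Age at onset of clinical finding")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_3",
            fhir="(Condition.onsetAge)",
            pheno="(Disease.onset.ontology_class)",
        ),
        _el(
            "5.4",
            "Date of Onset",
            _L.CUSTOM,
            [_b(_SCT, "298059007", "Date of onset")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Condition.onsetDateTime",
            pheno="Disease.onset.timestamp",
        ),
        _el(
            "5.5",
            "Age at Diagnosis",
            _L.ERDRI_CDS,
            [_x("age-at-diagnosis", "Age at diagnosis")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_5",
            fhir="(Condition.recordedDate)",
        ),
        _el(
            "5.6",
            "Date of Diagnosis",
            _L.CUSTOM,
            [_x("date-of-diagnosis", "Date of diagnosis")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Condition.recordedDate",
            pheno="(Disease.onset)",
        ),
        _el(
            "5.7",
            "Body Site",
            _L.STANDARD,
            [_x("body-site", "Body site")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_7",
            fhir="Condition.bodySite",
            pheno="(Disease.term)",
        ),
        _el(
            "5.8",
            "Clinical Status",
            _L.STANDARD,
            [_x("clinical-status", "Clinical status")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_8",
            fhir="Condition.clinicalStatus",
            pheno="(Disease.resolution)",
        ),
        _el(
            "5.9",
            "Severity",
            _L.STANDARD,
            [_b(_SCT, "246112005", "Severity")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_5_9",
            fhir="Condition.severity",
        ),
    ]

    s61 = [
        _el(
            "6.1.1",
            "Genomic Diagnosis",
            _L.STANDARD,
            [_x("genomic-diagnosis", "Genomic diagnosis")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="OMIM_g / OMIM_p coding; linkable to 5.1 via shared OMIM codes",
            fhir="(Condition.code)",
            pheno="Interpretation.diagnosis.disease",
        ),
        _el(
            "6.1.2",
            "Progress Status of Interpretation",
            _L.STANDARD,
            [ga4gh_b("Interpretation.progress_status")],
            _D.CODE,
            _T.GA4GH_SPEC,
            _A.GA4GH,
            vs="vs_6_1_2",
            pheno="Interpretation.progress_status",
        ),
        _el(
            "6.1.3",
            "Interpretation Status",
            _L.STANDARD,
            [ga4gh_b("GenomicInterpretation.interpretation_status")],
            _D.CODE,
            _T.GA4GH_SPEC,
            _A.GA4GH,
            vs="vs_6_1_3",
            pheno="GenomicInterpretation.interpretation_status",
        ),
        _el(
            "6.1.4",
            "Genomic Analysis Method",
            _L.STANDARD,
            [fhir_b("Observation.method")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_6_1_4",
            fhir="Observation.method",
        ),
        _el(
            "6.1.5",
            "Reference Genome",
            _L.STANDARD,
            [fhir_b("Observation.component['genome-build']"),
             _b(CodeSystem.LOINC, "62374-4", "Human reference sequence assembly version")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.BOTH,
            vs="vs_6_1_5",
            fhir="Observation.component['genome-build']",
            pheno="(VariationDescriptor.vcf_record.genome_assembly)",
        ),
        _el(
            "6.1.6",
            "Genetic Mutation String",
            _L.STANDARD,
            [fhir_b("Observation.value"),
             _b(CodeSystem.LOINC, "x-genetic-mutation-string", "Genetic mutation string")],
            _D.STRING,
            _T.FHIR_SPEC,
            _A.BOTH,
            spec="unvalidated HGVS-like free text",
            fhir="(Observation.valueString)",
            pheno="(VariationDescriptor.description)",
            desc="Allows initial recording of genetic information with "
            "subsequent validation.",
        ),
        _el(
            "6.1.7",
            "Genomic DNA Change",
            _L.STANDARD,
            [fhir_b("Observation.component['genomic-hgvs']"),
             _b(CodeSystem.LOINC, "81290-9", "Genomic DNA change (gHGVS)")],
            _D.STRING,
            _T.FHIR_SPEC,
            _A.BOTH,
            spec="validated HGVS g. expression",
            fhir="Observation.component['genomic-hgvs']",
            pheno="VariationDescriptor.expressions['hgvs.g']",
        ),
        _el(
            "6.1.8",
            "Sequence DNA Change",
            _L.STANDARD,
            [fhir_b("Observation.component['coding-hgvs']"),
             _b(CodeSystem.LOINC, "48004-6", "DNA change (c.HGVS)")],
            _D.STRING,
            _T.FHIR_SPEC,
            _A.BOTH,
            spec="validated HGVS c. expression",
            fhir="Observation.component['coding-hgvs']",
            pheno="VariationDescriptor.expressions['hgvs.c']",
        ),
        _el(
            "6.1.9",
            "Amino Acid Change",
            _L.STANDARD,
            [fhir_b("Observation.component['protein-hgvs']"),
             _b(CodeSystem.LOINC, "48005-3", "Amino acid change (pHGVS)")],
            _D.STRING,
            _T.FHIR_SPEC,
            _A.BOTH,
            spec="validated HGVS p. expression",
            fhir="Observation.component['protein-hgvs']",
            pheno="VariationDescriptor.expressions['hgvs.p']",
        ),
        _el(
            "6.1.10",
            "Gene",
            _L.STANDARD,
            [fhir_b("Observation.component['gene-studied']"),
             _b(CodeSystem.LOINC, "48018-6", "Gene studied [ID]")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.BOTH,
            spec="HGNC gene identifier and symbol",
            fhir="Observation.component['gene-studied']",
            pheno="VariationDescriptor.gene_context",
        ),
        _el(
            "6.1.11",
            "Zygosity",
            _L.STANDARD,
            [_b(CodeSystem.LOINC, "53034-5", "Allelic state")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_1_11",
            fhir="Observation.component['allelic-state']",
            pheno="VariationDescriptor.allelic_state",
        ),
        _el(
            "6.1.12",
            "Genomic Source Class",
            _L.STANDARD,
            [fhir_b("Observation.component['genomic-source-class']"),
             _b(CodeSystem.LOINC, "48002-0", "Genomic source class")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_6_1_12",
            fhir="Observation.component['genomic-source-class']",
        ),
        _el(
            "6.1.13",
            "DNA Change Type",
            _L.STANDARD,
            [fhir_b("Observation.component['dna-change-type']"),
             _b(CodeSystem.LOINC, "48019-4", "DNA change type")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_6_1_13",
            fhir="Observation.component['dna-change-type']",
        ),
        _el(
            "6.1.14",
            "Clinical Significance (ACMG)",
            _L.STANDARD,
            [fhir_b("Observation.component['clinical-significance']"),
             _b(CodeSystem.LOINC, "53037-8", "Genetic variation clinical significance")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.BOTH,
            vs="vs_6_1_14",
            fhir="Observation.component['clinical-significance']",
        ),
        _el(
            "6.1.15",
            "Therapeutic Actionability",
            _L.STANDARD,
            [ga4gh_b("VariantInterpretation.therapeutic_actionability")],
            _D.CODE,
            _T.GA4GH_SPEC,
            _A.GA4GH,
            vs="vs_6_1_15",
            pheno="VariantInterpretation.therapeutic_actionability",
        ),
        _el(
            "6.1.16",
            "Clinical Annotation Level of Evidence",
            _L.STANDARD,
            [fhir_b("Observation.component['level-of-evidence']"),
             _b(CodeSystem.LOINC, "93044-6", "Level of evidence")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_6_1_16",
            fhir="Observation.component['level-of-evidence']",
        ),
    ]

    s62 = [
        _el(
            "6.2.1",
            "Phenotypic Finding",
            _L.ERDRI_CDS,
            [_b(CodeSystem.HPO, "HP:0000118", "Phenotypic abnormality")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open HPO coding",
            fhir="Observation.code",
            pheno="PhenotypicFeature.type",
        ),
        _el(
            "6.2.2",
            "Status",
            _L.STANDARD,
            [_x("phenotype-status", "Phenotypic finding status")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_2_2",
            fhir="(Observation.status)",
            pheno="PhenotypicFeature.excluded",
            desc="Value set simplified to Confirmed present and Refuted, "
            "corresponding to PhenotypicFeature.excluded.",
        ),
        _el(
            "6.2.3",
            "Determination Date",
            _L.STANDARD,
            # the one post-coordinated SNOMED CT expression in the model
            [_b(_SCT, "439272007:704321009=x-phenotype-determination",
                "Date of observation (post-coordinated)")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Observation.effectiveDateTime",
            pheno="(PhenotypicFeature.onset.timestamp)",
        ),
        _el(
            "6.2.4",
            "Resolution Date",
            _L.STANDARD,
            [_x("phenotype-resolution-date", "Resolution date")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="(Observation.effectivePeriod.end)",
            pheno="PhenotypicFeature.resolution",
        ),
        _el(
            "6.2.5",
            "Onset Category",
            _L.STANDARD,
            [_b(CodeSystem.HPO, "HP:0003674", "Onset")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_2_5",
            fhir="(Observation.component['onset-category'])",
            pheno="PhenotypicFeature.onset.ontology_class",
        ),
        _el(
            "6.2.6",
            "Temporal Pattern",
            _L.STANDARD,
            [_x("temporal-pattern", "Temporal pattern", CodeSystem.HPO)],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_2_6",
            fhir="(Observation.component['temporal-pattern'])",
            pheno="(PhenotypicFeature.modifiers)",
        ),
        _el(
            "6.2.7",
            "Severity",
            _L.STANDARD,
            [_b(CodeSystem.HPO, "HP:0012824", "Severity")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_2_7",
            fhir="(Observation.component['severity'])",
            pheno="PhenotypicFeature.severity",
        ),
        _el(
            "6.2.8",
            "Modifiers",
            _L.STANDARD,
            [_b(CodeSystem.HPO, "HP:0012823", "Clinical modifier")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open HPO clinical-modifier coding or NCBITaxon agent",
            fhir="(Observation.component['modifier'])",
            pheno="PhenotypicFeature.modifiers",
        ),
        _el(
            "6.2.9",
            "Evidence",
            _L.STANDARD,
            [ga4gh_b("PhenotypicFeature.evidence")],
            _D.CODE,
            _T.GA4GH_SPEC,
            _A.BOTH,
            spec="open ECO coding",
            fhir="(Observation.derivedFrom)",
            pheno="PhenotypicFeature.evidence",
        ),
    ]

    s63 = [
        _el(
            "6.3.1",
            "Assay",
            _L.STANDARD,
            [_x("assay", "Assay", CodeSystem.NCIT)],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open NCIT / LOINC coding",
            fhir="Observation.code",
            pheno="Measurement.assay",
        ),
        _el(
            "6.3.2",
            "Value",
            _L.STANDARD,
            [_x("measurement-value", "Value", CodeSystem.NCIT)],
            _D.STRING,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="decimal number",
            fhir="Observation.valueQuantity.value",
            pheno="Measurement.value.quantity.value",
        ),
        _el(
            "6.3.3",
            "Value Unit",
            _L.STANDARD,
            [_x("value-unit", "Value unit", CodeSystem.NCIT)],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open UO coding",
            fhir="Observation.valueQuantity.unit",
            pheno="Measurement.value.quantity.unit",
        ),
        _el(
            "6.3.4",
            "Interpretation",
            _L.STANDARD,
            [_x("interpretation", "Interpretation", CodeSystem.NCIT)],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open NCIT coding",
            fhir="Observation.interpretation",
            pheno="(Measurement.description)",
        ),
        _el(
            "6.3.5",
            "Time Observed",
            _L.STANDARD,
            [_x("time-observed", "Time observed")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Observation.effectiveDateTime",
            pheno="Measurement.time_observed",
        ),
        _el(
            "6.3.6",
            "Procedure",
            _L.STANDARD,
            [_x("procedure", "Procedure")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="open SNOMED CT / NCIT coding",
            fhir="Procedure.code",
            pheno="Measurement.procedure.code",
        ),
    ]

    s64 = [
        _el(
            "6.4.1",
            "Family Member Pseudonym",
            _L.STANDARD,
            [_b(CodeSystem.CUSTOM, "rd_cdm:family_member_pseudonym",
                "Family member pseudonym")],
            _D.STRING,
            _T.CUSTOM,
            _A.FHIR,
            fhir="FamilyMemberHistory.name",
            pheno="Family.relatives.id",
        ),
        _el(
            "6.4.2",
            "Propositus/-a",
            _L.CUSTOM,
            [_x("propositus", "Propositus/-a")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_6_4_2",
            pheno="(Family.proband_id)",
        ),
        _el(
            "6.4.3",
            "Relationship to Index Case",
            _L.CUSTOM,
            [_x("relationship-to-index-case", "Relationship to index case")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_6_4_3",
            pheno="(Pedigree.persons)",
        ),
        _el(
            "6.4.4",
            "Consanguinity",
            _L.CUSTOM,
            [_x("consanguinity", "Consanguinity")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_6_4_4",
            pheno="Family.consanguinous_parents",
        ),
        _el(
            "6.4.5",
            "Family Member Relationship",
            _L.STANDARD,
            [_x("family-member-relationship", "Family member relationship")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            vs="vs_6_4_5",
            fhir="FamilyMemberHistory.relationship",
            pheno="(Family.relatives)",
            desc="SNOMED CT-based value set for natural family members, "
            "based on the HL7 FHIR FamilyMember value set.",
        ),
        _el(
            "6.4.6",
            "Family Member Record Status",
            _L.STANDARD,
            [fhir_b("FamilyMemberHistory.status")],
            _D.CODE,
            _T.FHIR_SPEC,
            _A.FHIR,
            vs="vs_6_4_6",
            fhir="FamilyMemberHistory.status",
        ),
        _el(
            "6.4.7",
            "Family Member Sex",
            _L.STANDARD,
            [_x("family-member-sex", "Family member sex")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            vs="vs_6_4_7",
            fhir="FamilyMemberHistory.sex",
            pheno="Family.relatives.subject.sex",
        ),
        _el(
            "6.4.8",
            "Family Member Age",
            _L.STANDARD,
            [_x("family-member-age", "Family member age")],
            _D.INTEGER,
            _T.ONTOLOGY,
            _A.NEITHER,
            spec="age in completed years; Age value type required in HL7 FHIR",
            fhir="(FamilyMemberHistory.ageAge)",
            pheno="(Family.relatives.subject.time_at_last_encounter.age)",
        ),
        _el(
            "6.4.9",
            "Family Member Date of Birth",
            _L.STANDARD,
            [_b(_SCT, "184099003", "Date of birth")],
            _D.DATE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="FamilyMemberHistory.bornDate",
            pheno="Family.relatives.subject.date_of_birth",
        ),
        _el(
            "6.4.10",
            "Family Member Deceased",
            _L.STANDARD,
            [_x("family-member-deceased", "Family member deceased")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_6_4_10",
            fhir="(FamilyMemberHistory.deceasedBoolean)",
            pheno="(Family.relatives.subject.vital_status.status)",
            desc="FHIR deceasedBoolean altered to an extended value set "
            "including the option Unknown.",
        ),
        _el(
            "6.4.11",
            "Family Member Cause of Death",
            _L.STANDARD,
            [_x("family-member-cause-of-death", "Family member cause of death")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            spec="ICD-10 code; requires 6.4.10 = yes",
            fhir="(FamilyMemberHistory.condition.code)",
            pheno="(Family.relatives.subject.vital_status.cause_of_death)",
        ),
        _el(
            "6.4.12",
            "Family Member Deceased Age",
            _L.STANDARD,
            [_x("family-member-deceased-age", "Family member deceased age")],
            _D.INTEGER,
            _T.ONTOLOGY,
            _A.NEITHER,
            spec="age in completed years; requires 6.4.10 = yes",
            fhir="(FamilyMemberHistory.deceasedAge)",
            pheno="(Family.relatives.subject.vital_status.time_of_death)",
        ),
        _el(
            "6.4.13",
            "Family Member Diagnosis",
            _L.CUSTOM,
            [_x("family-member-diagnosis", "Family member diagnosis")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.BOTH,
            spec="must match a code captured in 5.1 or 6.1.1",
            fhir="FamilyMemberHistory.condition.code",
            pheno="Pedigree.persons.affected_status",
        ),
    ]
    # datatype alignments that deviate from the constructor defaults above
    # are set explicitly here to match the published data-type layer
    _set_dt = {
        "6.4.1": _A.FHIR, "6.4.2": _A.NEITHER, "6.4.3": _A.NEITHER,
        "6.4.4": _A.NEITHER, "6.4.5": _A.FHIR, "6.4.6": _A.FHIR,
        "6.4.7": _A.BOTH, "6.4.8": _A.NEITHER, "6.4.9": _A.BOTH,
        "6.4.10": _A.NEITHER, "6.4.11": _A.FHIR, "6.4.12": _A.NEITHER,
        "6.4.13": _A.BOTH,
    }
    s64 = [
        el.model_copy(update={"datatype_alignment": _set_dt[el.element_id]})
        for el in s64
    ]

    s7 = [
        _el(
            "7.1",
            "Consent Status",
            _L.STANDARD,
            [_x("consent-status", "Consent status")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.FHIR,
            vs="vs_7_1",
            fhir="Consent.status",
        ),
        _el(
            "7.2",
            "Consent Date",
            _L.STANDARD,
            [fhir_b("Consent.dateTime")],
            _D.DATE,
            _T.FHIR_SPEC,
            _A.FHIR,
            spec="ISO 8601 date (YYYY-MM-DD)",
            fhir="Consent.dateTime",
        ),
        _el(
            "7.3",
            "Health Policy Monitoring",
            _L.STANDARD,
            [_b(CodeSystem.LOINC, "77602-1", "Research study consent")],
            _D.STRING,
            _T.ONTOLOGY,
            _A.FHIR,
            fhir="Consent.policy",
        ),
        _el(
            "7.4",
            "Agreement to Be Contacted for Research Purposes",
            _L.ERDRI_CDS,
            [_b(CodeSystem.CUSTOM, "rd_cdm:research_contact",
                "Agreement to be contacted for research purposes")],
            _D.CODE,
            _T.CUSTOM,
            _A.FHIR,
            vs="vs_7_4",
            fhir="(Consent.provision)",
        ),
        _el(
            "7.5",
            "Consent to the Reuse of Data",
            _L.ERDRI_CDS,
            [_b(CodeSystem.CUSTOM, "rd_cdm:data_reuse_consent",
                "Consent to the reuse of data")],
            _D.CODE,
            _T.CUSTOM,
            _A.FHIR,
            vs="vs_7_5",
            fhir="(Consent.provision)",
        ),
        _el(
            "7.6",
            "Biological Sample",
            _L.ERDRI_CDS,
            [_x("biological-sample", "Biological sample")],
            _D.CODE,
            _T.ONTOLOGY,
            _A.NEITHER,
            vs="vs_7_6",
        ),
        _el(
            "7.7",
            "Link to a Biobank",
            _L.ERDRI_CDS,
            [_b(CodeSystem.CUSTOM, "rd_cdm:biobank_link", "Link to a biobank")],
            _D.STRING,
            _T.CUSTOM,
            _A.NEITHER,
        ),
    ]

    s8 = [
        _el(
            "8.1",
            "Classification of Functioning/Disability",
            _L.ERDRI_CDS,
            [_b(CodeSystem.CUSTOM, "rd_cdm:icf_score", "ICF score")],
            _D.CODE,
            _T.CUSTOM,
            _A.NEITHER,
            spec="value encoded with the WHO ICF classification; "
            "HPO HP:0031058 is a possible Phenopacket surrogate",
        ),
    ]

    return {
        "1": s1, "2": s2, "3": s3, "4": s4, "5": s5,
        "6.1": s61, "6.2": s62, "6.3": s63, "6.4": s64,
        "7": s7, "8": s8,
    }


_SECTION_NAMES = {
    "1": "Formal Criteria",
    "2": "Personal Information",
    "3": "Patient Status",
    "4": "Care Pathway",
    "5": "Disease",
    "6.1": "Genetic Findings",
    "6.2": "Phenotypic Findings",
    "6.3": "Measurements",
    "6.4": "Family History",
    "7": "Consent",
    "8": "Disability",
}


def _vs_6_4_6() -> ValueSet:
    return ValueSet(
        id="vs_6_4_6",
        name="Family Member Record Status",
        choices=_fhir_choices(
            ("partial", "Partial"),
            ("completed", "Completed"),
            ("entered-in-error", "Entered in Error"),
            ("health-unknown", "Health Unknown"),
        ),
        derivation=Derivation.VS,
        source_standard=SourceStandard.FHIR,
    )


@lru_cache(maxsize=1)
def builtin_registry() -> ModelRegistry:
    """Return the bundled RD-CDM v2.0.0 registry (validated on build)."""
    from .model import DEFAULT_CARDINALITIES

    elements = _elements()
    sections = [
        Section(
            id=sid,
            name=_SECTION_NAMES[sid],
            elements=els,
            recommended_cardinality=DEFAULT_CARDINALITIES[sid],
        )
        for sid, els in elements.items()
    ]
    value_sets = _value_sets()
    # keep ordering stable: insert the FHIR-derived 6.4.6 set with its section
    idx = next(i for i, v in enumerate(value_sets) if v.id == "vs_6_4_7")
    value_sets.insert(idx, _vs_6_4_6())
    return ModelRegistry(
        version=REGISTRY_VERSION,
        sections=sections,
        value_sets=value_sets,
        code_system_versions=dict(CODE_SYSTEM_VERSIONS),
    )
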