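# Methods

## Model transcription

The bundled registry (`rdcdm.builtin`) transcribes the rare disease common
data model v2.0.0: 11 sections — formal criteria (1), personal information
(2), patient status (3), care pathway (4), disease (5), genetic findings
(6.1), phenotypic findings (6.2), measurements (6.3), family history (6.4),
consent (7), disability (8) — holding 2, 5, 6, 4, 9, 16, 9, 6, 13, 7 and 1
data elements respectively (78 in total), plus 39 value sets.

Each element stores:

- its identifying ontology code(s) (SNOMED CT, LOINC, NCIT, HPO, …) with
  pinned code-system versions;
- declared data type (`CODE`, `DATE`, `STRING`, `INTEGER`, `BOOLEAN`) and an
  optional value-set binding;
- the HL7 FHIR R4 (v4.0.1) expression and/or GA4GH Phenopacket Schema v2.0
  element it maps to, when one exists. Partial mappings are kept in
  brackets (e.g. `(Condition.onsetAge)`); extension proposals carry a
  `Suggestion:` prefix. Both still count as "aligned" — the brackets record
  mapping quality, not absence;
- labelling provenance (`ERDRI_CDS`, `STANDARD`, `CUSTOM`), terminology
  source (`FHIR_SPEC`, `GA4GH_SPEC`, `ONTOLOGY`, `CUSTOM`) and data-type
  alignment (`FHIR`, `GA4GH`, `BOTH`, `NEITHER`).

### Placeholder codes

Where the source material names a value-set member without printing its
ontology code, the fixture stores a clearly synthetic code
(`x-<slugified-display>`, e.g. `x-onset-in-childhood`) flagged
`placeholder: true`. This keeps value sets complete and machine-checkable
without fabricating real-looking ontology identifiers. Real codes are used
wherever the source prints them (e.g. SNOMED CT `419099009` *Dead*,
LOINC ACMG classes `LA6668-3` …). Ten genetic-findings elements whose
primary binding comes from a standard specification additionally carry their
secondary LOINC panel codes, which is what makes 63 elements in total carry
a clinical terminology code.

## Harmonisation layers

All six layers are *derived* from element/value-set metadata at call time;
no category label is stored:

| Layer | Population | Categories | Derivation |
|---|---|---|---|
| ALIGNMENT | 78 elements | FHIR / GA4GH / BOTH / NEITHER | presence of `fhir_expression` / `phenopacket_element` |
| LABELLING | 78 elements | ERDRI_CDS / STANDARD / CUSTOM | `label_source` |
| TERMINOLOGY_BINDING | 78 elements | FHIR_SPEC / GA4GH_SPEC / ONTOLOGY / CUSTOM | `terminology_source` |
| DATA_TYPE | 78 elements | FHIR / GA4GH / BOTH / NEITHER | `datatype_alignment` |
| VALUE_SET | 39 value-set uses | VS_FHIR / VS_GA4GH / ONTOLOGY_ENCODED / MIXED | derivation kind + choice code systems |
| VALUE_SET_CHOICE | 227 net choices | FHIR_CODE / GA4GH_CODE / SNOMED / LOINC / HPO / NCIT / CUSTOM | per-choice `source_category` |

A value set reused by two elements counts once per hosting element, which is
why the 39 uses carry 227 net choices (the 14-member family value set is
hosted twice). The layer-5 supplementary figure "datatype-aligned value
sets" (34) counts sets whose host element is datatype-aligned with at least
one standard, plus two-choice sets on `BOOLEAN` hosts (a yes/no set bijects
onto the standards' native boolean even though the element's own datatype
flag is `NEITHER`). Percentages are integers rounded half-up with
`decimal.Decimal` (banker's rounding would shift several printed figures).

## Validation

`validate_record` applies the rule catalogue documented in
`rdcdm/validation.py` and returns a list of issues — an empty list iff the
record satisfies rules (a)–(g); semantic problems are never raised. The HGVS
plausibility check is deliberately *not* part of `validate_record`: it is a
syntactic shape heuristic (`reference:prefix.description`, not a full HGVS
grammar) returning PASS/WARN, and the free-text variant level always passes
because the model allows initial free-text recording. Gestational age uses a
`weeks+days` pattern with weeks 0–45 and days 0–6.

Cardinality profiles: the `default` profile uses the model's recommended
cardinalities (sections 1 and 7 required, 2/3/8 at most once, the rest
0..n); `strict` additionally requires sections 2 and 3. Arbitrary profiles
load from YAML.

## Export mappings

**Phenopacket** (`to_phenopacket` / `extract_record`): native fields are
populated per the model's mapping statements (subject, vitalStatus,
diseases, phenotypicFeatures, measurements, interpretations, family,
metaData resource closure over used CURIE prefixes). Because several targets
are enum- or oneOf-constrained and narrower than the model's value sets,
every block also carries an `rdCdmExtensions` map with the exact source
values; extraction prefers that map (lossless inversion, verified
property-style over seeded cohorts) and falls back to native inverses for
foreign documents. Section-6.1 instances group into one interpretation per
(genomic diagnosis, progress status) pair and remember their instance index.

**FHIR** (`to_fhir`): Patient, Encounter, Condition, Observation (karyotype,
age category, gestation, undiagnosed flag, disability, phenotype,
measurement, and genomics-style component Observations per variant),
FamilyMemberHistory and Consent, as plain R4-shaped JSON. Custom codes are
emitted with system `rd_cdm` and prefix-stripped codes; partial mappings use
namespaced extensions (`urn:rd-cdm:extension:<element id>`). Populated
values of the eight elements with no FHIR expression are returned in an
`unmapped` manifest instead of being dropped. `check_fhir_shape` performs
structural checks (single Patient, reference closure, coding completeness) —
it is not a FHIR profile validator.

**ERDRI-CDS** (`to_erdri`): a single 16-column row per record. First contact
with a specialised centre = earliest encounter start among encounters whose
class is the custom RD-specialist-centre code; onset/diagnosis ages come
from the earliest-dated disease instance; diagnosis codes are filtered to
ORDO/OMIM CURIEs. Header labels are provisional (the official label list is
cited, not reprinted, in the source narrative). The projection is invariant
under permutation of repeatable-section instances.

## Synthetic cohorts

Each record draws from `random.Random(f"{seed}:{index}")` — string seeding
is hash-stable across platforms and per-record streams make cohorts
prefix-stable (record *i* is identical for n=5 and n=500). Coded values come
from registry value sets; free identifiers use transparent toy pools
(`x-ordo-1`, `HP:x000001`, `XT_000000.1:g.…`). Dates are generated in order
(birth ≤ encounters/onset ≤ diagnosis ≤ admission ≤ death) and dependent
fields (cause of death, family-member death details, family diagnosis
linkage) are only emitted when their preconditions hold, so generated
records produce zero validation issues, warnings included. Knobs:
per-section missingness, repeat ranges, and an `unknown_rate` governing how
often "Unknown" choices are picked (realised fraction verified within ±0.08
at n=200).

## Library choices

Pydantic v2 models provide schema generation (`model_json_schema`) and
validation for the registry and records; JSON Schema documents are emitted
in the 2020-12 dialect. Standard-library `csv`, `json`, `decimal` and
`random` cover serialisation, rounding and generation. Phenopacket and FHIR
documents are hand-shaped JSON trees rather than bindings to protobuf/FHIR
packages, keeping the dependency footprint to pydantic, click and PyYAML;
the shape checkers document exactly which structural guarantees are made.
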