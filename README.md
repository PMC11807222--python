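# rdcdm

An ontology-based rare disease common data model (RD-CDM v2.0.0) as a typed,
executable Python library.

## The problem

Roughly 6–8 % of the population lives with one of several thousand rare
diseases, yet clinical data about these patients is scattered across
registries, hospital information systems and research databases that do not
speak the same language. The European Rare Disease Registry Infrastructure's
Common Data Set (ERDRI-CDS) defines *what* to capture, HL7 FHIR defines *how*
to exchange it with hospital systems, and the GA4GH Phenopacket Schema
defines *how* to exchange deep phenotypic and genomic detail for research.
None of the three alone covers routine rare-disease care, and mapping between
them by hand is error-prone.

A rare disease common data model (RD-CDM) reconciles the three: 78 data
elements in 11 sections, each element annotated with ontology codes
(SNOMED CT, LOINC, HPO, NCIT, ICD-10/11, ORDO, OMIM, HGNC, HGVS, …), a FHIR R4
expression where one exists, and a Phenopacket v2.0 schema element where one
exists. This package makes that model *executable*:

- **`rdcdm.model` / `rdcdm.builtin`** — the full registry (78 elements,
  39 value sets, 227 net value-set choices) as typed, schema-checked objects,
  exportable/reloadable as JSON and as a review-friendly CSV table;
- **`rdcdm.records` / `rdcdm.validation`** — patient records keyed by element
  id, with cardinality profiles and a rule catalogue (typing, value-set
  membership, date/gestation/decimal formats, encounter periods, temporal
  ordering, cause-of-death and family-history dependencies, diagnosis
  linkage) plus a standalone HGVS plausibility check;
- **`rdcdm.harmonisation`** — the model's six harmonisation layers
  (standard alignment, labelling, terminology binding, data-type alignment,
  value-set derivation, per-choice encoding) recomputed from metadata,
  never read from stored labels;
- **`rdcdm.phenopacket` / `rdcdm.fhir` / `rdcdm.erdri`** — lossless
  Phenopacket-shaped export with an exact inverse, FHIR R4-shaped resources
  with an unmapped-value manifest, and the flat 16-column ERDRI-CDS row;
- **`rdcdm.synth`** — seedable synthetic cohorts that pass validation
  cleanly, for pipeline testing without real patient data.

## Worked example

Generate a synthetic cohort, validate it, and convert one record:

```console
$ rdcdm generate --n 3 --seed 11 --out cohort
wrote 3 records to cohort
$ rdcdm validate cohort/record-00000.json
OK: record is valid
```

Every record is a flat JSON document keyed by section and element ids
(`{"1": {"1.1": "SYN-11-00000", ...}, "5": [...], ...}`). Conversion to a
Phenopacket-shaped document:

```pycon
>>> import json
>>> from rdcdm import builtin_registry, read_record, to_phenopacket
>>> reg = builtin_registry()
>>> rec = read_record("cohort/record-00000.json", reg)
>>> packet = to_phenopacket(rec, reg)
>>> print(json.dumps(packet["subject"], indent=2, sort_keys=True))
{
  "dateOfBirth": "1967-05-16T00:00:00Z",
  "gender": {
    "id": "SNOMEDCT:x-male-gender",
    "label": "Male gender"
  },
  "id": "SYN-11-00000",
  "karyotypicSex": "XO",
  "sex": "OTHER_SEX",
  "timeAtLastEncounter": {
    "ontologyClass": {
      "id": "SNOMEDCT:x-toddler",
      "label": "Toddler"
    },
    "timestamp": "2010-12-28T00:00:00Z"
  },
  "vitalStatus": {
    "status": "ALIVE"
  }
}
```

(Codes prefixed `x-` are clearly-synthetic placeholders; see
`docs/methods.md`.) The same record flattens to an ERDRI-CDS row:

```console
$ rdcdm export erdri cohort/*.json | cut -c1-120
pseudonym,date_of_birth,sex,patient_status,date_of_death,first_contact_specialised_centre,age_at_onset,age_at_diagnosis
SYN-11-00000,1967-05-16,Indeterminate sex,Alive,,,Congenital onset,Diagnosis in childhood,ORPHA:x-ordo-5; OMIM:x-omim-3
SYN-11-00001,1988-01-01,Intersex,Dead,2021-09-12,,Onset in adolescence,Diagnosis in childhood,ORPHA:x-ordo-4; OMIM:x-om
SYN-11-00002,1974-05-09,Intersex,Lost to follow-up,,,Antenatal onset,Diagnosis in childhood,ORPHA:x-ordo-1; OMIM:x-omim
```

The harmonisation report recomputes the model's alignment statistics from
element metadata:

```console
$ rdcdm report-harmonisation --format md | head -18
## ALIGNMENT

| Section | FHIR | GA4GH | BOTH | NEITHER | Σ |
|---|---|---|---|---|---|
| 1 | 0 | 0 | 2 | 0 | 2 |
| 2 | 1 | 0 | 4 | 0 | 5 |
| 3 | 1 | 0 | 5 | 0 | 6 |
| 4 | 4 | 0 | 0 | 0 | 4 |
| 5 | 2 | 0 | 7 | 0 | 9 |
| 6.1 | 5 | 3 | 8 | 0 | 16 |
| 6.2 | 0 | 0 | 9 | 0 | 9 |
| 6.3 | 0 | 0 | 6 | 0 | 6 |
| 6.4 | 1 | 3 | 9 | 0 | 13 |
| 7 | 5 | 0 | 0 | 2 | 7 |
| 8 | 0 | 0 | 0 | 1 | 1 |
| Sum | 19 | 6 | 50 | 3 | 78 |
| % | 24% | 8% | 64% | 4% |  |
```

75 of 78 elements (96 %) align with at least one international standard.
Other CLI verbs: `rdcdm registry` (JSON/CSV dump), `rdcdm convert phenopacket
| fhir`, `rdcdm validate --profile strict|<file>`. Exit codes: 0 success,
1 validation errors, 2 usage/parse errors.

## Reproduction

All headline statistics of the bundled model are recomputed from metadata
and checked in CI-style tests:

```bash
python -m pytest                        # full suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script writes the model statistics (aligned elements 75/78,
standard-derived value sets 15/39, net choices 227, standard-coded choices
91/227, terminology-coded choices 135/227, datatype-aligned value sets 34/39,
ontology-bound elements 53/78, custom-terminology elements 5/78,
standard-labelled elements 52/78) as JSON. They are deterministic functions
of the registry; the `--seed` flag exists for interface uniformity only.

Synthetic cohorts are fully deterministic per `(seed, index)`; re-running
`rdcdm generate` with the same arguments reproduces the same records
byte-for-byte.

## Documentation

`docs/methods.md` describes the model transcription, placeholder-code
policy, harmonisation-layer definitions, rounding, export mapping decisions
and the synthetic-cohort design.
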