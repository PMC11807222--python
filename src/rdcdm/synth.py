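"""Seedable synthetic cohorts that pass validation cleanly.

Every record draws from its own pseudorandom stream split from the master
seed (``Random(f"{seed}:{index}")``), so changing the cohort size never
perturbs earlier records. All coded values come from the registry's value
sets or clearly synthetic ``x-``-prefixed toy codes (fabricated accession
patterns avoid implying real variants or disorders); dates are internally
ordered (birth <= admission/onset <= diagnosis/death) so no temporal
warnings are emitted.
"""

from __future__ import annotations

import random
from datetime import date, timedelta
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .model import CodeBinding, CodeSystem, ModelRegistry, ValueSet
from .records import PatientRecord, SectionInstance


class CohortConfig(BaseModel):
    n: int = 10
    seed: int = 0
    #: per-section probability of omitting the section entirely
    #: (sections 1 and 7 are profile minima and are never omitted)
    missingness: dict[str, float] = {}
    #: per-repeatable-section (min, max) instance counts
    repeat_range: dict[str, tuple[int, int]] = {}
    #: probability of choosing an "Unknown" choice where the value set has one
    unknown_rate: float = Field(default=0.1, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _valid(self) -> "CohortConfig":
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for sid, p in self.missingness.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{sid}] must be in [0, 1]")
        for sid, (lo, hi) in self.repeat_range.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"repeat_range[{sid}] must satisfy 0 <= min <= max")
        return self


_DEFAULT_REPEATS = {
    "4": (1, 2), "5": (1, 2), "6.1": (1, 2),
    "6.2": (1, 3), "6.3": (1, 2), "6.4": (1, 2),
}

#: toy code pools (clearly synthetic identifiers)
_ORDO_POOL = [("x-ordo-%d" % k, "Synthetic rare disorder %d" % k) for k in range(1, 6)]
_OMIM_POOL = [("x-omim-%d" % k, "Synthetic Mendelian disorder %d" % k) for k in range(1, 5)]
_HPO_POOL = [("HP:x%06d" % k, "Synthetic phenotypic finding %d" % k) for k in range(1, 7)]
_GENE_POOL = [("x-hgnc-%d" % k, "TOY%d" % k) for k in range(1, 5)]
_ASSAY_POOL = [("x-assay-%d" % k, "Synthetic assay %d" % k) for k in range(1, 4)]
_UNIT_POOL = [("x-unit-1", "g/L"), ("x-unit-2", "mmol/L")]
_COUNTRIES = ["DE", "FR", "IT", "ES", "NL"]
_ICD10_POOL = [("x-icd10-%d" % k, "Synthetic ICD-10 cause %d" % k) for k in (1, 2)]
_ICF_POOL = [("x-icf-%d" % k, "Synthetic ICF category %d" % k) for k in (1, 2)]
_ECO_POOL = [("x-eco-1", "Synthetic clinical evidence")]


def _binding(system: CodeSystem, pool_entry: tuple[str, str]) -> CodeBinding:
    code, display = pool_entry
    return CodeBinding(system=system, code=code, display=display)


def _is_unknown(display: str) -> bool:
    return display.upper().startswith("UNKNOWN")


def _pick(rng: random.Random, vs: ValueSet, unknown_rate: float) -> CodeBinding:
    unknowns = [c for c in vs.choices if _is_unknown(c.display)]
    others = [c for c in vs.choices if not _is_unknown(c.display)]
    if unknowns and rng.random() < unknown_rate:
        return rng.choice(unknowns).binding
    return rng.choice(others or unknowns).binding


def _date(rng: random.Random, start: date, end: date) -> date:
    span = max((end - start).days, 0)
    return start + timedelta(days=rng.randint(0, span))


def _iso(d: date) -> str:
    return d.isoformat()


class _RecordBuilder:
    def __init__(self, registry: ModelRegistry, config: CohortConfig,
                 rng: random.Random, index: int):
        self.registry = registry
        self.config = config
        self.rng = rng
        self.index = index

    def pick(self, element_id: str) -> CodeBinding:
        vs = self.registry.element_value_set(element_id)
        return _pick(self.rng, vs, self.config.unknown_rate)

    def omitted(self, section_id: str) -> bool:
        p = self.config.missingness.get(section_id, 0.0)
        return self.rng.random() < p

    def repeats(self, section_id: str) -> int:
        if self.omitted(section_id):
            return 0
        lo, hi = self.config.repeat_range.get(
            section_id, _DEFAULT_REPEATS[section_id]
        )
        return self.rng.randint(lo, hi)

    def build(self) -> PatientRecord:
        rng = self.rng
        cfg = self.config
        birth = _date(rng, date(1950, 1, 1), date(2010, 12, 31))
        admission = _date(rng, birth + timedelta(days=365), date(2023, 12, 31))
        pseudonym = f"SYN-{cfg.seed}-{self.index:05d}"

        singletons: dict[str, SectionInstance] = {}
        repeats: dict[str, list[SectionInstance]] = {}

        singletons["1"] = SectionInstance(
            section_id="1", values={"1.1": pseudonym, "1.2": _iso(admission)}
        )

        if not self.omitted("2"):
            singletons["2"] = SectionInstance(section_id="2", values={
                "2.1": _iso(birth),
                "2.2": self.pick("2.2"),
                "2.3": self.pick("2.3"),
                "2.4": self.pick("2.4"),
                "2.5": CodeBinding(
                    system=CodeSystem.ISO3166, code=rng.choice(_COUNTRIES),
                    display=rng.choice(_COUNTRIES),
                ),
            })

        if not self.omitted("3"):
            vital = self.pick("3.1")
            values = {
                "3.1": vital,
                "3.4": self.pick("3.4"),
                "3.5": f"{rng.randint(24, 42)}+{rng.randint(0, 6)}",
                "3.6": rng.random() < 0.2,
            }
            if vital.display == "Dead":
                death = _date(rng, admission, date(2024, 12, 31))
                values["3.2"] = _iso(death)
                values["3.3"] = _binding(CodeSystem.ICD10, rng.choice(_ICD10_POOL))
            singletons["3"] = SectionInstance(section_id="3", values=values)

        encounters = []
        for _ in range(self.repeats("4")):
            start = _date(rng, birth, admission)
            end = _date(rng, start, admission)
            encounters.append(SectionInstance(section_id="4", values={
                "4.1": _iso(start),
                "4.2": _iso(end),
                "4.3": self.pick("4.3"),
                "4.4": self.pick("4.4"),
            }))
        if encounters:
            repeats["4"] = encounters

        diseases = []
        disease_codes: list[CodeBinding] = []
        for _ in range(self.repeats("5")):
            onset = _date(rng, birth, admission)
            diagnosis = _date(rng, onset, admission)
            primary = _binding(CodeSystem.ORDO, rng.choice(_ORDO_POOL))
            secondary = _binding(CodeSystem.OMIM_G, rng.choice(_OMIM_POOL))
            disease_codes.extend([primary, secondary])
            diseases.append(SectionInstance(section_id="5", values={
                "5.1": [primary, secondary],
                "5.2": self.pick("5.2"),
                "5.3": self.pick("5.3"),
                "5.4": _iso(onset),
                "5.5": self.pick("5.5"),
                "5.6": _iso(diagnosis),
                "5.7": self.pick("5.7"),
                "5.8": self.pick("5.8"),
                "5.9": self.pick("5.9"),
            }))
        if diseases:
            repeats["5"] = diseases

        variants = []
        for k in range(self.repeats("6.1")):
            gene = _binding(CodeSystem.HGNC, rng.choice(_GENE_POOL))
            genomic_diag = _binding(CodeSystem.OMIM_G, rng.choice(_OMIM_POOL))
            disease_codes.append(genomic_diag)
            pos = rng.randint(100, 9999)
            variants.append(SectionInstance(section_id="6.1", values={
                "6.1.1": genomic_diag,
                "6.1.2": self.pick("6.1.2"),
                "6.1.3": self.pick("6.1.3"),
                "6.1.4": self.pick("6.1.4"),
                "6.1.5": self.pick("6.1.5"),
                "6.1.6": f"possible variant near {gene.display}",
                "6.1.7": f"XT_{self.index:06d}.{k + 1}:g.{pos}A>G",
                "6.1.8": f"XM_{self.index:06d}.{k + 1}:c.{pos % 500 + 1}A>G",
                "6.1.9": f"XP_{self.index:06d}.{k + 1}:p.Arg{pos % 90 + 1}Ser",
                "6.1.10": gene,
                "6.1.11": self.pick("6.1.11"),
                "6.1.12": self.pick("6.1.12"),
                "6.1.13": self.pick("6.1.13"),
                "6.1.14": self.pick("6.1.14"),
                "6.1.15": self.pick("6.1.15"),
                "6.1.16": self.pick("6.1.16"),
            }))
        if variants:
            repeats["6.1"] = variants

        features = []
        for _ in range(self.repeats("6.2")):
            determined = _date(rng, birth, admission)
            resolved = _date(rng, determined, admission)
            features.append(SectionInstance(section_id="6.2", values={
                "6.2.1": _binding(CodeSystem.HPO, rng.choice(_HPO_POOL)),
                "6.2.2": self.pick("6.2.2"),
                "6.2.3": _iso(determined),
                "6.2.4": _iso(resolved),
                "6.2.5": self.pick("6.2.5"),
                "6.2.6": self.pick("6.2.6"),
                "6.2.7": self.pick("6.2.7"),
                "6.2.8": _binding(CodeSystem.HPO, rng.choice(_HPO_POOL)),
                "6.2.9": _binding(CodeSystem.ECO, _ECO_POOL[0]),
            }))
        if features:
            repeats["6.2"] = features

        measurements = []
        for _ in range(self.repeats("6.3")):
            measurements.append(SectionInstance(section_id="6.3", values={
                "6.3.1": _binding(CodeSystem.NCIT, rng.choice(_ASSAY_POOL)),
                "6.3.2": f"{rng.randint(1, 200)}.{rng.randint(0, 9)}",
                "6.3.3": _binding(CodeSystem.UO, rng.choice(_UNIT_POOL)),
                "6.3.4": _binding(
                    CodeSystem.NCIT, ("x-interpretation-1", "Within reference range")
                ),
                "6.3.5": _iso(_date(rng, birth, admission)),
                "6.3.6": _binding(
                    CodeSystem.SNOMED_CT, ("x-procedure-1", "Synthetic procedure")
                ),
            }))
        if measurements:
            repeats["6.3"] = measurements

        relatives = []
        for k in range(self.repeats("6.4")):
            rel_birth = _date(rng, date(1930, 1, 1), birth)
            deceased = self.pick("6.4.10")
            values = {
                "6.4.1": f"{pseudonym}-REL{k}",
                "6.4.2": self.pick("6.4.2"),
                "6.4.3": self.pick("6.4.3"),
                "6.4.4": self.pick("6.4.4"),
                "6.4.5": self.pick("6.4.5"),
                "6.4.6": self.pick("6.4.6"),
                "6.4.7": self.pick("6.4.7"),
                "6.4.8": rng.randint(20, 90),
                "6.4.9": _iso(rel_birth),
                "6.4.10": deceased,
            }
            if deceased.display == "Yes":
                values["6.4.11"] = _binding(CodeSystem.ICD10, rng.choice(_ICD10_POOL))
                values["6.4.12"] = rng.randint(30, 95)
            if disease_codes:
                values["6.4.13"] = rng.choice(disease_codes)
            relatives.append(SectionInstance(section_id="6.4", values=values))
        if relatives:
            repeats["6.4"] = relatives

        singletons["7"] = SectionInstance(section_id="7", values={
            "7.1": self.pick("7.1"),
            "7.2": _iso(_date(rng, birth, admission)),
            "7.3": "synthetic registry consent policy v1",
            "7.4": self.pick("7.4"),
            "7.5": self.pick("7.5"),
            "7.6": self.pick("7.6"),
            "7.7": f"https://biobank.example.org/sample/{pseudonym}",
        })

        if not self.omitted("8"):
            singletons["8"] = SectionInstance(section_id="8", values={
                "8.1": _binding(CodeSystem.ICF, rng.choice(_ICF_POOL)),
            })

        return PatientRecord(singletons=singletons, repeats=repeats)


def generate(config: CohortConfig, registry: ModelRegistry) -> list[PatientRecord]:
    """Generate ``config.n`` validation-clean records, deterministically."""
    records = []
    for index in range(config.n):
        rng = random.Random(f"{config.seed}:{index}")
        records.append(_RecordBuilder(registry, config, rng, index).build())
    return records


def coverage_audit(
    cohort: list[PatientRecord], registry: ModelRegistry
) -> dict[str, int]:
    """How often each of the 78 elements is populated across the cohort."""
    counts = {el.element_id: 0 for el in registry.iter_elements()}
    for record in cohort:
        for el in registry.iter_elements():
            for inst in record.instances(el.section_id):
                if inst.get(el.element_id) is not None:
                    counts[el.element_id] += 1
    return counts


def unknown_fraction(
    cohort: list[PatientRecord], registry: ModelRegistry
) -> Optional[float]:
    """Realised fraction of "Unknown" picks among unknown-capable fields."""
    capable = {
        el.element_id
        for el in registry.iter_elements()
        if el.value_set_id
        and any(
            _is_unknown(c.display)
            for c in registry.value_set(el.value_set_id).choices
        )
    }
    total = 0
    unknown = 0
    for record in cohort:
        for eid in capable:
            for value in record.all_values(eid):
                codes = value if isinstance(value, list) else [value]
                for code in codes:
                    total += 1
                    if _is_unknown(code.display):
                        unknown += 1
    if total == 0:
        return None
    return unknown / total
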