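"""Record validation: cardinality, typing, value sets, formats, dependencies.

Rule catalogue (stable rule_ids):

========================== ======== =====================================================
rule_id                    severity checks
========================== ======== =====================================================
cardinality                ERROR    section instance counts against the active profile
type                       ERROR    value matches the element's declared data type
value_set_membership       ERROR    closed CODE values are members of the bound value set
date_format                ERROR    DATE values are ISO-8601 calendar dates
gestation_format           ERROR    3.5 matches "XX+X" with weeks 0-45 and days 0-6
decimal_format             ERROR    6.3.2 measurement value parses as a decimal number
encounter_period           ERROR    encounter start (4.1) <= end (4.2)
temporal_order             WARNING  birth <= admission, birth <= death, onset <= diagnosis
dependency_cause_of_death  ERROR    cause of death (3.3) requires vital status = Dead
dependency_family_deceased ERROR    6.4.11/6.4.12 require family-member deceased = yes
linkage_family_diagnosis   ERROR    6.4.13 code appears in some 5.1 or 6.1.1 entry
========================== ======== =====================================================

"Unknown" is a first-class value-set choice and counts as present. Temporal
ordering is WARNING-level except encounter start/end (the only ordering the
model itself defines); gestation bounds (0-45 weeks) are configurable via
module constants.
"""

from __future__ import annotations

import enum
import re
from datetime import date
from typing import Optional

from pydantic import BaseModel

from .model import CodeBinding, DataElement, DataType, Cardinality, ModelRegistry
from .records import CardinalityProfile, ISO_DATE_RE, PatientRecord

GESTATION_RE = re.compile(r"^(\d{1,2})\+(\d)$")
GESTATION_MAX_WEEKS = 45
DECIMAL_RE = re.compile(r"^-?\d+(\.\d+)?$")

#: reference codes used by dependency rules
_DEAD_CODE = "419099009"
_YES_CODE = "373066001"


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


class ValidationIssue(BaseModel):
    target: str  # element_id or section_id
    severity: Severity
    rule_id: str
    message: str
    instance_index: Optional[int] = None

    def __str__(self) -> str:
        idx = f"[{self.instance_index}]" if self.instance_index is not None else ""
        return f"{self.severity.value} {self.rule_id} {self.target}{idx}: {self.message}"


def _err(target, rule, msg, idx=None) -> ValidationIssue:
    return ValidationIssue(
        target=target, severity=Severity.ERROR, rule_id=rule, message=msg,
        instance_index=idx,
    )


def _warn(target, rule, msg, idx=None) -> ValidationIssue:
    return ValidationIssue(
        target=target, severity=Severity.WARNING, rule_id=rule, message=msg,
        instance_index=idx,
    )


# ---------------------------------------------------------------------------
# HGVS plausibility (syntactic shape only; full grammar is out of scope)
# ---------------------------------------------------------------------------


class HgvsLevel(str, enum.Enum):
    G = "G"
    C = "C"
    P = "P"
    FREE = "FREE"


class HgvsResult(str, enum.Enum):
    PASS = "PASS"
    WARN = "WARN"


_HGVS_RE = re.compile(
    r"^[A-Za-z][A-Za-z0-9_.]*:(?P<prefix>[gcp])\.[A-Za-z0-9_>*+?()=\[\]-]+$"
)


def hgvs_plausibility(expr: str, level: HgvsLevel) -> HgvsResult:
    """Syntactic reference:prefix.description shape check.

    The free-text level (element 6.1.6) always passes: the model
    deliberately allows initial recording with subsequent validation.
    """
    if not expr:
        raise ValueError("expr must be non-empty")
    if level == HgvsLevel.FREE:
        return HgvsResult.PASS
    m = _HGVS_RE.match(expr)
    if m is None:
        return HgvsResult.WARN
    if m.group("prefix") != level.value.lower():
        return HgvsResult.WARN
    return HgvsResult.PASS


# ---------------------------------------------------------------------------
# validate_record
# ---------------------------------------------------------------------------


def _is_code(v) -> bool:
    return isinstance(v, CodeBinding)


def _codes_of(value) -> list[CodeBinding]:
    if isinstance(value, CodeBinding):
        return [value]
    if isinstance(value, list):
        return [v for v in value if isinstance(v, CodeBinding)]
    return []


def _type_ok(value, data_type: DataType) -> bool:
    if data_type == DataType.CODE:
        return _is_code(value) or (
            isinstance(value, list) and value and all(_is_code(v) for v in value)
        )
    if data_type in (DataType.DATE, DataType.STRING):
        return isinstance(value, str)
    if data_type == DataType.INTEGER:
        return isinstance(value, int) and not isinstance(value, bool)
    if data_type == DataType.BOOLEAN:
        return isinstance(value, bool)
    return False


def _parse_date(value) -> Optional[date]:
    if isinstance(value, str) and ISO_DATE_RE.match(value):
        try:
            return date.fromisoformat(value)
        except ValueError:
            return None
    return None


def _check_element_value(
    el: DataElement, value, registry: ModelRegistry, idx, issues
) -> None:
    eid = el.element_id
    if not _type_ok(value, el.data_type):
        issues.append(
            _err(eid, "type",
                 f"expected {el.data_type.value}, got {type(value).__name__}", idx)
        )
        return
    if el.data_type == DataType.DATE:
        if _parse_date(value) is None:
            issues.append(
                _err(eid, "date_format", f"not an ISO-8601 calendar date: {value!r}", idx)
            )
    if eid == "3.5":
        m = GESTATION_RE.match(value)
        if (
            not m
            or not 0 <= int(m.group(1)) <= GESTATION_MAX_WEEKS
            or not 0 <= int(m.group(2)) <= 6
        ):
            issues.append(
                _err(eid, "gestation_format",
                     f"gestation must be 'weeks+days' with weeks 0-{GESTATION_MAX_WEEKS} "
                     f"and days 0-6, got {value!r}", idx)
            )
    if eid == "6.3.2" and not DECIMAL_RE.match(value):
        issues.append(
            _err(eid, "decimal_format", f"not a decimal number: {value!r}", idx)
        )
    if el.data_type == DataType.CODE and el.value_set_id:
        vs = registry.value_set(el.value_set_id)
        members = {(c.binding.system, c.binding.code) for c in vs.choices}
        for code in _codes_of(value):
            if (code.system, code.code) not in members:
                issues.append(
                    _err(eid, "value_set_membership",
                         f"code {code.system.value}:{code.code} not in value set "
                         f"{vs.id} ({vs.name})", idx)
                )


def _display_or_code(value) -> tuple[str, str]:
    codes = _codes_of(value)
    if codes:
        return codes[0].code, codes[0].display
    return "", ""


def validate_record(
    record: PatientRecord,
    registry: ModelRegistry,
    profile: Optional[CardinalityProfile] = None,
) -> list[ValidationIssue]:
    """Validate a record; all semantic problems are returned, never raised."""
    if profile is None:
        profile = CardinalityProfile.default()
    issues: list[ValidationIssue] = []

    # (a) cardinalities
    for sid, card in profile.cardinalities.items():
        n = len(record.instances(sid))
        if card == Cardinality.ONE_ONE and n != 1:
            issues.append(
                _err(sid, "cardinality",
                     f"section {sid} requires exactly one instance, found {n}")
            )
        elif card == Cardinality.ZERO_ONE and n > 1:
            issues.append(
                _err(sid, "cardinality",
                     f"section {sid} allows at most one instance, found {n}")
            )

    # (b)-(d) per-value checks
    for sid in profile.cardinalities:
        for idx, inst in enumerate(record.instances(sid)):
            for eid, value in inst.values.items():
                try:
                    el = registry.element(eid)
                except KeyError:
                    issues.append(_err(eid, "type", "unknown element id", idx))
                    continue
                _check_element_value(el, value, registry, idx, issues)

    # (e) temporal ordering
    birth = _parse_date(record.first("2.1"))
    admission = _parse_date(record.first("1.2"))
    death = _parse_date(record.first("3.2"))
    if birth and admission and birth > admission:
        issues.append(
            _warn("1.2", "temporal_order",
                  f"date of birth {birth} after admission {admission}")
        )
    if birth and death and birth > death:
        issues.append(
            _warn("3.2", "temporal_order",
                  f"date of birth {birth} after time of death {death}")
        )
    for idx, inst in enumerate(record.instances("5")):
        onset = _parse_date(inst.get("5.4"))
        diagnosis = _parse_date(inst.get("5.6"))
        if onset and diagnosis and onset > diagnosis:
            issues.append(
                _warn("5.6", "temporal_order",
                      f"onset {onset} after diagnosis {diagnosis}", idx)
            )
    for idx, inst in enumerate(record.instances("4")):
        start = _parse_date(inst.get("4.1"))
        end = _parse_date(inst.get("4.2"))
        if start and end and start > end:
            issues.append(
                _err("4.2", "encounter_period",
                     f"encounter start {start} after end {end}", idx)
            )

    # (f) dependencies
    if record.first("3.3") is not None:
        vital = record.first("3.1")
        code, display = _display_or_code(vital) if vital is not None else ("", "")
        if code != _DEAD_CODE and display != "Dead":
            issues.append(
                _err("3.3", "dependency_cause_of_death",
                     "cause of death requires vital status (3.1) = Dead")
            )
    for idx, inst in enumerate(record.instances("6.4")):
        if inst.get("6.4.11") is not None or inst.get("6.4.12") is not None:
            deceased = inst.get("6.4.10")
            code, display = (
                _display_or_code(deceased) if deceased is not None else ("", "")
            )
            if code != _YES_CODE and display != "Yes":
                issues.append(
                    _err("6.4.10", "dependency_family_deceased",
                         "deceased age/cause of death require "
                         "family-member deceased (6.4.10) = yes", idx)
                )

    # (g) linkage 6.4.13 -> 5.1 / 6.1.1
    known: set[tuple] = set()
    for value in record.all_values("5.1") + record.all_values("6.1.1"):
        known.update((c.system, c.code) for c in _codes_of(value))
    for idx, inst in enumerate(record.instances("6.4")):
        diag = inst.get("6.4.13")
        if diag is None:
            continue
        for code in _codes_of(diag):
            if (code.system, code.code) not in known:
                issues.append(
                    _err("6.4.13", "linkage_family_diagnosis",
                         f"family-member diagnosis {code.system.value}:{code.code} "
                         "matches no 5.1 or 6.1.1 entry", idx)
                )
    return issues


def has_errors(issues: list[ValidationIssue]) -> bool:
    return any(i.severity == Severity.ERROR for i in issues)


class RecordInvalidError(ValueError):
    """Raised by exporters when a record fails its validation precondition."""

    def __init__(self, issues: list[ValidationIssue]):
        self.issues = issues
        super().__init__(
            "record fails validation: " + "; ".join(str(i) for i in issues)
        )


def require_valid(record: PatientRecord, registry: ModelRegistry) -> None:
    errors = [
        i for i in validate_record(record, registry)
        if i.severity == Severity.ERROR
    ]
    if errors:
        raise RecordInvalidError(errors)
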