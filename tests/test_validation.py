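"""Validation rule catalogue, HGVS plausibility, issue monotonicity."""

import copy
import json

import pytest

from rdcdm import (
    CardinalityProfile,
    HgvsLevel,
    HgvsResult,
    Severity,
    hgvs_plausibility,
    read_record,
    validate_record,
    write_record,
)
from rdcdm.model import Cardinality, SECTION_IDS
from rdcdm.validation import has_errors


def _rules(issues):
    return {(i.rule_id, i.severity) for i in issues}


def _all_optional():
    return CardinalityProfile(
        name="all-optional",
        cardinalities={sid: Cardinality.ZERO_MANY for sid in SECTION_IDS},
    )


def _valid_base(registry):
    return read_record({
        "1": {"1.1": "P-1", "1.2": "2021-03-02"},
        "2": {"2.1": "1990-05-01"},
        "3": {"3.5": "32+4"},
        "7": {"7.2": "2020-01-01"},
    }, registry)


def test_clean_record_has_no_issues(registry):
    assert validate_record(_valid_base(registry), registry) == []


def test_generated_cohort_is_validation_clean(registry, cohort):
    for record in cohort:
        assert validate_record(record, registry) == []


def test_missing_section_one_is_cardinality_error(registry):
    record = read_record({"7": {"7.2": "2020-01-01"}}, registry)
    issues = validate_record(record, registry)
    assert ("cardinality", Severity.ERROR) in _rules(issues)
    # with an all-optional profile the same record is clean
    assert validate_record(record, registry, _all_optional()) == []


def test_strict_profile_requires_sections_2_and_3(registry):
    record = read_record(
        {"1": {"1.1": "P-1"}, "7": {"7.2": "2020-01-01"}}, registry
    )
    assert validate_record(record, registry) == []
    strict = validate_record(record, registry, CardinalityProfile.strict())
    assert {i.target for i in strict if i.rule_id == "cardinality"} == {"2", "3"}


def test_gestation_format(registry):
    record = _valid_base(registry)
    assert validate_record(record, registry) == []
    record.singletons["3"].values["3.5"] = "32+9"
    issues = validate_record(record, registry)
    assert ("gestation_format", Severity.ERROR) in _rules(issues)
    record.singletons["3"].values["3.5"] = "52+1"
    assert ("gestation_format", Severity.ERROR) in _rules(
        validate_record(record, registry)
    )


def test_value_set_membership(registry):
    doc = {
        "1": {"1.1": "P-1"},
        "7": {"7.2": "2020-01-01"},
        "6.2": [{"6.2.2": {"system": "SNOMED_CT", "code": "999999",
                           "display": "Bogus"}}],
    }
    issues = validate_record(read_record(doc, registry), registry)
    membership = [i for i in issues if i.rule_id == "value_set_membership"]
    assert len(membership) == 1
    assert membership[0].target == "6.2.2"
    assert membership[0].instance_index == 0


def test_date_and_decimal_formats(registry):
    doc = {
        "1": {"1.1": "P-1", "1.2": "2021-02-30"},
        "7": {"7.2": "2020-01-01"},
        "6.3": [{"6.3.2": "12,5"}],
    }
    rules = _rules(validate_record(read_record(doc, registry), registry))
    assert ("date_format", Severity.ERROR) in rules
    assert ("decimal_format", Severity.ERROR) in rules


def test_encounter_period_error_and_temporal_warnings(registry):
    doc = {
        "1": {"1.1": "P-1", "1.2": "2000-01-01"},
        "2": {"2.1": "2005-06-01"},  # birth after admission -> warning
        "7": {"7.2": "2020-01-01"},
        "4": [{"4.1": "2020-05-01", "4.2": "2020-04-01"}],
        "5": [{"5.4": "2020-03-01", "5.6": "2020-02-01"}],
    }
    issues = validate_record(read_record(doc, registry), registry)
    rules = _rules(issues)
    assert ("encounter_period", Severity.ERROR) in rules
    assert ("temporal_order", Severity.WARNING) in rules
    warnings = [i for i in issues if i.rule_id == "temporal_order"]
    assert {i.target for i in warnings} == {"1.2", "5.6"}


def test_cause_of_death_requires_dead_status(registry):
    doc = {
        "1": {"1.1": "P-1"},
        "7": {"7.2": "2020-01-01"},
        "3": {
            "3.1": {"system": "SNOMED_CT", "code": "438949009",
                    "display": "Alive"},
            "3.3": {"system": "ICD10", "code": "x-cause", "display": "Toy"},
        },
    }
    issues = validate_record(read_record(doc, registry), registry)
    assert ("dependency_cause_of_death", Severity.ERROR) in _rules(issues)
    doc["3"]["3.1"] = {"system": "SNOMED_CT", "code": "419099009",
                       "display": "Dead"}
    issues = validate_record(read_record(doc, registry), registry)
    assert "dependency_cause_of_death" not in {i.rule_id for i in issues}


def test_family_deceased_dependency_and_linkage(registry):
    doc = {
        "1": {"1.1": "P-1"},
        "7": {"7.2": "2020-01-01"},
        "6.4": [{
            "6.4.10": {"system": "SNOMED_CT", "code": "373067005",
                       "display": "No"},
            "6.4.12": 70,
            "6.4.13": {"system": "ORDO", "code": "x-1", "display": "Toy"},
        }],
    }
    rules = _rules(validate_record(read_record(doc, registry), registry))
    assert ("dependency_family_deceased", Severity.ERROR) in rules
    assert ("linkage_family_diagnosis", Severity.ERROR) in rules
    # adding the matching 5.1 entry resolves the linkage error
    doc["5"] = [{"5.1": {"system": "ORDO", "code": "x-1", "display": "Toy"}}]
    rules = _rules(validate_record(read_record(doc, registry), registry))
    assert ("linkage_family_diagnosis", Severity.ERROR) not in rules


def test_issue_monotonicity_under_corruption(registry, cohort):
    """Corrupting one field of a clean record never reduces the issue count."""
    record = cohort[0]
    base = len(validate_record(record, registry))
    doc = json.loads(write_record(record))
    corruptions = [
        ("3", "3.5", "99+9"),
        ("1", "1.2", "not-a-date"),
    ]
    for sid, eid, bad in corruptions:
        broken = copy.deepcopy(doc)
        if sid in broken:
            broken[sid][eid] = bad
            issues = validate_record(read_record(broken, registry), registry)
            assert len(issues) > base
            assert has_errors(issues)


@pytest.mark.parametrize("expr,level,expected", [
    ("NC_000017.11:g.50198002C>T", HgvsLevel.G, HgvsResult.PASS),
    ("NM_000000.0:c.100A>G", HgvsLevel.C, HgvsResult.PASS),
    ("NP_000000.0:p.Arg97Ser", HgvsLevel.P, HgvsResult.PASS),
    ("NM_000000.0:g.100A>G", HgvsLevel.C, HgvsResult.WARN),
    ("totally free text", HgvsLevel.FREE, HgvsResult.PASS),
    ("no separator", HgvsLevel.G, HgvsResult.WARN),
])
def test_hgvs_plausibility(expr, level, expected):
    assert hgvs_plausibility(expr, level) == expected


def test_hgvs_rejects_empty_expression():
    with pytest.raises(ValueError):
        hgvs_plausibility("", HgvsLevel.G)


def test_hgvs_is_not_part_of_validate_record(registry):
    """A malformed HGVS string is WARN-able standalone but validate_record
    stays silent: the record-level contract covers the rule catalogue only."""
    doc = {
        "1": {"1.1": "P-1"},
        "7": {"7.2": "2020-01-01"},
        "6.1": [{"6.1.7": "not hgvs at all"}],
    }
    record = read_record(doc, registry)
    assert validate_record(record, registry) == []
    assert hgvs_plausibility("not hgvs at all", HgvsLevel.G) == HgvsResult.WARN
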