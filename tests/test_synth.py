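"""Synthetic cohort generation: determinism, soundness, coverage, knobs."""

import pytest

from rdcdm import CohortConfig, coverage_audit, generate, validate_record, write_record
from rdcdm.synth import unknown_fraction


def test_determinism(registry):
    a = generate(CohortConfig(n=5, seed=42), registry)
    b = generate(CohortConfig(n=5, seed=42), registry)
    assert [write_record(r) for r in a] == [write_record(r) for r in b]


def test_per_record_streams_are_size_independent(registry):
    small = generate(CohortConfig(n=3, seed=42), registry)
    large = generate(CohortConfig(n=8, seed=42), registry)
    assert [write_record(r) for r in small] == [
        write_record(r) for r in large[:3]
    ]


def test_different_seeds_differ(registry):
    a = generate(CohortConfig(n=3, seed=1), registry)
    b = generate(CohortConfig(n=3, seed=2), registry)
    assert [write_record(r) for r in a] != [write_record(r) for r in b]


def test_records_are_validation_clean_including_warnings(registry):
    for record in generate(CohortConfig(n=10, seed=42), registry):
        assert validate_record(record, registry) == []


def test_full_element_coverage(registry):
    cohort = generate(CohortConfig(n=100, seed=7), registry)
    counts = coverage_audit(cohort, registry)
    assert len(counts) == 78
    missing = [eid for eid, n in counts.items() if n == 0]
    assert missing == []


def test_missingness_knob(registry):
    cohort = generate(
        CohortConfig(n=20, seed=3, missingness={"8": 1.0}), registry
    )
    counts = coverage_audit(cohort, registry)
    assert counts["8.1"] == 0


def test_unknown_rate_band(registry):
    cohort = generate(CohortConfig(n=200, seed=1, unknown_rate=0.3), registry)
    realised = unknown_fraction(cohort, registry)
    assert abs(realised - 0.3) < 0.08


def test_unknown_rate_zero(registry):
    cohort = generate(CohortConfig(n=50, seed=1, unknown_rate=0.0), registry)
    assert unknown_fraction(cohort, registry) == 0.0


def test_empty_cohort(registry):
    cohort = generate(CohortConfig(n=0, seed=0), registry)
    assert cohort == []
    assert unknown_fraction(cohort, registry) is None


def test_pseudonyms_are_unique(registry, cohort):
    pseudonyms = [r.pseudonym() for r in cohort]
    assert len(set(pseudonyms)) == len(cohort)


def test_config_rejects_bad_parameters():
    with pytest.raises(ValueError):
        CohortConfig(unknown_rate=1.5)
    with pytest.raises(ValueError):
        CohortConfig(missingness={"8": 2.0})
    with pytest.raises(ValueError):
        CohortConfig(repeat_range={"5": (3, 1)})
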