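import pytest

from rdcdm import CohortConfig, builtin_registry, generate


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture(scope="session")
def cohort(registry):
    """Small full-coverage cohort shared across test modules."""
    return generate(CohortConfig(n=25, seed=7), registry)
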