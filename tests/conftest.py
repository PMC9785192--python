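import pytest

from pbpkddi.compound import load_compound
from pbpkddi.engine import SolverSettings
from pbpkddi.physiology import REFERENCE_DEMOGRAPHICS, build_individual


@pytest.fixture(scope="session")
def reference_individual():
    return build_individual(REFERENCE_DEMOGRAPHICS)


@pytest.fixture(scope="session")
def ruxolitinib():
    return load_compound("ruxolitinib")


@pytest.fixture(scope="session")
def posaconazole():
    return load_compound("posaconazole")


@pytest.fixture(scope="session")
def midazolam():
    return load_compound("midazolam")


@pytest.fixture(scope="session")
def fast_settings():
    """Solver settings for routine tests (population-grade accuracy)."""
    return SolverSettings(rtol=1e-6, atol=1e-9)


@pytest.fixture(scope="session")
def tight_settings():
    """Solver settings for closed-form and limiting-case comparisons."""
    return SolverSettings(rtol=1e-9, atol=1e-12)
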