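import pytest
from hypothesis import HealthCheck, settings

from denovopep.graph_core import standard_residue_table
from denovopep.scoring import theoretical_spectrum

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table():
    """The 20 standard residues, no modifications."""
    return standard_residue_table()


@pytest.fixture(scope="session")
def mod_table():
    """Fixed carbamidomethyl-C, variable oxidized M (starred symbol)."""
    return standard_residue_table(("C+57.02146",), ("M+15.99491",))


@pytest.fixture
def ga_spectrum(table):
    """Noise-free b/y ladder of the dipeptide GA (the worked example)."""
    return theoretical_spectrum("GA", table)
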