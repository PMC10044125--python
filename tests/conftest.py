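import pytest
from hypothesis import HealthCheck, settings

from mitochar.reference import cydalima_annotation, cydalima_codon_counts
from mitochar.synthetic_data import generate_mitogenome, perspectalis_like_profile

settings.register_profile(
    "suite", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_annotation():
    """Published box-tree-moth annotation (KY865331)."""
    return cydalima_annotation()


@pytest.fixture(scope="session")
def ref_codon_counts():
    """Published per-codon counts of the 13 concatenated PCGs."""
    return cydalima_codon_counts()


@pytest.fixture(scope="session")
def synthetic_mitogenome():
    """One seeded synthetic mitogenome shared across tests:
    (genome, annotation, manifest)."""
    return generate_mitogenome(perspectalis_like_profile(seed=11))
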