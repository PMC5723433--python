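import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ca6_protein():
    from captx import synth
    return synth.synthetic_ca6_protein(seed=0)


@pytest.fixture(scope="session")
def ca6_alignment():
    from captx import synth
    return synth.synthetic_ca6_alignment(seed=0)


@pytest.fixture(scope="session")
def ca6_cds_pair():
    from captx import synth
    return synth.synthetic_ca6_cds_pair(seed=0)
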