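import pytest
from hypothesis import HealthCheck, settings

from chimeraseg.community import build_region_map, simulate_references
from chimeraseg.detector import ChimeraDetector

settings.register_profile(
    "fast",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


@pytest.fixture(scope="session")
def region_map():
    return build_region_map(total_length=1500, n_conserved=10, conserved_len=50)


@pytest.fixture(scope="session")
def community(region_map):
    return simulate_references(region_map=region_map, seed=11)


@pytest.fixture(scope="session")
def detector(community):
    return ChimeraDetector(community)
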