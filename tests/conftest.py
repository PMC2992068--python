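import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from tripwave import CombSpec, make_comb, single_track_indicators  # noqa: E402


@pytest.fixture(scope="session")
def comb_p3():
    return make_comb(CombSpec(period=3))


@pytest.fixture(scope="session")
def comb_p6():
    return make_comb(CombSpec(period=6))


@pytest.fixture(scope="session")
def comb_p9():
    return make_comb(CombSpec(period=9))


@pytest.fixture(scope="session")
def ind_p3(comb_p3):
    return single_track_indicators(comb_p3)


@pytest.fixture(scope="session")
def ind_p6(comb_p6):
    return single_track_indicators(comb_p6)


@pytest.fixture(scope="session")
def ind_p9(comb_p9):
    return single_track_indicators(comb_p9)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
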