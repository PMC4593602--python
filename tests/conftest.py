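import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prostab.fixtures import FixtureSpec, make_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix18():
    """18-residue ideal alpha-helical polyalanine."""
    return make_fixture(FixtureSpec(kind="ideal_helix", length=18))


@pytest.fixture(scope="session")
def strand12():
    return make_fixture(FixtureSpec(kind="extended_strand", length=12))


@pytest.fixture(scope="session")
def turn_fixture():
    return make_fixture(FixtureSpec(kind="beta_turn", turn_type="I"))


@pytest.fixture(scope="session")
def salt_bridge():
    """ASP/LYS pair with OD1-NZ at exactly 3.0 A."""
    return make_fixture(FixtureSpec(kind="residue_pair", pair_distance=3.0))


@pytest.fixture(scope="session")
def left_handed():
    return make_fixture(FixtureSpec(kind="left_handed_site", length=9))


@pytest.fixture(scope="session")
def metal_site():
    return make_fixture(FixtureSpec(kind="metal_site"))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
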