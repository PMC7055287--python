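import pytest
from hypothesis import settings

from ankfam import family_scan, simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def profile():
    return family_scan.default_profile()


@pytest.fixture(scope="session")
def family(profile):
    """Default family simulation used by several recovery tests."""
    return simulate.simulate_family(simulate.FamilySimSpec(seed=42), profile)
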