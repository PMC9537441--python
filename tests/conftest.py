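import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from capture_kit.cassette_design import (  # noqa: E402
    CassetteSpec,
    GuideSite,
    assemble_cassette,
)


@pytest.fixture(scope="session")
def spec() -> CassetteSpec:
    return CassetteSpec()


@pytest.fixture(scope="session")
def site_a() -> GuideSite:
    return GuideSite("a0", "ACGTACGTACGTACGTACGA", "top")


@pytest.fixture(scope="session")
def site_b() -> GuideSite:
    return GuideSite("b0", "TGCATGCATGCATGCATGCA", "bottom")


@pytest.fixture(scope="session")
def cassette(site_a, site_b, spec):
    return assemble_cassette(site_a, site_b, spec)
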