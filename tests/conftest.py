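import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohort():
    """The packaged 112-variant PCD cohort table."""
    from pcd_triage import load_packaged_cohort

    return load_packaged_cohort()
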