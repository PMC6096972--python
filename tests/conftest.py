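import pytest
from hypothesis import HealthCheck, settings

import phsorb

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def compound_records():
    """The bundled 19-compound property table."""
    return phsorb.read_compound_table()


@pytest.fixture(scope="session")
def compounds_by_name(compound_records):
    return {r.name: r for r in compound_records}
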