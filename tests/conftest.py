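import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default-condition synthetic scenario shared across tests."""
    from targetlink.synthetic import ScenarioConfig, generate_scenario

    out = tmp_path_factory.mktemp("scenario")
    return generate_scenario(ScenarioConfig(seed=11), out)
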