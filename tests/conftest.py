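from __future__ import annotations

import pytest
from hypothesis import settings

from dyadsense.synth import ScheduleConfig, simulate_week

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> ScheduleConfig:
    return ScheduleConfig(seed=7)


@pytest.fixture(scope="session")
def sim_week(default_config, tmp_path_factory):
    """One default simulated week written to an inbound folder."""
    folder = tmp_path_factory.mktemp("inbound")
    result = simulate_week(default_config, folder)
    return folder, result
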