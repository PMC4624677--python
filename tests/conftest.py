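import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zfscreen import synth

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena() -> synth.ArenaSpec:
    return synth.ArenaSpec()


@pytest.fixture(scope="session")
def short_ptz_params() -> synth.BehaviorParams:
    """The hyperactive preset cut to a 30-s session (cheap to render)."""
    return dataclasses.replace(
        synth.BEHAVIOR_PRESETS["ptz20"], session_duration=30.0
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
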