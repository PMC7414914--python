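from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig3_noisefree():
    from sabrefit import preset, simulate

    return simulate(replace(preset("fig3"), noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def fig6_noisefree():
    from sabrefit import preset, simulate

    return simulate(replace(preset("fig6"), noise_sd=0.0), seed=1)


@pytest.fixture(scope="session")
def fig8_noisefree():
    from sabrefit import preset, simulate

    return simulate(replace(preset("fig8"), noise_sd=0.0), seed=1)
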