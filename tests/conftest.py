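import dataclasses

import pytest

from fragquant.simulate import SimulationParams


@pytest.fixture
def tiny_params() -> SimulationParams:
    """Small, fast fragment: 80 um diameter, three timepoints."""
    return SimulationParams(
        fragment_diameter_um=80.0,
        time_points_h=(0.0, 12.0, 24.0),
        seed=11,
    )


def noise_free(params: SimulationParams, **overrides) -> SimulationParams:
    """Copy of params with all noise sources switched off."""
    return dataclasses.replace(
        params,
        background_level=0.0,
        background_sd=0.0,
        signal_dispersion=0.0,
        **overrides,
    )


@pytest.fixture
def tiny_noise_free(tiny_params) -> SimulationParams:
    return noise_free(tiny_params)
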