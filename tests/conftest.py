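import pytest
from hypothesis import settings

from ectsim.model import ModelParameters, SolverConfig, simulate
from ectsim.waveforms import PRESETS, get_preset

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def preset_trajectories(params):
    """Full 25-min simulations of every preset, computed once per session."""
    return {
        name: simulate(get_preset(name), params, t_end=25 * 60.0) for name in PRESETS
    }
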