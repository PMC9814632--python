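import numpy as np
import pytest

from turingforce.config import ProtocolStage, SimulationConfig
from turingforce.model import ModelParams
from turingforce import pde

#: reference parameter set used throughout (sigma, b, c of the study)
REF = dict(b=1.9, sigma=8.0, c=1.5)


@pytest.fixture(scope="session")
def settled_a24():
    """Unforced scaled-down run at a=24 settled into a stationary
    pattern; shared across tests that only read the result."""
    cfg = SimulationConfig(
        params=ModelParams(a=24.0, **REF),
        stages=(ProtocolStage(duration=200.0),),
        nx=100, ny=100, dx=0.25, dt=1e-3, noise_sd=0.01, seed=1,
        snapshot_interval=50.0,
    )
    return pde.run_protocol(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
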