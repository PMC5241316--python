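import numpy as np
import pytest

from hebbnet import Config, ConnectomeParams, ModelParams, build_architecture


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def tiny_connectome():
    """Two small areas with default connectivity rules (deterministic)."""
    cp = ConnectomeParams(grid=5, n_exc=3, n_inh=3, p0=0.5)
    return build_architecture(cp, rng=7, areas=["A1", "PB"], edges=[("A1", "PB")])


@pytest.fixture
def tiny_config():
    """A deliberately small end-to-end configuration for fast protocol tests."""
    cfg = Config()
    cfg.areas = ["A1", "PB", "M1_i", "V1", "M1_L"]
    cfg.edges = [("A1", "PB"), ("PB", "M1_i"), ("PB", "V1"), ("PB", "M1_L")]
    cfg.connectome.grid = 5
    cfg.connectome.n_exc = 3
    cfg.connectome.n_inh = 3
    cfg.protocol.n_words = 2
    cfg.protocol.cells_per_pattern = 3
    cfg.protocol.trials_per_pattern = 5
    cfg.protocol.baseline_steps = 60
    cfg.protocol.stim_steps = 40
    cfg.protocol.post_steps = 40
    cfg.protocol.test_trials_per_stimulus = 2
    cfg.validate()
    return cfg
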