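import numpy as np
import pytest

from retinaos import RetinaModelConfig, StimulusProtocol, generate_retina, synthesize_responses


@pytest.fixture(scope="session")
def proto():
    return StimulusProtocol()


@pytest.fixture(scope="session")
def small_retina():
    """A small mixed retina with responses, shared across tests."""
    cfg = RetinaModelConfig(
        n_fovs=4, cells_per_fov_mean=40, cells_per_fov_sd=5, seed=123
    )
    cells, fovs = generate_retina(cfg)
    responses = synthesize_responses(cells, cfg)
    return cfg, cells, fovs, responses


@pytest.fixture(scope="session")
def noiseless_os_retina():
    """Purely orientation-selective cells, no trace noise, no map noise."""
    cfg = RetinaModelConfig(
        n_fovs=4,
        cells_per_fov_mean=30,
        cells_per_fov_sd=0,
        frac_os=1.0,
        frac_ds=0.0,
        frac_both=0.0,
        underrep_frac=0.0,
        noise_sd=0.0,
        angular_noise_kappa=np.inf,
        seed=7,
    )
    cells, fovs = generate_retina(cfg)
    responses = synthesize_responses(cells, cfg)
    return cfg, cells, fovs, responses
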