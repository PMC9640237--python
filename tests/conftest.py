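import numpy as np
import pytest

from kymovoice import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Well-separated two-class voice-parameter table (50 per class)."""
    return synthetic.generate_dataset(
        50, cfg=synthetic.SimConfig(seed=5), n_cycles=40
    )


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Rendering configuration with every noise source disabled."""
    return synthetic.SimConfig(
        n_frames=100, fps=2000.0, blue_noise_sd=0.0, sensor_noise_sd=0.0, seed=3
    )


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_cfg):
    wf = synthetic.simulate_glottal_waveform(
        synthetic.VoiceParams(f0=200.0), noiseless_cfg
    )
    stack, drift = synthetic.render_frames(wf, noiseless_cfg)
    return stack, wf, drift
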