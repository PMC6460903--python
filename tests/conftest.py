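import numpy as np
import pytest

from hfokit.preprocess import apply_fir, design_fir
from hfokit.signal_model import Channel, Epoch, Recording
from hfokit.synthetic import SimConfig, generate_background

RATE = 2000.0


@pytest.fixture(scope="session")
def band_kernel():
    """80-250 Hz single-pass band-pass kernel at 2 kHz."""
    return design_fir(80.0, 250.0, RATE, 513)


@pytest.fixture(scope="session")
def background():
    """10 s pink-noise background, 1 channel, seed 0."""
    return generate_background(
        SimConfig(n_channels=1, duration_s=10.0, rate=RATE,
                  background_scale=10.0, seed=0)
    )


@pytest.fixture(scope="session")
def inband_sd(background, band_kernel):
    """SD of the band-passed background (calibration reference)."""
    return float(apply_fir(background, band_kernel).epochs[0].channels[0].samples.std())


@pytest.fixture()
def two_channel_recording():
    rng = np.random.default_rng(42)
    return Recording(
        [
            Epoch(
                [
                    Channel("A1", 256.0, 50.0 * rng.standard_normal(256)),
                    Channel("A2", 256.0, 50.0 * rng.standard_normal(256)),
                ]
            )
        ],
        subject_id="fixture",
    )
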