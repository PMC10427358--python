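import numpy as np
import pytest

from perfusense import simulate as sim
from perfusense.spectra import FMN_CHANNEL, NADH_CHANNEL, WavelengthGrid, Spectrum


@pytest.fixture
def grid():
    return sim.DEFAULT_GRID


@pytest.fixture
def no_noise():
    return sim.NoiseModel.none()


@pytest.fixture
def anchored():
    return sim.anchored_noise(0)


@pytest.fixture
def fmn_channel():
    return FMN_CHANNEL


@pytest.fixture
def nadh_channel():
    return NADH_CHANNEL


def make_spectrum(counts, grid=None, led_id="LED405", is_dark=False,
                  integration_time_s=1.0, timestamp_s=0.0, **kw):
    grid = grid or WavelengthGrid(300.0, 1.0, 501)
    counts = np.broadcast_to(np.asarray(counts, dtype=float), (grid.n_points,)).copy()
    return Spectrum(grid, counts, led_id, is_dark, integration_time_s,
                    timestamp_s, **kw)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
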