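import numpy as np
import pytest

import recamp
from recamp import RunConfig, windowed_spectrum
from recamp import synth


def peak_period(values, t_grid) -> int:
    """Period bin of the global spectrum maximum."""
    return int(np.asarray(t_grid)[int(np.argmax(values))])


@pytest.fixture(scope="session")
def sine20():
    """2 s of a 20-Hz unit sine at fs=1000 (period exactly 50 samples)."""
    return synth.make_wave(synth.WaveSpec("sine", 20.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def fig4_tfs():
    """Windowed spectrum of the waveform compound (600-ms windows, 50 %
    overlap, eps = 10 % window STD, auto embedding)."""
    sig = synth.fig4_compound()
    return windowed_spectrum(sig, RunConfig(en=10.0, window=600, overlap=0.5, db=False))


@pytest.fixture(scope="session")
def fig5_tfs():
    """Windowed spectrum of the five-step frequency staircase (1,000-sample
    windows, 50 % overlap, eps = 10 % window STD)."""
    sig = synth.fig5_steps()
    return windowed_spectrum(sig, RunConfig(en=10.0, window=1000, overlap=0.5, db=False))
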