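import numpy as np
import pytest

import oscivent as ov


@pytest.fixture(scope="session")
def tube():
    return ov.WaveTubeSpec()


@pytest.fixture(scope="session")
def forcing():
    return ov.make_forcing_signal(seed=1)


@pytest.fixture(scope="session")
def baseline_params():
    """Tabulated healthy baseline mechanics (PVV group, moderate PEEP)."""
    return ov.CPMParams(raw=9.2, iaw=0.01, g=80.2, h=252.0)


@pytest.fixture(scope="session")
def injured_params():
    """Tabulated post-injury mechanics (PVV group, moderate PEEP)."""
    return ov.CPMParams(raw=14.5, iaw=0.01, g=251.0, h=1105.0)


@pytest.fixture(scope="session")
def baseline_subject():
    return ov.default_baseline_subject()


def add_complex_noise(z, rel_sd, rng):
    """Additive complex Gaussian noise with SD rel_sd * |Z| per frequency."""
    from oscivent.signals_fot import ImpedanceSpectrum

    noise = rng.normal(0.0, 1.0, (2, len(z.freqs)))
    values = z.values + rel_sd * np.abs(z.values) * (
        noise[0] + 1j * noise[1]
    ) / np.sqrt(2.0)
    return ImpedanceSpectrum(freqs=z.freqs, values=values)
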