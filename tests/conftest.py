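import numpy as np
import pytest

from carotidflow import (
    BloodProperties,
    VelocityWaveform,
    VesselGeometry,
    canonical_waveform,
)


@pytest.fixture
def geometry():
    return VesselGeometry(6.3e-3)


@pytest.fixture
def blood():
    return BloodProperties(viscosity=3.5e-3)


@pytest.fixture
def pulse():
    """Default carotid-like cycle at 70 bpm."""
    return canonical_waveform(70.0, 128)


@pytest.fixture
def random_waveform():
    """Arbitrary positive band-limited 64-sample cycle."""
    rng = np.random.default_rng(42)
    s = np.arange(64) / 64
    v = np.full(64, 0.6)
    for n in range(1, 9):
        v += 0.4 / n * rng.uniform(-1, 1) * np.cos(2 * np.pi * n * s + rng.uniform(0, 2 * np.pi))
    return VelocityWaveform.from_samples(v, 0.8)
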