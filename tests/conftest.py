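import numpy as np
import pytest

from pvccs import CTVolume, make_ceora_spec, simulate_acquisition


def make_volume(intensities, spacing=(1.0, 1.0, 1.0)):
    return CTVolume(np.asarray(intensities, dtype=float), spacing)


@pytest.fixture(scope="session")
def ceora_noiseless():
    """One noiseless, unjittered replica acquisition (shared: simulation is slow)."""
    spec = make_ceora_spec("none", seed=7, noise_sigma_hu=0.0)
    volume, gt = simulate_acquisition(spec)
    return spec, volume, gt
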