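import numpy as np
import pytest

from t1relax import ImageVolume, PhantomSpec, SequenceParams, generate_phantom


@pytest.fixture(scope="session")
def params() -> SequenceParams:
    """The 3 T acquisition the method defaults to: TR 8 ms, flip 15 deg."""
    return SequenceParams(tr=8.0, te=3.6, flip_angle=15.0)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 noiseless phantom with two WM lesions, k_true = 100."""
    return generate_phantom(PhantomSpec(shape=(32, 32, 32), lesion_count=2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture()
def small_volume(small_phantom):
    return ImageVolume(small_phantom.signal)
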