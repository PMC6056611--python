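import numpy as np
import pytest

from neopli.montage import Montage, Recording


@pytest.fixture(scope="session")
def montage() -> Montage:
    return Montage()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_recording(rng, montage) -> Recording:
    """A short 21-channel white-noise recording at 500 Hz."""
    return Recording(
        data=rng.standard_normal((21, 10_000)) * 30.0,
        sampling_rate=500.0,
        montage=montage,
        subject_id="noise",
    )
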