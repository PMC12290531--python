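import numpy as np
import pytest
from hypothesis import settings

from oddtag.montage import standard_64_montage
from oddtag.preprocess import EEGRecording

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def montage64():
    """The bundled standard 10/10 64-channel montage (labels, positions)."""
    return standard_64_montage()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_montage():
    """Small deterministic montage on a line, distances trivially known."""
    labels = [f"E{i}" for i in range(8)]
    coords = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
    return labels, coords


@pytest.fixture()
def toy_recording(toy_montage, rng):
    labels, coords = toy_montage
    data = rng.standard_normal((8, 4000))
    return EEGRecording(
        data=data,
        rate=200.0,
        ch_names=labels,
        montage=coords,
        events=[(0, "trial"), (1000, "trial"), (2000, "trial")],
    )
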