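import numpy as np
import pytest

from neurofuse.containers import SignalBlock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_block():
    """10 Hz unit sine, 250 Hz, 10 s, single channel."""
    rate = 250.0
    t = np.arange(int(10 * rate)) / rate
    return SignalBlock("eeg", np.sin(2 * np.pi * 10.0 * t)[None, :], rate,
                       ["C3"])


def make_block(data, rate=250.0, modality="eeg", **kw):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = kw.pop("labels", [f"ch{i}" for i in range(data.shape[0])])
    return SignalBlock(modality, data, rate, labels, **kw)
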