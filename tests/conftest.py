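import numpy as np
import pytest

from assrshift.containers import EpochSet
from assrshift.montage import CHANNELS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(
    data=None, n_epochs=8, n_channels=4, n_samples=550, fs=500.0, t0=-0.4,
    state="task", group="NC", subject_id="S0", finalized=False, seed=0,
):
    if data is None:
        data = 1e-6 * np.random.default_rng(seed).standard_normal(
            (n_epochs, n_channels, n_samples)
        )
    n_channels = data.shape[1]
    names = CHANNELS[:n_channels] if n_channels <= len(CHANNELS) else tuple(
        f"CH{i}" for i in range(n_channels)
    )
    return EpochSet(
        data=data, fs=fs, t0=t0, channel_names=names, state=state,
        subject_id=subject_id, group=group, finalized=finalized,
    )


@pytest.fixture
def small_epochs():
    return make_epochs()
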