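import numpy as np
import pytest

from robot_erp import load_standard_montage
from robot_erp.montage_io import EpochSet, Montage


@pytest.fixture(scope="session")
def montage64() -> Montage:
    return load_standard_montage("study64")


@pytest.fixture(scope="session")
def ring16() -> np.ndarray:
    """Ring adjacency over 16 channels (for small cluster fixtures)."""
    adj = np.zeros((16, 16), dtype=bool)
    for i in range(16):
        adj[i, (i + 1) % 16] = adj[(i + 1) % 16, i] = True
    return adj


def make_epochs(n_epochs=40, n_channels=8, n_times=50, srate=100.0,
                tmin=-0.2, seed=0, effect=0.0, effect_channel=0,
                effect_window=(0.2, 0.4)) -> EpochSet:
    """Small random epoch set with an optional condition effect injected on
    one channel inside a time window."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_epochs, n_channels, n_times))
    labels = np.array(["optimal", "suboptimal"] * (n_epochs // 2))
    times = tmin + np.arange(n_times) / srate
    if effect:
        win = (times >= effect_window[0]) & (times < effect_window[1])
        data[np.ix_(labels == "suboptimal", [effect_channel], win)] += effect
    return EpochSet(data=data, srate=srate, tmin=tmin, labels=labels,
                    subject="synthetic", unit="csd")
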