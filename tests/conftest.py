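import numpy as np
import pytest

from inhibisense import annet, io, simulate
from inhibisense.registry import BACTERIA, POLLUTANTS


@pytest.fixture(scope="session")
def codebook():
    return annet.Codebook()


@pytest.fixture(scope="session")
def table1():
    return io.load_table1()


@pytest.fixture(scope="session")
def anchor36(codebook):
    """Noise-free dataset of the 36 anchored (pollutant, level) classes."""
    X, T, classes = [], [], []
    for p in POLLUTANTS:
        for lv in (1.0, 10.0, 100.0):
            X.append([simulate.response_surface(b, p, lv) for b in BACTERIA])
            T.append(codebook.bits(codebook.encode_class(p, lv)))
            classes.append((p, lv))
    return np.array(X), np.array(T), classes


@pytest.fixture(scope="session")
def anchor_net(anchor36):
    """Desk-scale network trained on the noise-free anchored classes."""
    X, T, _ = anchor36
    return annet.train_lm((X, T), annet.NetworkConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_run():
    """The end-to-end recovery experiment: train seed 42, test seed 43."""
    train = simulate.generate_dataset(n_per_class=20, noise_cv=0.10, seed=42)
    test = simulate.generate_dataset(n_per_class=20, noise_cv=0.10, seed=43)
    net = annet.train_lm(train, annet.NetworkConfig())
    return net, train, test
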