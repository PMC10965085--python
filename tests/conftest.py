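import numpy as np
import pytest

from semdrift import (LatentCorpusParams, SGNSConfig, TrainingPairs,
                      generate_latent_corpus, generate_random_walk)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_walk():
    """iid random-walk ensemble, (T=30, N=200, D=5)."""
    return generate_random_walk(n_traj=200, n_times=30, dims=5, rng=99)


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 60-word, 4-window latent corpus plus its vocabulary and truth."""
    params = LatentCorpusParams(
        n_words=60, latent_dim=8, n_windows=4, drift_process="random_walk",
        drift_scale=0.3, pairs_per_window=6000, seed=17)
    return generate_latent_corpus(params)


@pytest.fixture(scope="session")
def tiny_sgns_config():
    return SGNSConfig(dim=8, epochs=2)


@pytest.fixture(scope="session")
def tiny_pairs(tiny_corpus):
    windows, vocab, _ = tiny_corpus
    return TrainingPairs.from_window(windows[0], vocab)
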