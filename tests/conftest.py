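import numpy as np
import pytest

import skimnet as sk


@pytest.fixture(scope="session")
def toy_task():
    """A small pattern-in-noise detection task (5 channels, 10k steps).

    Scaled-down version of the standard benchmark sequence, big enough to
    train a working detector in well under a second.
    """
    pattern = sk.make_pattern(L=5, n_spikes=9, duration=200, seed=7)
    train_seq = sk.embed_pattern(pattern, K=10_000, presentation_rate=580e-5,
                                 noise_ratio=1.0, seed=8)
    test_seq = sk.embed_pattern(pattern, K=10_000, presentation_rate=580e-5,
                                noise_ratio=1.0, seed=9)
    return pattern, train_seq, test_seq


@pytest.fixture(scope="session")
def trained(toy_task):
    """A fitted 40-dendrite detector on the toy task, with its internals."""
    _, train_seq, _ = toy_task
    model, A, target = sk.train(
        train_seq.raster, train_seq.presentation_end_times, M=40, seed=11,
        return_internals=True,
    )
    return model, A, target


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
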