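import numpy as np
import pytest

from bwcrn.hmm import HMMParams, ObservedSequence


@pytest.fixture
def toy2():
    """Two states, deterministic emissions: state k emits symbol k."""
    return HMMParams([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[1.0, 0.0], [0.0, 1.0]])


@pytest.fixture
def toy3():
    """Two states, noisy emissions biased 3:1 toward the matching symbol."""
    return HMMParams([0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]], [[0.75, 0.25], [0.25, 0.75]])


@pytest.fixture
def seq_ab():
    return ObservedSequence.from_tokens(["a", "b"], ["a", "b"])


def random_instance(rng, n_hidden=None, n_symbols=None, L=None):
    """Strictly positive random parameters plus a sampled sequence covering
    the alphabet (resampled until coverage, so Theta-preservation holds)."""
    from bwcrn.hmm import sample_sequence

    n_hidden = n_hidden or int(rng.integers(2, 4))
    n_symbols = n_symbols or int(rng.integers(2, 4))
    L = L or int(rng.integers(3, 11))
    params = HMMParams.random(n_hidden, n_symbols, rng)
    for attempt in range(200):
        seq, hidden = sample_sequence(params, L, int(rng.integers(0, 2**31)))
        if len(set(seq.symbols.tolist())) == n_symbols:
            return params, seq, hidden
    raise RuntimeError("could not cover the alphabet")


@pytest.fixture
def rng():
    return np.random.default_rng(20230621)
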