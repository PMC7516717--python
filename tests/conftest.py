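import numpy as np
import pytest

import quoterflow as qf


@pytest.fixture(scope="session")
def vocab_small():
    return qf.zipf_vocabulary(10, 1.0)


@pytest.fixture(scope="session")
def vocab_paper():
    """Vocabulary at the study conditions: z=1000 words, Zipf exponent 1.5."""
    return qf.zipf_vocabulary(1000, 1.5)


@pytest.fixture(scope="session")
def small_corpus(vocab_paper):
    """One quoter run on a small random graph, shared across read-only tests."""
    g = qf.generate_er(30, 6, seed=11)
    cfg = qf.QuoterConfig(q=0.5, vocab=vocab_paper, steps_per_node=300, seed=12)
    return g, qf.simulate_quoter(g, cfg)


def random_stream_pair(rng, z=8, max_len=60):
    """Random timestamped stream pair for oracle comparisons."""
    la = int(rng.integers(1, max_len))
    lb = int(rng.integers(2, max_len))
    a_words = rng.integers(1, z + 1, size=la)
    b_words = rng.integers(1, z + 1, size=lb)
    a_times = np.sort(rng.integers(0, 3 * max_len, size=la))
    b_times = np.sort(rng.integers(0, 3 * max_len, size=lb))
    return (qf.TextStream(words=a_words, times=a_times),
            qf.TextStream(words=b_words, times=b_times))
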