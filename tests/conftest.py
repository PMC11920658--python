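import itertools

import numpy as np
import pytest

from plurivote.model import LABELS, ResponsePool, SentimentLabel


def make_pool(message_id="msg", **counts):
    """Pool from label-name counts, e.g. make_pool(ANTI=13, PRO=7)."""
    labels = []
    for name, k in counts.items():
        labels.extend([SentimentLabel(name)] * k)
    return ResponsePool(message_id, tuple(labels))


def brute_force_distribution(pool: ResponsePool, m: int) -> np.ndarray:
    """Independent oracle: enumerate every label sequence of length m.

    Each sequence gets probability prod(counts[l]/N); its mass goes to the
    plurality label, with ties split proportionally to pool counts.
    """
    pool_counts = pool.count_vector()
    probs = pool_counts / pool.n
    out = np.zeros(len(LABELS))
    for seq in itertools.product(range(len(LABELS)), repeat=m):
        p = 1.0
        for i in seq:
            p *= probs[i]
        if p == 0.0:
            continue
        counts = np.bincount(seq, minlength=len(LABELS))
        top = counts.max()
        tied = np.flatnonzero(counts == top)
        if tied.size == 1:
            out[tied[0]] += p
        else:
            w = pool_counts[tied].astype(float)
            out[tied] += p * w / w.sum()
    return out


def random_pool(rng: np.random.Generator, n_max: int = 20) -> ResponsePool:
    n = int(rng.integers(2, n_max + 1))
    k = int(rng.integers(1, len(LABELS) + 1))
    chosen = rng.choice(len(LABELS), size=k, replace=False)
    labels = [LABELS[i] for i in rng.choice(chosen, size=n)]
    return ResponsePool(f"rand-{rng.integers(1 << 30)}", tuple(labels))


@pytest.fixture
def pool_13_7():
    return make_pool("p13-7", ANTI=13, PRO=7)


@pytest.fixture
def pool_10_10():
    return make_pool("p10-10", ANTI=10, PRO=10)
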