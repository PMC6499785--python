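import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from senet.network import MultilevelNetwork

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=30)
settings.load_profile("ci")


def make_actors(n, rng=None, sites=("a", "b"), gears=("trap", "net")):
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "id": [f"f{i}" for i in range(n)],
        "gear": rng.choice(gears, n),
        "landing_site": rng.choice(sites, n),
        "leader": rng.random(n) < 0.2,
        "community": "c1",
    })


def make_network(A, X=None, B=None):
    """Wrap adjacency arrays in a MultilevelNetwork with generic ids."""
    A = np.asarray(A, dtype=np.int8)
    n = A.shape[0]
    if X is None:
        X = np.zeros((n, 2), dtype=np.int8)
    X = np.asarray(X, dtype=np.int8)
    m = X.shape[1]
    if B is None:
        B = np.zeros((m, m), dtype=np.int8)
    return MultilevelNetwork([f"f{i}" for i in range(n)],
                             [f"s{j}" for j in range(m)], A, B, X)


def random_graph(rng, n, p):
    A = (rng.random((n, n)) < p).astype(np.int8)
    A = np.triu(A, 1)
    return A + A.T


def random_multilevel(rng, n=12, m=5, p_a=0.25, p_x=0.4):
    A = random_graph(rng, n, p_a)
    X = (rng.random((n, m)) < p_x).astype(np.int8)
    return make_network(A, X)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
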