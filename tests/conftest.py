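import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def path_graph(n: int) -> np.ndarray:
    adj = np.zeros((n, n))
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1.0
    return adj


def complete_graph(n: int) -> np.ndarray:
    adj = np.ones((n, n)) - np.eye(n)
    return adj


def star_graph(n_leaves: int) -> np.ndarray:
    adj = np.zeros((n_leaves + 1, n_leaves + 1))
    adj[0, 1:] = adj[1:, 0] = 1.0
    return adj


def triangle_plus_pendant() -> np.ndarray:
    adj = np.zeros((4, 4))
    for u, v in [(0, 1), (0, 2), (1, 2), (2, 3)]:
        adj[u, v] = adj[v, u] = 1.0
    return adj
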