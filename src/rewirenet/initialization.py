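"""Initial conditions, parameter families, and null-model ensembles.

This is the synthetic-data stage of the study: everything the simulations
consume is generated here — uniform random simple graphs with a fixed edge
count, Uniform(0, 1) initial activations, the five named parameter families,
and the random-graph ensembles used to normalize network statistics.

The reference configuration is 300 nodes and 5,200 edges (density ≈ 0.116),
with the first 50 nodes forming the "minority" partition whose amplitude or
coupling is perturbed away from the baseline (alpha = 1.8, epsilon = 0.4):

====== ================ ==================
family minority alpha   minority epsilon
====== ================ ==================
BL     1.8              0.4   (baseline)
LC     1.7              0.4   (less chaotic)
MC     1.9              0.4   (more chaotic)
SC     1.8              0.3   (sub-coupled)
HC     1.8              0.5   (hyper-coupled)
====== ================ ==================

Matched initialization: for a given instantiation index the initial graph and
activation vector are identical across all five families (see
:mod:`rewirenet._seeds`), so family comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .dynamics import ActivationState, ParameterSet

__all__ = [
    "FamilySpec",
    "FAMILIES",
    "Partition",
    "check_adjacency",
    "random_graph",
    "initial_activations",
    "family_parameters",
    "er_baseline_ensemble",
    "degree_preserving_randomize",
    "edge_endpoints",
]

N_NODES = 300
N_EDGES = 5200
MINORITY_SIZE = 50


@dataclass(frozen=True)
class FamilySpec:
    """One parameter condition ("family")."""

    name: str
    minority_alpha: float
    minority_epsilon: float
    majority_alpha: float = 1.8
    majority_epsilon: float = 0.4
    minority_size: int = MINORITY_SIZE


FAMILIES: dict[str, FamilySpec] = {
    "BL": FamilySpec("BL", 1.8, 0.4),
    "LC": FamilySpec("LC", 1.7, 0.4),
    "MC": FamilySpec("MC", 1.9, 0.4),
    "SC": FamilySpec("SC", 1.8, 0.3),
    "HC": FamilySpec("HC", 1.8, 0.5),
}


@dataclass(frozen=True)
class Partition:
    """Minority/majority node split (minority = first nodes by convention)."""

    minority: np.ndarray
    majority: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "minority", np.asarray(self.minority, dtype=int))
        object.__setattr__(self, "majority", np.asarray(self.majority, dtype=int))
        if np.intersect1d(self.minority, self.majority).size:
            raise ValueError("minority and majority must be disjoint")

    @classmethod
    def default(cls, n_nodes: int = N_NODES, minority_size: int = MINORITY_SIZE) -> "Partition":
        if not 0 < minority_size < n_nodes:
            raise ValueError("minority_size must be in (0, n_nodes)")
        idx = np.arange(n_nodes)
        return cls(minority=idx[:minority_size], majority=idx[minority_size:])

    @property
    def n_nodes(self) -> int:
        return self.minority.size + self.majority.size


def check_adjacency(adj: np.ndarray, n_edges: int | None = None) -> None:
    """Assert the binary, symmetric, zero-diagonal adjacency invariants."""
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.all((adj == 0) | (adj == 1)):
        raise ValueError("adjacency entries must be 0/1")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if n_edges is not None and int(adj.sum()) != 2 * n_edges:
        raise ValueError(f"expected {n_edges} edges, found {int(adj.sum()) // 2}")


def random_graph(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random simple graph with exactly ``m`` edges.

    Sampled by drawing ``m`` distinct node pairs uniformly without
    replacement, i.e. uniform over simple graphs with ``m`` edges.
    """
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"edge count {m} outside [0, {max_m}]")
    iu, ju = np.triu_indices(n, k=1)
    chosen = rng.choice(max_m, size=m, replace=False)
    adj = np.zeros((n, n))
    adj[iu[chosen], ju[chosen]] = 1.0
    adj += adj.T
    return adj


def initial_activations(n: int, rng: np.random.Generator) -> ActivationState:
    """I.i.d. Uniform(0, 1) initial activations, update counter 0."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return ActivationState(x=rng.random(n), t=0)


def family_parameters(spec: FamilySpec, partition: Partition) -> ParameterSet:
    """Per-node (alpha, epsilon) vectors for one family on one partition."""
    n = partition.n_nodes
    alpha = np.empty(n)
    eps = np.empty(n)
    alpha[partition.majority] = spec.majority_alpha
    eps[partition.majority] = spec.majority_epsilon
    alpha[partition.minority] = spec.minority_alpha
    eps[partition.minority] = spec.minority_epsilon
    return ParameterSet(alpha=alpha, epsilon=eps)


def er_baseline_ensemble(
    n: int, m: int, count: int = 100, rng: np.random.Generator | None = None
) -> list[np.ndarray]:
    """``count`` independent fixed-edge-count random graphs."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    return [random_graph(n, m, rng) for _ in range(count)]


def edge_endpoints(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (upper-triangle endpoints, lower index first)."""
    iu, ju = np.nonzero(np.triu(np.asarray(adj), k=1))
    return iu.astype(np.int64), ju.astype(np.int64)


def degree_preserving_randomize(
    adj: np.ndarray, n_swaps: int | None = None, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Randomize a graph by double-edge swaps, preserving every degree.

    ``n_swaps`` counts swap *attempts* (default 10x the edge count, a
    standard mixing heuristic); attempts that would create a self-loop or a
    multi-edge are rejected.
    """
    if rng is None:
        rng = np.random.default_rng()
    adj = np.asarray(adj, dtype=float).copy()
    eu, ev = edge_endpoints(adj)
    m = eu.size
    if m < 2:
        return adj
    if n_swaps is None:
        n_swaps = 10 * m
    pair_idx = rng.integers(0, m, size=(n_swaps, 2))
    orient = rng.integers(0, 2, size=n_swaps)
    _kernel.double_edge_swaps(adj, eu, ev, pair_idx, orient.astype(np.int64))
    return adj
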