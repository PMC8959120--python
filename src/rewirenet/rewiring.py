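"""Synchronization-driven adaptive rewiring.

One rewiring attempt picks a pivot node uniformly at random, disconnects it
from the neighbor whose activation is most dissimilar (largest absolute
activation difference) and connects it to the non-neighbor whose activation is
most similar.  Ties at the argmax are broken toward the lowest node index so
that trajectories are reproducible.  The total edge count is conserved by
every successful attempt.

Two pathologies can end a model's evolution:

* ``no_non_neighbor`` — the pivot is connected to every other node, so no edge
  can be added;
* ``isolated_node``  — a previous removal left some node with degree zero, so
  the next dynamics step is undefined.

Both are reported as outcomes (never exceptions); the experiment driver
freezes a terminated model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ActivationState, DegenerateDynamicsError, ParameterSet, iterate

__all__ = ["ScoreVectors", "RewiringOutcome", "score_vectors", "rewire_once", "run_epoch"]


@dataclass(frozen=True)
class ScoreVectors:
    """Distance/similarity vectors for one pivot.

    ``d`` is the full per-node distance vector |x_j - x_pivot|, ``s = 1 - d``;
    ``delta`` masks ``d`` to the pivot's neighbors, ``sigma`` masks ``s`` to
    its non-neighbors; both are zero at the pivot itself.
    """

    d: np.ndarray
    s: np.ndarray
    delta: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class RewiringOutcome:
    pivot: int | None = None
    removed: int | None = None
    added: int | None = None
    terminated: bool = False
    termination_reason: str = "none"


def score_vectors(pivot: int, state: ActivationState, adj: np.ndarray) -> ScoreVectors:
    """Distance/similarity scores of all nodes relative to ``pivot``."""
    adj = np.asarray(adj, dtype=float)
    x = state.x
    d = np.abs(x - x[pivot])
    s = 1.0 - d
    row = adj[pivot]
    delta = row * d
    non_neighbor = 1.0 - row
    non_neighbor[pivot] = 0.0
    sigma = non_neighbor * s
    return ScoreVectors(d=d, s=s, delta=delta, sigma=sigma)


def rewire_once(
    state: ActivationState, adj: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, RewiringOutcome]:
    """Perform one rewiring attempt; returns (new adjacency, outcome).

    The input adjacency is not modified.  On termination the adjacency is
    returned unchanged.
    """
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    pivot = int(rng.integers(n))
    row = adj[pivot]
    neighbors = np.flatnonzero(row == 1)
    mask = row == 0
    mask[pivot] = False
    non_neighbors = np.flatnonzero(mask)
    if neighbors.size == 0:
        return adj, RewiringOutcome(
            pivot=pivot, terminated=True, termination_reason="isolated_node"
        )
    if non_neighbors.size == 0:
        return adj, RewiringOutcome(
            pivot=pivot, terminated=True, termination_reason="no_non_neighbor"
        )
    sv = score_vectors(pivot, state, adj)
    # np.argmax keeps the first (lowest-index) maximum: the stated tie rule.
    xi = int(neighbors[np.argmax(sv.d[neighbors])])
    zeta = int(non_neighbors[np.argmax(sv.s[non_neighbors])])
    new_adj = adj.copy()
    new_adj[pivot, xi] = new_adj[xi, pivot] = 0.0
    new_adj[pivot, zeta] = new_adj[zeta, pivot] = 1.0
    return new_adj, RewiringOutcome(pivot=pivot, removed=xi, added=zeta)


def run_epoch(
    state: ActivationState,
    adj: np.ndarray,
    params: ParameterSet,
    rng: np.random.Generator,
    updates_per_rewiring: int = 20,
    prior: RewiringOutcome | None = None,
) -> tuple[ActivationState, np.ndarray, RewiringOutcome]:
    """One epoch: ``updates_per_rewiring`` dynamics updates, then one attempt.

    If ``prior`` records a termination the epoch is a no-op re-reporting it
    (terminated models are absorbing).  A degree-zero node encountered during
    the dynamics yields an ``isolated_node`` termination.
    """
    if updates_per_rewiring < 1:
        raise ValueError("updates_per_rewiring must be >= 1")
    if prior is not None and prior.terminated:
        return state, adj, prior
    try:
        state = iterate(state, adj, params, updates_per_rewiring)
    except DegenerateDynamicsError as err:
        return state, adj, RewiringOutcome(
            pivot=err.node, terminated=True, termination_reason="isolated_node"
        )
    adj, outcome = rewire_once(state, adj, rng)
    return state, adj, outcome
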