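"""Coupled logistic-map dynamics on a fixed binary network.

Each node carries a logistic map ``x -> 1 - alpha * x**2`` whose update is
mixed with the mean map of its graph neighbors, weighted by a per-node
coupling strength ``epsilon``:

    x_i(t+1) = (1 - eps_i) * (1 - alpha_i * x_i(t)**2)
               + eps_i / |B_i| * sum_{j in B_i} (1 - alpha_i * x_j(t)**2)

where ``B_i`` is the neighbor set of node i.  Algebraically this collapses to

    x_i(t+1) = 1 - alpha_i * [(1 - eps_i) * x_i**2 + eps_i/|B_i| * sum x_j**2]

which is the vectorized form used here.  Note the amplitude applied to the
neighbor term: by default the *receiving* node's ``alpha_i`` multiplies the
neighbors' squared activities; the convention of applying each neighbor's own
``alpha_j`` is available through ``ParameterSet.neighbor_amplitude``.

After one update every activation lies in ``[1 - max(alpha), 1]``; for
``alpha <= 2`` the dynamics are therefore bounded without clipping.

A node of degree zero makes the neighbor average undefined; this raises
:class:`DegenerateDynamicsError`, which upstream drivers translate into a
model termination (pathological network development is allowed to happen and
is recorded, not papered over).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParameterSet",
    "ActivationState",
    "DegenerateDynamicsError",
    "logistic_f",
    "coupled_update",
    "iterate",
]


class DegenerateDynamicsError(ValueError):
    """Raised when a degree-0 node makes the coupled update undefined."""

    def __init__(self, node: int):
        self.node = int(node)
        super().__init__(f"node {node} has degree 0; coupled update undefined")


@dataclass(frozen=True)
class ParameterSet:
    """Per-node amplitudes and coupling strengths.

    Parameters
    ----------
    alpha : ndarray
        Logistic-map amplitudes, one per node, each in (0, 2].
    epsilon : ndarray
        Coupling strengths, one per node, each in [0, 1).
    neighbor_amplitude : {"self", "neighbor"}
        Which amplitude multiplies the neighbor activities in the coupling
        term: the receiving node's own ("self", default) or each neighbor's
        ("neighbor").
    """

    alpha: np.ndarray
    epsilon: np.ndarray
    neighbor_amplitude: str = "self"

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        epsilon = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "epsilon", epsilon)
        if alpha.shape != epsilon.shape or alpha.ndim != 1:
            raise ValueError("alpha and epsilon must be 1-D vectors of equal length")
        if np.any(alpha <= 0) or np.any(alpha > 2):
            raise ValueError("alpha entries must lie in (0, 2]")
        if np.any(epsilon < 0) or np.any(epsilon >= 1):
            raise ValueError("epsilon entries must lie in [0, 1)")
        if self.neighbor_amplitude not in ("self", "neighbor"):
            raise ValueError("neighbor_amplitude must be 'self' or 'neighbor'")

    @property
    def n_nodes(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class ActivationState:
    """Activation vector ``x`` plus the discrete update counter ``t``."""

    x: np.ndarray
    t: int = 0

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))

    @property
    def n_nodes(self) -> int:
        return self.x.shape[0]


def logistic_f(x, alpha):
    """Elementwise logistic map ``1 - alpha * x**2``."""
    return 1.0 - np.asarray(alpha, dtype=float) * np.square(np.asarray(x, dtype=float))


def coupled_update(
    state: ActivationState, adj: np.ndarray, params: ParameterSet
) -> ActivationState:
    """One synchronous update of all coupled maps.

    Raises
    ------
    DegenerateDynamicsError
        If any node has degree zero.
    """
    adj = np.asarray(adj, dtype=float)
    x = state.x
    deg = adj.sum(axis=1)
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        raise DegenerateDynamicsError(zero[0])
    x2 = x * x
    alpha, eps = params.alpha, params.epsilon
    if params.neighbor_amplitude == "self":
        x_new = 1.0 - alpha * ((1.0 - eps) * x2 + eps * (adj @ x2) / deg)
    else:
        x_new = 1.0 - (1.0 - eps) * alpha * x2 - eps * (adj @ (alpha * x2)) / deg
    return ActivationState(x=x_new, t=state.t + 1)


def iterate(
    state: ActivationState, adj: np.ndarray, params: ParameterSet, n_steps: int
) -> ActivationState:
    """Apply :func:`coupled_update` ``n_steps`` times (identity for 0)."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    for _ in range(n_steps):
        state = coupled_update(state, adj, params)
    return state
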