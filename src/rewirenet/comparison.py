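"""Comparing evolved models within and between parameter families.

Two network representations are compared:

* **anatomical** connectivity — the evolved adjacency matrix;
* **functional** connectivity — the momentary matrix of absolute activation
  differences, optionally binarized to a graph by keeping the most similar
  pairs at the anatomical edge count.

Two dissimilarity measures are computed for every model pair:

* **NetSimile** — per-node structural features (degree, local clustering,
  two neighborhood averages, three egonet counts) aggregated into a 35-entry
  signature (median, mean, SD, skewness, kurtosis per feature); signatures
  are compared by Canberra distance, and a matrix of distances is normalized
  to [0, 1] by its maximum.
* **HHG** — the Heller-Heller-Gorfine distance-based independence test
  between the two models' node-feature clouds (paired by shared node
  identity), with permutation p-values.  Following the study design, a
  *higher* p-value is read as lower resemblance; this usage is heterodox and
  only meaningful alongside NetSimile.

Block averages of a dissimilarity matrix over family assignments give the
contrast table; the differentiation score of a family is its within-family
resemblance relative to its mean between-family resemblance (NetSimile only,
which is normalized to [0, 1]).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import canberra, pdist, squareform
from scipy.stats import kurtosis, skew

from . import _kernel
from .dynamics import ActivationState

__all__ = [
    "functional_connectivity",
    "functional_graph",
    "netsimile_features",
    "netsimile_signature",
    "netsimile_distance",
    "netsimile_matrix",
    "hhg_pvalue",
    "contrast",
    "differentiation",
    "composite_dissimilarity",
]

N_FEATURES = 7
N_AGGREGATORS = 5
SIGNATURE_LENGTH = N_FEATURES * N_AGGREGATORS


def functional_connectivity(state: ActivationState) -> np.ndarray:
    """Momentary functional connectivity: f_ij = |x_i - x_j|."""
    x = state.x
    return np.abs(x[:, None] - x[None, :])


def functional_graph(f: np.ndarray, target_edges: int) -> np.ndarray:
    """Binarize a functional-connectivity matrix by keeping the
    ``target_edges`` most similar pairs (smallest differences; ties broken by
    the lexicographically lower index pair)."""
    f = np.asarray(f, dtype=float)
    n = f.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if target_edges > iu.size:
        raise ValueError("target_edges exceeds the number of node pairs")
    order = np.lexsort((ju, iu, f[iu, ju]))
    keep = order[:target_edges]
    adj = np.zeros((n, n))
    adj[iu[keep], ju[keep]] = 1.0
    adj += adj.T
    return adj


def netsimile_features(adj: np.ndarray) -> np.ndarray:
    """Per-node NetSimile feature matrix (n x 7).

    Columns: degree; local clustering coefficient; mean degree of neighbors;
    mean clustering of neighbors; egonet edge count; egonet outgoing edge
    count; number of distinct neighbors of the egonet.
    """
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    if n == 0:
        raise ValueError("graph is empty")
    deg = adj.sum(axis=1)
    a2 = adj @ adj
    triangles = (a2 * adj).sum(axis=1) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        local_c = np.where(denom > 0, triangles / denom, 0.0)
        mean_nb_deg = np.where(deg > 0, (adj @ deg) / deg, 0.0)
        mean_nb_c = np.where(deg > 0, (adj @ local_c) / deg, 0.0)
    ego_edges = np.empty(n)
    ego_out = np.empty(n)
    ego_nbrs = np.empty(n)
    bool_adj = adj.astype(bool)
    for i in range(n):
        ego_mask = bool_adj[i].copy()
        ego_mask[i] = True
        members = np.flatnonzero(ego_mask)
        block = adj[np.ix_(members, members)]
        internal = block.sum() / 2.0
        total_deg = deg[members].sum()
        ego_edges[i] = internal
        ego_out[i] = total_deg - 2.0 * internal
        outside = bool_adj[members].any(axis=0) & ~ego_mask
        ego_nbrs[i] = outside.sum()
    return np.column_stack(
        [deg, local_c, mean_nb_deg, mean_nb_c, ego_edges, ego_out, ego_nbrs]
    )


def _aggregate(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    if sd == 0:
        sk, ku = 0.0, 0.0  # moments of a constant feature are degenerate
    else:
        sk = float(skew(values))
        ku = float(kurtosis(values))
    return np.array([float(np.median(values)), float(values.mean()), float(sd), sk, ku])


def netsimile_signature(adj: np.ndarray) -> np.ndarray:
    """35-entry signature: 5 aggregators (median, mean, SD, skewness, excess
    kurtosis) of each of the 7 node features."""
    feats = netsimile_features(adj)
    return np.concatenate([_aggregate(feats[:, j]) for j in range(feats.shape[1])])


def netsimile_distance(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """Canberra distance between two signatures."""
    sig_a = np.asarray(sig_a, dtype=float)
    sig_b = np.asarray(sig_b, dtype=float)
    if sig_a.shape != sig_b.shape:
        raise ValueError("signatures must have equal length")
    return float(canberra(sig_a, sig_b))


def netsimile_matrix(signatures: list[np.ndarray], normalize: bool = True) -> np.ndarray:
    """Pairwise NetSimile distance matrix over a model collection, normalized
    to [0, 1] by its maximum entry (when nonzero)."""
    k = len(signatures)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = netsimile_distance(signatures[i], signatures[j])
    if normalize and mat.max() > 0:
        mat = mat / mat.max()
    return mat


def hhg_pvalue(
    features_a: np.ndarray,
    features_b: np.ndarray,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value of the HHG independence test between two paired
    node-feature matrices (rows paired by shared node identity).

    The statistic is computed from the Euclidean distance matrices of the two
    feature clouds; the null permutes the node pairing of one side.  The
    p-value uses the add-one convention (1 + #{null >= observed}) /
    (1 + n_permutations).
    """
    if rng is None:
        rng = np.random.default_rng()
    fa = np.atleast_2d(np.asarray(features_a, dtype=float))
    fb = np.atleast_2d(np.asarray(features_b, dtype=float))
    if fa.shape[0] != fb.shape[0]:
        raise ValueError("feature matrices must have the same number of rows (nodes)")
    n = fa.shape[0]
    if n < 3:
        raise ValueError("HHG needs at least 3 paired observations")
    dx = squareform(pdist(fa))
    dy = squareform(pdist(fb))
    observed = _kernel.hhg_statistic(dx, dy)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _kernel.hhg_statistic(dx, dy[np.ix_(perm, perm)]) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_permutations)


def contrast(diss: np.ndarray, families: list[str]) -> pd.DataFrame:
    """Family x family block averages of a model-pair dissimilarity matrix.

    Each block mean divides by the full block size |f_i| x |f_j|; diagonal
    blocks therefore include the zero self-pairs, matching the averaging
    used for 10-model families.
    """
    diss = np.asarray(diss, dtype=float)
    families = list(families)
    if diss.shape[0] != len(families):
        raise ValueError("family assignment length must match matrix size")
    names = list(dict.fromkeys(families))
    labels = np.asarray(families)
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for fi in names:
        for fj in names:
            rows = np.flatnonzero(labels == fi)
            cols = np.flatnonzero(labels == fj)
            if rows.size == 0 or cols.size == 0:
                raise ValueError(f"empty family {fi or fj!r}")
            table.loc[fi, fj] = float(diss[np.ix_(rows, cols)].mean())
    return table


def differentiation(contrasts: pd.DataFrame, family: str) -> float:
    """Within-family resemblance over mean between-family resemblance.

    Requires dissimilarities normalized to [0, 1] (NetSimile); values above 1
    mean the family's members resemble each other more than they resemble
    other families.
    """
    others = [f for f in contrasts.index if f != family]
    if not others:
        raise ValueError("differentiation needs >= 2 families")
    within = 1.0 - float(contrasts.loc[family, family])
    between = np.mean([1.0 - float(contrasts.loc[family, other]) for other in others])
    if between == 0:
        raise ValueError("between-family resemblance is zero")
    return within / float(between)


def composite_dissimilarity(netsimile: np.ndarray, hhg: np.ndarray) -> np.ndarray:
    """Composite matrix: HHG p-values below the diagonal, normalized
    NetSimile distances above it, zero diagonal."""
    netsimile = np.asarray(netsimile, dtype=float)
    hhg = np.asarray(hhg, dtype=float)
    if netsimile.shape != hhg.shape or netsimile.shape[0] != netsimile.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    out = np.zeros_like(netsimile)
    lower = np.tril_indices_from(out, k=-1)
    upper = np.triu_indices_from(out, k=1)
    out[lower] = hhg[lower]
    out[upper] = netsimile[upper]
    return out
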