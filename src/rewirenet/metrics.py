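"""Graph statistics for whole networks and partition subgraphs.

Implements the six statistics tracked during network evolution — edge
density, global clustering coefficient, average path length, small-world
index, fast-greedy modularity, degree assortativity — plus the rich-club
profile computed against degree-preserving null ensembles.

Conventions that matter:

* Average path length treats disconnected pairs as distance 0 (they simply do
  not contribute to the sum), so the statistic stays defined on fragmented
  subgraphs.
* The interpartition scope keeps only minority-majority edges; its edge
  density divides by |V_min| * |V_maj| (each cross pair counted once).
* Modularity is the standard Newman Q with m = |E| normalization, maximized
  by the Clauset-Newman-Moore fast-greedy algorithm (igraph).
* Degree assortativity is undefined (NaN) on regular graphs; NaNs are dropped
  from time averages downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import shortest_path
from scipy.stats import wilcoxon

from .initialization import Partition, degree_preserving_randomize

__all__ = [
    "SCOPES",
    "METRIC_COLUMNS",
    "RichClubProfile",
    "subgraph",
    "scope_pair_count",
    "edge_density",
    "global_clustering",
    "average_path_length",
    "small_world_index",
    "modularity",
    "degree_assortativity",
    "rich_club_curve",
    "rich_club_profile",
    "metric_record",
    "normalize_metrics",
]

SCOPES = ("whole", "minority", "majority", "interpartition")
METRIC_COLUMNS = (
    "edge_density",
    "clustering",
    "path_length",
    "small_world",
    "modularity",
    "assortativity",
)


def subgraph(adj: np.ndarray, partition: Partition, scope: str) -> np.ndarray:
    """Scope adjacency: induced minority/majority subgraph, cross edges only
    for ``interpartition`` (full node set), or the whole graph."""
    adj = np.asarray(adj, dtype=float)
    if scope == "whole":
        return adj
    if scope == "minority":
        return adj[np.ix_(partition.minority, partition.minority)]
    if scope == "majority":
        return adj[np.ix_(partition.majority, partition.majority)]
    if scope == "interpartition":
        out = np.zeros_like(adj)
        block = adj[np.ix_(partition.minority, partition.majority)]
        out[np.ix_(partition.minority, partition.majority)] = block
        out[np.ix_(partition.majority, partition.minority)] = block.T
        return out
    raise ValueError(f"unknown scope {scope!r}")


def scope_pair_count(partition: Partition, scope: str) -> int:
    """Number of distinct node pairs that can carry an edge in a scope."""
    n_min = partition.minority.size
    n_maj = partition.majority.size
    if scope == "whole":
        n = n_min + n_maj
        return n * (n - 1) // 2
    if scope == "minority":
        return n_min * (n_min - 1) // 2
    if scope == "majority":
        return n_maj * (n_maj - 1) // 2
    if scope == "interpartition":
        return n_min * n_maj
    raise ValueError(f"unknown scope {scope!r}")


def edge_density(adj: np.ndarray, pair_count: int | None = None) -> float:
    """Fraction of realizable pairs that carry an edge.

    For square scopes ``pair_count`` defaults to n(n-1)/2; bipartite scopes
    pass |V_min|*|V_maj| explicitly.
    """
    adj = np.asarray(adj)
    n = adj.shape[0]
    if pair_count is None:
        if n < 2:
            raise ValueError("edge density needs >= 2 nodes")
        pair_count = n * (n - 1) // 2
    return float(adj.sum() / 2.0 / pair_count)


def global_clustering(adj: np.ndarray) -> float:
    """Closed over connected triplets, via the trace formula
    Tr(A^3) / (sum(A^2) - Tr(A^2)); 0 when no connected triplet exists."""
    adj = np.asarray(adj, dtype=float)
    a2 = adj @ adj
    triplets = a2.sum() - np.trace(a2)
    if triplets == 0:
        return 0.0
    closed = float((a2 * adj).sum())  # == Tr(A^3)
    return closed / float(triplets)


def average_path_length(adj: np.ndarray) -> float:
    """Mean shortest-path length over ordered distinct pairs, with
    disconnected pairs contributing 0."""
    adj = np.asarray(adj, dtype=float)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("path length needs >= 2 nodes")
    dist = shortest_path(sparse.csr_matrix(adj), method="D", unweighted=True)
    dist[np.isinf(dist)] = 0.0
    return float(dist.sum() / (n * (n - 1)))


def small_world_index(clustering: float, path_length: float) -> float:
    """C / PL; NaN when the path length is zero."""
    if path_length == 0 or np.isnan(path_length):
        return float("nan")
    return clustering / path_length


def _to_igraph(adj: np.ndarray) -> ig.Graph:
    iu, ju = np.nonzero(np.triu(np.asarray(adj), k=1))
    return ig.Graph(n=adj.shape[0], edges=list(zip(iu.tolist(), ju.tolist())))


def modularity(adj: np.ndarray) -> tuple[float, np.ndarray]:
    """Fast-greedy (Clauset-Newman-Moore) community detection; returns
    (Q, community labels)."""
    adj = np.asarray(adj)
    if adj.sum() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    g = _to_igraph(adj)
    clustering = g.community_fastgreedy().as_clustering()
    labels = np.asarray(clustering.membership, dtype=int)
    q = float(g.modularity(labels))
    return q, labels


def degree_assortativity(adj: np.ndarray) -> float:
    """Newman's degree assortativity: the Pearson correlation of the degrees
    at the two ends of an edge (over both orientations).  NaN on regular
    graphs, where the remaining-degree variance vanishes."""
    adj = np.asarray(adj, dtype=float)
    deg = adj.sum(axis=1)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    if iu.size < 2:
        return float("nan")
    du, dv = deg[iu], deg[ju]
    xs = np.concatenate([du, dv])
    ys = np.concatenate([dv, du])
    sx = xs.std()
    if sx == 0:
        return float("nan")
    return float(((xs - xs.mean()) * (ys - ys.mean())).mean() / (sx * sx))


def rich_club_curve(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RC(k) for k = 1..max degree: edge density of the subgraph induced by
    nodes of degree >= k.  Returns (k grid, RC values, club sizes); RC is NaN
    where fewer than 2 nodes survive the cutoff."""
    adj = np.asarray(adj, dtype=float)
    deg = adj.sum(axis=1).astype(int)
    kmax = int(deg.max(initial=0))
    if kmax == 0:
        return np.arange(0), np.empty(0), np.empty(0, dtype=int)
    iu, ju = np.nonzero(np.triu(adj, k=1))
    edge_min_deg = np.minimum(deg[iu], deg[ju])
    # suffix sums: nodes (edges) whose (endpoint-minimum) degree is >= k
    node_counts = np.bincount(deg, minlength=kmax + 1)
    edge_counts = np.bincount(edge_min_deg, minlength=kmax + 1)
    nodes_ge = np.cumsum(node_counts[::-1])[::-1]
    edges_ge = np.cumsum(edge_counts[::-1])[::-1]
    ks = np.arange(1, kmax + 1)
    n_k = nodes_ge[1:].astype(int)
    e_k = edges_ge[1:].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = 2.0 * e_k / (n_k * (n_k - 1))
    rc[n_k < 2] = np.nan
    return ks, rc, n_k


@dataclass(frozen=True)
class RichClubProfile:
    """Raw, null-ensemble and normalized rich-club coefficients per club size,
    with one-sided Wilcoxon significance flags against the null ensemble."""

    k: np.ndarray
    club_size: np.ndarray
    rc_raw: np.ndarray
    rc_null_mean: np.ndarray
    rc_norm: np.ndarray
    pvalue: np.ndarray
    significant: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "club_size": self.club_size,
                "rc_raw": self.rc_raw,
                "rc_null_mean": self.rc_null_mean,
                "rc_norm": self.rc_norm,
                "pvalue": self.pvalue,
                "significant": self.significant,
            }
        )


def rich_club_profile(
    adj: np.ndarray,
    null_count: int = 200,
    significance: float = 0.01,
    rng: np.random.Generator | None = None,
    n_swaps: int | None = None,
) -> RichClubProfile:
    """Rich-club coefficients normalized against a degree-preserving null
    ensemble.

    For each club size k the observed RC(k) is divided by the mean RC(k) of
    ``null_count`` degree-preserving randomizations, and tested one-sided
    (observed exceeding the nulls) with a one-sample Wilcoxon signed-rank
    test (normal approximation with continuity correction).
    """
    if rng is None:
        rng = np.random.default_rng()
    adj = np.asarray(adj, dtype=float)
    if adj.sum() < 4:
        raise ValueError("rich-club profile needs >= 2 edges")
    ks, rc, n_k = rich_club_curve(adj)
    nulls = np.full((null_count, ks.size), np.nan)
    for r in range(null_count):
        randomized = degree_preserving_randomize(adj, n_swaps=n_swaps, rng=rng)
        _, rc_null, _ = rich_club_curve(randomized)
        nulls[r, : rc_null.size] = rc_null
    with np.errstate(invalid="ignore"):
        null_mean = np.nanmean(nulls, axis=0)
        rc_norm = rc / null_mean
    pvals = np.full(ks.size, np.nan)
    for idx in range(ks.size):
        if n_k[idx] < 2 or np.isnan(rc[idx]):
            continue
        diffs = nulls[:, idx] - rc[idx]
        diffs = diffs[~np.isnan(diffs)]
        if diffs.size == 0 or np.all(diffs == 0):
            continue
        # H1: nulls fall below the observed coefficient
        res = wilcoxon(diffs, alternative="less", correction=True, method="approx")
        pvals[idx] = float(res.pvalue)
    significant = pvals < significance
    return RichClubProfile(
        k=ks,
        club_size=n_k,
        rc_raw=rc,
        rc_null_mean=null_mean,
        rc_norm=rc_norm,
        pvalue=pvals,
        significant=significant,
    )


def metric_record(adj: np.ndarray, partition: Partition, scope: str) -> dict:
    """All six statistics for one scope of one snapshot (dict of scalars)."""
    sub = subgraph(adj, partition, scope)
    pair_count = scope_pair_count(partition, scope)
    ed = edge_density(sub, pair_count=pair_count)
    c = global_clustering(sub)
    pl = average_path_length(sub)
    sw = small_world_index(c, pl)
    if sub.sum() > 0:
        q, _ = modularity(sub)
    else:
        q = float("nan")
    r = degree_assortativity(sub)
    return {
        "scope": scope,
        "edge_density": ed,
        "clustering": c,
        "path_length": pl,
        "small_world": sw,
        "modularity": q,
        "assortativity": r,
        "n_edges": int(sub.sum() // 2),
    }


def normalize_metrics(series: pd.DataFrame, baseline_means: pd.DataFrame) -> pd.DataFrame:
    """Divide each metric by its random-baseline ensemble mean for the same
    scope; degree assortativity passes through unnormalized.

    ``baseline_means`` is indexed by scope with one column per metric.
    A zero baseline mean yields NaN.
    """
    out = series.copy()
    for scope, row in baseline_means.iterrows():
        mask = out["scope"] == scope
        if not mask.any():
            continue
        for metric in METRIC_COLUMNS:
            if metric == "assortativity":
                continue
            denom = row[metric]
            if denom == 0 or np.isnan(denom):
                out.loc[mask, metric] = np.nan
            else:
                out.loc[mask, metric] = out.loc[mask, metric] / denom
    return out
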