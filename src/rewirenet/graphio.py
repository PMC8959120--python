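"""Readers/writers for graphs and run archives.

Edge lists are plain text: comment/header lines start with ``#``, then one
undirected edge per line as two whitespace-separated 1-based node indices,
lower index first.  GraphML goes through networkx.  A run archive is a
directory holding the manifest (JSON), the metric series (CSV), the final
adjacency (edge list) and the final activations (text), and round-trips
losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import ActivationState
from .experiment import RunManifest, RunResult, TerminationRecord

__all__ = ["write_graph", "read_graph", "save_run", "load_run", "ParseError"]


class ParseError(ValueError):
    """Malformed graph file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def _write_edgelist(path: Path, adj: np.ndarray) -> None:
    n = adj.shape[0]
    iu, ju = np.nonzero(np.triu(adj, k=1))
    with open(path, "w") as fh:
        fh.write("# undirected edge list, 1-based indices, lower index first\n")
        fh.write(f"# nodes: {n}\n")
        fh.write(f"# edges: {iu.size}\n")
        for u, v in zip(iu, ju):
            fh.write(f"{u + 1} {v + 1}\n")


def _read_edgelist(path: Path) -> np.ndarray:
    n = None
    edges = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "nodes:" in stripped:
                    try:
                        n = int(stripped.split("nodes:")[1])
                    except ValueError:
                        raise ParseError(path, line_no, "bad node count header")
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ParseError(path, line_no, f"expected two indices, got {stripped!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError:
                raise ParseError(path, line_no, f"non-integer index in {stripped!r}")
            if u < 1 or v < 1:
                raise ParseError(path, line_no, "indices are 1-based")
            if u == v:
                raise ParseError(path, line_no, "self-loop")
            edges.append((u - 1, v - 1))
    if n is None:
        n = 1 + max((max(e) for e in edges), default=-1)
    adj = np.zeros((n, n))
    for u, v in edges:
        if u >= n or v >= n:
            raise ParseError(path, 0, f"edge ({u + 1}, {v + 1}) exceeds node count {n}")
        adj[u, v] = adj[v, u] = 1.0
    return adj


def write_graph(path, adj: np.ndarray, format: str | None = None) -> None:
    """Write an adjacency matrix as edge-list text or GraphML (inferred from
    the ``.graphml`` suffix when ``format`` is None)."""
    path = Path(path)
    fmt = format or ("graphml" if path.suffix == ".graphml" else "edgelist")
    adj = np.asarray(adj, dtype=float)
    if fmt == "edgelist":
        _write_edgelist(path, adj)
    elif fmt == "graphml":
        g = nx.from_numpy_array(adj)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_graph(path, format: str | None = None) -> np.ndarray:
    """Inverse of :func:`write_graph`; node labeling is preserved."""
    path = Path(path)
    fmt = format or ("graphml" if path.suffix == ".graphml" else "edgelist")
    if fmt == "edgelist":
        return _read_edgelist(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = sorted(g.nodes, key=int)
        return np.asarray(nx.to_numpy_array(g, nodelist=nodes, dtype=float))
    raise ValueError(f"unknown format {fmt!r}")


def save_run(directory, result: RunResult) -> Path:
    """Persist a run (manifest, metric series, final graph and activations)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = dataclasses.asdict(result.manifest)
    manifest["termination"] = dataclasses.asdict(result.termination)
    manifest["final_t"] = result.state.t
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    result.metrics.to_csv(directory / "metrics.csv", index=False)
    write_graph(directory / "final_adjacency.txt", result.adjacency)
    np.savetxt(directory / "final_activations.txt", result.state.x)
    for attempt, snap in result.snapshots.items():
        write_graph(directory / f"adjacency_at_{attempt}.txt", snap)
    return directory


def load_run(directory) -> RunResult:
    """Load a run archive written by :func:`save_run`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    term = TerminationRecord(**manifest.pop("termination"))
    final_t = manifest.pop("final_t")
    run_manifest = RunManifest(**manifest)
    adjacency = read_graph(directory / "final_adjacency.txt")
    x = np.loadtxt(directory / "final_activations.txt")
    metrics = pd.read_csv(directory / "metrics.csv")
    snapshots = {
        int(p.stem.split("_at_")[1]): read_graph(p)
        for p in sorted(directory.glob("adjacency_at_*.txt"))
    }
    return RunResult(
        manifest=run_manifest,
        adjacency=adjacency,
        state=ActivationState(x=x, t=final_t),
        metrics=metrics,
        termination=term,
        snapshots=snapshots,
    )
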