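"""Orchestration of full simulation batteries.

A *run* evolves one network (one family, one instantiation) for a configured
number of rewiring attempts, checkpointing the six network statistics for the
whole network and the minority/majority/interpartition subgraphs.  A
*battery* runs several families x instantiations with matched initial
conditions (identical initial graph and activations for a given
instantiation index across families), normalizes the metric series against
random-graph baselines, and summarizes windowed means/SDs in the style of a
per-family, per-scope table.

Pathological terminations (a node reaching maximal degree, or an isolated
node making the dynamics undefined) freeze the affected model; terminated
runs are excluded from summary statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from ._seeds import substream
from .dynamics import ActivationState, ParameterSet
from .initialization import (
    FAMILIES,
    FamilySpec,
    Partition,
    edge_endpoints,
    family_parameters,
    initial_activations,
    random_graph,
)
from .metrics import METRIC_COLUMNS, SCOPES, metric_record, normalize_metrics, scope_pair_count

logger = logging.getLogger("rewirenet")

__all__ = [
    "RunManifest",
    "TerminationRecord",
    "RunResult",
    "BatteryConfig",
    "BatteryResult",
    "run_model",
    "run_family_battery",
    "baseline_metric_means",
    "growth_factors",
    "summary_table",
]

WINDOW_START = 60_000  # attempts after which the statistics have plateaued


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce one model run."""

    family: str = "BL"
    instantiation: int = 0
    master_seed: int = 0
    n_nodes: int = 300
    n_edges: int = 5200
    minority_size: int = 50
    updates_per_rewiring: int = 20
    total_attempts: int = 1_000_000
    metric_cadence: int = 100
    neighbor_amplitude: str = "self"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.updates_per_rewiring < 1:
            raise ValueError("updates_per_rewiring must be >= 1")
        if self.metric_cadence < 1:
            raise ValueError("metric_cadence must be >= 1")

    @property
    def model_id(self) -> str:
        return f"{self.family}{self.instantiation + 1}"


@dataclass(frozen=True)
class TerminationRecord:
    terminated: bool = False
    attempt: int | None = None
    reason: str = "none"


@dataclass
class RunResult:
    manifest: RunManifest
    adjacency: np.ndarray
    state: ActivationState
    metrics: pd.DataFrame
    termination: TerminationRecord
    snapshots: dict[int, np.ndarray] = None  # attempt -> adjacency copy

    def __post_init__(self):
        if self.snapshots is None:
            self.snapshots = {}

    @property
    def model_id(self) -> str:
        return self.manifest.model_id


def _family_spec(manifest: RunManifest) -> FamilySpec:
    spec = FAMILIES[manifest.family]
    if spec.minority_size != manifest.minority_size:
        spec = FamilySpec(
            spec.name,
            spec.minority_alpha,
            spec.minority_epsilon,
            spec.majority_alpha,
            spec.majority_epsilon,
            minority_size=manifest.minority_size,
        )
    return spec


def _kernel_coefficients(params: ParameterSet, deg: np.ndarray):
    alpha, eps = params.alpha, params.epsilon
    c1 = alpha * (1.0 - eps)
    if params.neighbor_amplitude == "self":
        c2 = alpha * eps
        acc_alpha = 0
    else:
        c2 = eps.copy()
        acc_alpha = 1
    inv_deg = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    return c1, c2, inv_deg, acc_alpha


def run_model(
    manifest: RunManifest,
    scopes: tuple[str, ...] = SCOPES,
    snapshot_attempts: tuple[int, ...] = (),
) -> RunResult:
    """Execute one model run, checkpointing metrics every ``metric_cadence``
    attempts (and at attempt 0 and at termination).

    ``snapshot_attempts`` requests adjacency copies at those checkpoints
    (rounded up to the enclosing cadence boundary), so post-hoc analyses do
    not require re-simulation.
    """
    n, m = manifest.n_nodes, manifest.n_edges
    partition = Partition.default(n, manifest.minority_size)
    rng_init = substream(manifest.master_seed, "init", manifest.instantiation)
    adj = random_graph(n, m, rng_init)
    state = initial_activations(n, rng_init)
    params = family_parameters(_family_spec(manifest), partition)
    if manifest.neighbor_amplitude != "self":
        params = ParameterSet(
            params.alpha, params.epsilon, neighbor_amplitude=manifest.neighbor_amplitude
        )
    rng_dyn = substream(manifest.master_seed, "dynamics", manifest.family, manifest.instantiation)

    x = state.x.copy()
    deg = adj.sum(axis=1)
    eu, ev = edge_endpoints(adj)
    c1, c2, inv_deg, acc_alpha = _kernel_coefficients(params, deg)

    rows: list[dict] = []
    snapshots: dict[int, np.ndarray] = {}
    pending_snapshots = sorted(snapshot_attempts)

    def checkpoint(attempt: int) -> None:
        for scope in scopes:
            rec = metric_record(adj, partition, scope)
            rec["attempt"] = attempt
            rows.append(rec)
        while pending_snapshots and pending_snapshots[0] <= attempt:
            pending_snapshots.pop(0)
            snapshots[attempt] = adj.copy()

    checkpoint(0)
    termination = TerminationRecord()
    attempt = 0
    while attempt < manifest.total_attempts:
        chunk = min(manifest.metric_cadence, manifest.total_attempts - attempt)
        pivots = rng_dyn.integers(0, n, size=chunk)
        status, done, node = _kernel.run_attempts(
            adj,
            eu,
            ev,
            deg,
            x,
            c1,
            c2,
            inv_deg,
            acc_alpha,
            params.alpha,
            pivots,
            manifest.updates_per_rewiring,
        )
        attempt += int(done)
        if status != _kernel.OK:
            reason = (
                "no_non_neighbor" if status == _kernel.NO_NON_NEIGHBOR else "isolated_node"
            )
            termination = TerminationRecord(True, attempt, reason)
            logger.warning(
                "model %s terminated at attempt %d (%s, node %d)",
                manifest.model_id,
                attempt,
                reason,
                node,
            )
            checkpoint(attempt)
            break
        checkpoint(attempt)
        if attempt % 10_000 == 0:
            logger.info("model %s: %d attempts", manifest.model_id, attempt)

    metrics = pd.DataFrame(rows)
    metrics.insert(0, "model", manifest.model_id)
    metrics.insert(1, "family", manifest.family)
    final_state = ActivationState(x=x, t=attempt * manifest.updates_per_rewiring)
    return RunResult(
        manifest=manifest,
        adjacency=adj,
        state=final_state,
        metrics=metrics,
        termination=termination,
        snapshots=snapshots,
    )


def _bipartite_cross_graph(partition: Partition, m: int, rng: np.random.Generator) -> np.ndarray:
    """Random cross-edge-only graph with m minority-majority edges."""
    n = partition.n_nodes
    n_min, n_maj = partition.minority.size, partition.majority.size
    chosen = rng.choice(n_min * n_maj, size=m, replace=False)
    rows = partition.minority[chosen // n_maj]
    cols = partition.majority[chosen % n_maj]
    adj = np.zeros((n, n))
    adj[rows, cols] = 1.0
    adj += adj.T
    return adj


def baseline_metric_means(
    n_nodes: int,
    n_edges: int,
    partition: Partition,
    count: int = 100,
    rng: np.random.Generator | None = None,
    match: str = "scope",
    scopes: tuple[str, ...] = SCOPES,
) -> pd.DataFrame:
    """Ensemble means of all metrics on random graphs matched per scope.

    With ``match="scope"`` each scope gets its own ensemble: random graphs at
    the scope's node count with edge count = round(whole-graph density x
    scope pair count) (a random bipartite cross-edge set for the
    interpartition scope).  With ``match="whole"`` all scopes are normalized
    by the whole-network ensemble.
    """
    if rng is None:
        rng = np.random.default_rng()
    density = n_edges / (n_nodes * (n_nodes - 1) / 2)
    records: dict[str, dict[str, float]] = {}
    if match == "whole":
        vals = {metric: [] for metric in METRIC_COLUMNS}
        for _ in range(count):
            g = random_graph(n_nodes, n_edges, rng)
            rec = metric_record(g, partition, "whole")
            for metric in METRIC_COLUMNS:
                vals[metric].append(rec[metric])
        means = {metric: float(np.nanmean(v)) for metric, v in vals.items()}
        for scope in scopes:
            records[scope] = means
        return pd.DataFrame.from_dict(records, orient="index")
    if match != "scope":
        raise ValueError("match must be 'scope' or 'whole'")
    for scope in scopes:
        pairs = scope_pair_count(partition, scope)
        m_scope = int(round(density * pairs))
        vals = {metric: [] for metric in METRIC_COLUMNS}
        for _ in range(count):
            if scope == "interpartition":
                g = _bipartite_cross_graph(partition, m_scope, rng)
                sub_partition = partition
            elif scope == "whole":
                g = random_graph(n_nodes, n_edges, rng)
                sub_partition = partition
            else:
                size = partition.minority.size if scope == "minority" else partition.majority.size
                g = random_graph(size, m_scope, rng)
                sub_partition = Partition.default(size, max(1, min(size - 1, 1)))
            if scope in ("whole", "interpartition"):
                rec = metric_record(g, sub_partition, scope)
            else:
                # metrics of the standalone scope-sized graph
                rec = metric_record(g, sub_partition, "whole")
            vals_scope = {metric: rec[metric] for metric in METRIC_COLUMNS}
            for metric in METRIC_COLUMNS:
                vals[metric].append(vals_scope[metric])
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN scope metrics
            records[scope] = {metric: float(np.nanmean(v)) for metric, v in vals.items()}
    return pd.DataFrame.from_dict(records, orient="index")


@dataclass(frozen=True)
class BatteryConfig:
    """Configuration of a multi-family battery with matched initializations."""

    families: tuple[str, ...] = ("BL", "LC", "MC", "SC", "HC")
    n_instantiations: int = 10
    master_seed: int = 0
    total_attempts: int = 1_000_000
    metric_cadence: int = 1000
    n_nodes: int = 300
    n_edges: int = 5200
    minority_size: int = 50
    updates_per_rewiring: int = 20
    window_start: int = WINDOW_START
    baseline_count: int = 100
    baseline_match: str = "scope"
    neighbor_amplitude: str = "self"


@dataclass
class BatteryResult:
    config: BatteryConfig
    runs: dict[tuple[str, int], RunResult]
    baseline_means: pd.DataFrame
    summary: pd.DataFrame


def run_family_battery(config: BatteryConfig) -> BatteryResult:
    """Run all families x instantiations and summarize windowed, normalized
    statistics (terminated models excluded from the summary)."""
    if config.n_instantiations < 1:
        raise ValueError("n_instantiations must be >= 1")
    runs: dict[tuple[str, int], RunResult] = {}
    for family in config.families:
        for k in range(config.n_instantiations):
            manifest = RunManifest(
                family=family,
                instantiation=k,
                master_seed=config.master_seed,
                n_nodes=config.n_nodes,
                n_edges=config.n_edges,
                minority_size=config.minority_size,
                updates_per_rewiring=config.updates_per_rewiring,
                total_attempts=config.total_attempts,
                metric_cadence=config.metric_cadence,
                neighbor_amplitude=config.neighbor_amplitude,
            )
            runs[(family, k)] = run_model(manifest)
    partition = Partition.default(config.n_nodes, config.minority_size)
    baseline = baseline_metric_means(
        config.n_nodes,
        config.n_edges,
        partition,
        count=config.baseline_count,
        rng=substream(config.master_seed, "baseline"),
        match=config.baseline_match,
    )
    summary = summary_table(runs.values(), baseline, window_start=config.window_start)
    return BatteryResult(config=config, runs=runs, baseline_means=baseline, summary=summary)


def summary_table(
    runs, baseline_means: pd.DataFrame, window_start: int = WINDOW_START
) -> pd.DataFrame:
    """Windowed (attempt >= window_start) means and SDs of normalized metrics
    per family and scope, pooled over checkpoints of non-terminated runs.
    Degree assortativity is reported unnormalized."""
    frames = []
    for run in runs:
        if run.termination.terminated:
            continue
        series = run.metrics
        windowed = series[series["attempt"] >= window_start]
        if windowed.empty:
            continue
        frames.append(normalize_metrics(windowed, baseline_means))
    if not frames:
        return pd.DataFrame(
            columns=["family", "scope", "metric", "mean", "sd", "n_checkpoints", "n_runs"]
        )
    pooled = pd.concat(frames, ignore_index=True)
    rows = []
    for (family, scope), grp in pooled.groupby(["family", "scope"], sort=False):
        for metric in METRIC_COLUMNS:
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            rows.append(
                {
                    "family": family,
                    "scope": scope,
                    "metric": metric,
                    "mean": float(vals.mean()) if vals.size else float("nan"),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
                    "n_checkpoints": int(vals.size),
                    "n_runs": int(grp["model"].nunique()),
                }
            )
    return pd.DataFrame(rows)


def growth_factors(
    series: pd.DataFrame, window_start: int = WINDOW_START
) -> pd.DataFrame:
    """Per-scope, per-metric ratio of the windowed (attempt >= window_start)
    mean to the attempt-0 (initial random graph) value.

    Raises if the series does not cover attempt 0 and the window (e.g. a
    model that terminated before the window opened).
    """
    if (series["attempt"] == 0).sum() == 0:
        raise ValueError("series lacks the attempt-0 checkpoint")
    windowed = series[series["attempt"] >= window_start]
    if windowed.empty:
        raise ValueError(f"series has no checkpoints at or beyond attempt {window_start}")
    rows = {}
    for scope, grp in series[series["attempt"] == 0].groupby("scope", sort=False):
        base = grp.iloc[0]
        wgrp = windowed[windowed["scope"] == scope]
        factors = {}
        for metric in METRIC_COLUMNS:
            vals = wgrp[metric].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            base_val = float(base[metric])
            if vals.size == 0 or base_val == 0 or np.isnan(base_val):
                factors[metric] = float("nan")
            else:
                factors[metric] = float(vals.mean() / base_val)
        rows[scope] = factors
    return pd.DataFrame.from_dict(rows, orient="index")
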