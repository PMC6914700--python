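"""Efficiency metrics on binary undirected graphs.

Global efficiency of a graph G with N nodes is the mean inverse shortest
path length over ordered node pairs,

    E_global(G) = 1/(N(N-1)) * sum_{i != j} 1/d_ij ,

with 1/inf = 0 for disconnected pairs. Nodal global efficiency anchors the
same sum at one node, E_nodal_global(i) = 1/(N-1) * sum_{j != i} 1/d_ij.
Nodal local efficiency of node i is the global efficiency of the subgraph
induced by i's neighbors (node i itself excluded — the standard convention
of the Brain Connectivity Toolbox; including i would make every neighbor
pair trivially reachable through i and degenerate the measure). Local
efficiency of the network is the mean of the nodal local efficiencies.

A threshold-free summary of any metric across the sparsity sweep is its
area under the curve (AUC), the trapezoidal integral over the grid.

Shortest paths are hop counts computed by breadth-first search, vectorized
as boolean frontier expansion; these routines are self-contained so they
can be verified against independent oracles.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd

from .network import BinaryGraph
from .synthetic import SUBNETWORKS, AtlasSpec


def _adj(g) -> np.ndarray:
    a = g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g)
    return a.astype(bool)


def shortest_paths(g) -> np.ndarray:
    """All-pairs shortest path lengths in hops (BFS); unreachable = +inf."""
    A = _adj(g)
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    reached = np.eye(n, dtype=bool)
    frontier = np.eye(n, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ A) & ~reached
        D[frontier] = d
        reached |= frontier
    return D


def _inv_dist(D: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    return inv


def _pair_inv_sum(A: np.ndarray) -> float:
    """Sum of 1/d_ij over ordered pairs, accumulated during the BFS sweep
    (avoids materializing the distance matrix; 1/inf = 0)."""
    n = A.shape[0]
    eye = np.eye(n, dtype=bool)
    frontier = A & ~eye
    reached = eye | frontier
    total = float(frontier.sum())
    d = 1
    while True:
        nxt = (frontier @ A) & ~reached
        if not nxt.any():
            return total
        d += 1
        total += nxt.sum() / d
        reached |= nxt
        frontier = nxt


def global_efficiency(g) -> float:
    """Mean inverse shortest path length over ordered node pairs."""
    A = _adj(g)
    n = A.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _pair_inv_sum(A) / (n * (n - 1))


def nodal_global_efficiency(g, i: int | None = None):
    """Per-node mean inverse distance to all other nodes.

    Returns the full N-vector, or a scalar when ``i`` is given.
    """
    A = _adj(g)
    n = A.shape[0]
    if n < 2:
        raise ValueError("nodal global efficiency needs at least 2 nodes")
    vec = _inv_dist(shortest_paths(A)).sum(axis=1) / (n - 1)
    if i is None:
        return vec
    if not 0 <= i < n:
        raise ValueError(f"node index {i} out of range")
    return float(vec[i])


def nodal_local_efficiency(g, i: int | None = None):
    """Global efficiency of each node's neighbor-induced subgraph.

    Nodes with fewer than two neighbors score 0 (no pairs to connect).
    """
    A = _adj(g)
    n = A.shape[0]
    if i is not None and not 0 <= i < n:
        raise ValueError(f"node index {i} out of range")
    idx = range(n) if i is None else (i,)
    out = np.zeros(len(idx) if i is None else 1)
    for pos, node in enumerate(idx):
        nb = np.flatnonzero(A[node])
        m = nb.size
        if m < 2:
            continue
        out[pos] = _pair_inv_sum(A[nb][:, nb]) / (m * (m - 1))
    if i is None:
        return out
    return float(out[0])


def local_efficiency(g) -> float:
    """Network local efficiency: mean of the nodal local efficiencies."""
    A = _adj(g)
    if A.shape[0] < 1:
        raise ValueError("empty graph")
    return float(nodal_local_efficiency(A).mean())


def auc_over_sparsity(per_sparsity, values=None) -> float:
    """Trapezoidal integral of a metric over the sparsity grid.

    Accepts either a mapping {S: value} or two parallel arrays
    ``(sparsities, values)``. The grid must be strictly increasing with at
    least two points.
    """
    if values is None:
        if not isinstance(per_sparsity, Mapping):
            raise TypeError("pass a mapping {S: value} or two arrays")
        s = np.array(sorted(per_sparsity))
        v = np.array([per_sparsity[k] for k in s])
    else:
        s = np.asarray(per_sparsity, dtype=float)
        v = np.asarray(values, dtype=float)
    if s.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if not (np.diff(s) > 0).all():
        raise ValueError("sparsity grid must be strictly increasing")
    return float(np.trapezoid(v, s))


def _graph_metrics(A: np.ndarray) -> tuple:
    """(global, local, nodal_global vector, nodal_local vector) in one pass."""
    n = A.shape[0]
    if n < 2:  # singleton scope: every efficiency is 0 by convention
        return 0.0, 0.0, np.zeros(n), np.zeros(n)
    nodal_glob = _inv_dist(shortest_paths(A)).sum(axis=1) / (n - 1)
    glob = float(nodal_glob.mean())
    nodal_loc = nodal_local_efficiency(A)
    return glob, float(nodal_loc.mean()), nodal_glob, nodal_loc


def profile_subject(
    graphs: list,
    atlas: AtlasSpec,
    include_subnetwork_nodal: bool = True,
) -> pd.DataFrame:
    """Efficiency profiles of one subject across the sparsity sweep.

    Rows cover four scopes: whole-brain global & local efficiency; each
    subnetwork's global & local efficiency on its induced subgraph; every
    node's nodal global & local efficiency on the whole-brain graph; and
    (optionally) every node's nodal metrics within its subnetwork's induced
    subgraph. Columns: ``scope_type``, ``scope``, ``node_id``, ``metric``,
    one ``s_<S>`` column per sparsity level, and the AUC.
    """
    if not graphs:
        raise ValueError("empty sparsity sweep")
    svals = [g.sparsity for g in graphs]
    node_ids = list(atlas.node_ids)
    n = atlas.node_count
    sub_idx = {lab: atlas.indices_of(lab) for lab in SUBNETWORKS}

    # curves[(scope_type, scope, node_id, metric)] -> list over sparsity
    curves: dict = {}

    def push(key, val):
        curves.setdefault(key, []).append(val)

    for g in graphs:
        A = _adj(g)
        glob, loc, nglob, nloc = _graph_metrics(A)
        push(("whole_brain", "whole_brain", "", "global"), glob)
        push(("whole_brain", "whole_brain", "", "local"), loc)
        for k, nid in enumerate(node_ids):
            push(("node", "whole_brain", nid, "global"), nglob[k])
            push(("node", "whole_brain", nid, "local"), nloc[k])
        for lab in SUBNETWORKS:
            idx = sub_idx[lab]
            As = A[np.ix_(idx, idx)]
            sglob, sloc, snglob, snloc = _graph_metrics(As)
            push(("subnetwork", lab, "", "global"), sglob)
            push(("subnetwork", lab, "", "local"), sloc)
            if include_subnetwork_nodal:
                for pos, k in enumerate(idx):
                    nid = node_ids[k]
                    push(("subnetwork_node", lab, nid, "global"), snglob[pos])
                    push(("subnetwork_node", lab, nid, "local"), snloc[pos])

    rows = []
    s_cols = [f"s_{s:.2f}" for s in svals]
    for (scope_type, scope, nid, metric), vals in curves.items():
        row = {"scope_type": scope_type, "scope": scope, "node_id": nid, "metric": metric}
        row.update(dict(zip(s_cols, vals)))
        row["auc"] = auc_over_sparsity(svals, vals)
        rows.append(row)
    return pd.DataFrame(rows)
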