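"""From cleaned ROI time series to sparsity-thresholded binary graphs.

Edges are Pearson correlations between regional time series, Fisher
z-transformed for normality, then binarized at a *sparsity* threshold S:
exactly ``K = round(S * N(N-1)/2)`` strongest connections are kept as
undirected unweighted edges. Sweeping S from 0.10 to 0.40 in steps of 0.01
yields a nested family of graphs (same edge ranking, growing K) on which
the efficiency metrics are evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .preprocess import RoiTimeSeries
from .synthetic import AtlasSpec

R_CLIP = 1.0 - 1e-7  # |r| clip before atanh, keeps Fisher z finite


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric N x N Fisher-z association matrix with zero diagonal."""

    values: np.ndarray
    node_ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("connectivity matrix must be finite")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be exactly zero")
        if self.node_ids and len(self.node_ids) != v.shape[0]:
            raise ValueError("node_ids length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class BinaryGraph:
    """Undirected unweighted adjacency at one sparsity level."""

    adjacency: np.ndarray
    sparsity: float
    node_ids: tuple = ()

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if a.dtype != np.int8:
            a = a.astype(np.int8)
        object.__setattr__(self, "adjacency", a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.abs(np.diag(a)).max(initial=0) > 0:
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def pearson_connectivity(ts: RoiTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlations between regional time series.

    The diagonal is set to 0 by convention (self-correlations carry no
    information for thresholding). A zero-variance column is an error
    naming the offending node.
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 timepoints for correlation")
    sd = data.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = [ts.node_ids[j] if ts.node_ids else str(j) for j in bad]
        raise ValueError(f"zero-variance node(s): {names}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return r


def fisher_z(r_matrix: np.ndarray, node_ids: tuple = ()) -> ConnectivityMatrix:
    """Variance-stabilizing atanh transform, |r| clipped below 1."""
    r = np.asarray(r_matrix, dtype=float)
    if np.abs(r).max(initial=0.0) > 1.0:
        raise ValueError("correlations must satisfy |r| <= 1")
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z, tuple(node_ids))


def connectivity_from_timeseries(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation followed by Fisher z, in one step."""
    return fisher_z(pearson_connectivity(ts), ts.node_ids)


def edge_count_at_sparsity(n_nodes: int, sparsity: float) -> int:
    """K = round(S * N(N-1)/2), rounding half away from zero."""
    return int(math.floor(sparsity * n_nodes * (n_nodes - 1) / 2.0 + 0.5))


def _edge_ranking(cm: ConnectivityMatrix, absolute: bool = False) -> tuple:
    """Upper-triangle pairs sorted by descending weight, ties by ascending
    (i, j) lexicographic node order — a deterministic total order."""
    n = cm.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = cm.values[iu, ju]
    if absolute:
        w = np.abs(w)
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_sparsity(cm: ConnectivityMatrix, sparsity: float, absolute: bool = False) -> BinaryGraph:
    """Keep the K strongest connections as undirected unweighted edges.

    Ranking is by signed Fisher z by default (largest positive first);
    ``absolute=True`` ranks by |z| instead. Degenerate graphs (no edges, or
    all pairs connected) are rejected.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    n = cm.n_nodes
    total = n * (n - 1) // 2
    k = edge_count_at_sparsity(n, sparsity)
    if k == 0 or k == total:
        raise ValueError(f"sparsity {sparsity} yields a degenerate graph (K={k} of {total})")
    iu, ju = _edge_ranking(cm, absolute)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:k], ju[:k]] = 1
    adj |= adj.T
    return BinaryGraph(adj, sparsity, cm.node_ids)


def sparsity_grid(s_min: float = 0.10, s_max: float = 0.40, step: float = 0.01) -> np.ndarray:
    if step <= 0 or s_min <= 0 or s_max >= 1 or s_min > s_max:
        raise ValueError("invalid sparsity grid")
    n = int(math.floor((s_max - s_min) / step + 1e-9)) + 1
    return np.round(s_min + step * np.arange(n), 10)


def sparsity_sweep(
    cm: ConnectivityMatrix,
    s_min: float = 0.10,
    s_max: float = 0.40,
    step: float = 0.01,
    absolute: bool = False,
) -> list:
    """Binarize at every grid level. The edge ranking is computed once, so
    the resulting graphs are nested: edges at S_k are a subset of those at
    S_{k+1}."""
    grid = sparsity_grid(s_min, s_max, step)
    n = cm.n_nodes
    total = n * (n - 1) // 2
    iu, ju = _edge_ranking(cm, absolute)
    graphs = []
    adj = np.zeros((n, n), dtype=np.int8)
    prev_k = 0
    for s in grid:
        k = edge_count_at_sparsity(n, s)
        if k == 0 or k == total:
            raise ValueError(f"sparsity {s} yields a degenerate graph")
        adj[iu[prev_k:k], ju[prev_k:k]] = 1
        adj[ju[prev_k:k], iu[prev_k:k]] = 1
        prev_k = max(prev_k, k)
        graphs.append(BinaryGraph(adj.copy(), float(s), cm.node_ids))
    return graphs


def restrict_to_subnetwork(g: BinaryGraph, atlas: AtlasSpec, label: str) -> BinaryGraph:
    """Induced subgraph on one subnetwork's nodes; sparsity recomputed from
    the retained edges."""
    idx = atlas.indices_of(label)  # raises on unknown label
    sub = g.adjacency[np.ix_(idx, idx)]
    m = len(idx)
    pairs = m * (m - 1) / 2.0
    sp = float(np.triu(sub, 1).sum() / pairs) if pairs else 0.0
    ids = tuple(g.node_ids[k] for k in idx) if g.node_ids else ()
    return BinaryGraph(sub, sp, ids)
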