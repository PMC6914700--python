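import numpy as np
import pytest

from braineff import AtlasSpec, CohortDesign, RoiTimeSeries, generate_atlas


@pytest.fixture
def atlas12() -> AtlasSpec:
    """Tiny 12-node atlas, two nodes per subnetwork."""
    return generate_atlas(12)


@pytest.fixture
def small_design() -> CohortDesign:
    return CohortDesign(
        group_sizes={"HC": 6, "WMH-NC": 6, "WMH-CIND": 6},
        timepoints=150,
        seed=7,
    )


def make_ts(data, tr=2.0, **kw) -> RoiTimeSeries:
    data = np.asarray(data, dtype=float)
    return RoiTimeSeries(subject_id="sub-test", data=data, sampling_interval_s=tr, **kw)


# ---- independent shortest-path / efficiency oracles (exhaustive) ----

def floyd_warshall(adj) -> np.ndarray:
    A = np.asarray(adj, dtype=float)
    n = A.shape[0]
    D = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(D, 0.0)
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    return D


def oracle_global_eff(adj) -> float:
    D = floyd_warshall(adj)
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]):
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def oracle_nodal_global_eff(adj, i) -> float:
    D = floyd_warshall(adj)
    n = D.shape[0]
    total = sum(1.0 / D[i, j] for j in range(n) if j != i and np.isfinite(D[i, j]))
    return total / (n - 1)


def oracle_nodal_local_eff(adj, i) -> float:
    A = np.asarray(adj)
    nb = np.flatnonzero(A[i])
    if nb.size < 2:
        return 0.0
    return oracle_global_eff(A[np.ix_(nb, nb)])


def oracle_local_eff(adj) -> float:
    n = np.asarray(adj).shape[0]
    return float(np.mean([oracle_nodal_local_eff(adj, i) for i in range(n)]))


def random_adjacency(rng, n, p) -> np.ndarray:
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1).astype(np.int8)
    return A | A.T
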