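import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braineff import (
    BinaryGraph,
    ConnectivityMatrix,
    auc_over_sparsity,
    generate_atlas,
    global_efficiency,
    local_efficiency,
    nodal_global_efficiency,
    nodal_local_efficiency,
    profile_subject,
    shortest_paths,
    sparsity_grid,
    sparsity_sweep,
)
from .conftest import (
    floyd_warshall,
    oracle_global_eff,
    oracle_local_eff,
    oracle_nodal_global_eff,
    oracle_nodal_local_eff,
    random_adjacency,
)


def adj(edges, n):
    A = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


K3 = adj([(0, 1), (1, 2), (0, 2)], 3)
P3 = adj([(0, 1), (1, 2)], 3)
STAR4 = adj([(0, 1), (0, 2), (0, 3)], 4)
EMPTY4 = np.zeros((4, 4), dtype=np.int8)


class TestShortestPaths:
    def test_triangle_all_distance_one(self):
        D = shortest_paths(K3)
        assert (D[~np.eye(3, dtype=bool)] == 1).all()

    def test_path_graph_two_hops(self):
        assert shortest_paths(P3)[0, 2] == 2

    def test_disconnected_pairs_infinite(self):
        A = adj([(0, 1), (2, 3)], 4)
        D = shortest_paths(A)
        assert np.isinf(D[0, 2]) and np.isinf(D[1, 3])

    def test_agrees_with_floyd_warshall(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = random_adjacency(rng, rng.integers(3, 13), rng.uniform(0.1, 0.9))
            np.testing.assert_array_equal(shortest_paths(A), floyd_warshall(A))


class TestSpotValues:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_unit_efficiency(self, n):
        A = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
        assert global_efficiency(A) == pytest.approx(1.0)
        assert local_efficiency(A) == pytest.approx(1.0)

    def test_path_graph_values(self):
        assert global_efficiency(P3) == pytest.approx(5 / 6)
        assert nodal_global_efficiency(P3, 1) == pytest.approx(1.0)
        assert nodal_global_efficiency(P3, 0) == pytest.approx(0.75)

    def test_star_and_empty(self):
        assert nodal_local_efficiency(STAR4, 0) == 0.0
        assert local_efficiency(STAR4) == 0.0
        assert global_efficiency(EMPTY4) == 0.0
        assert nodal_global_efficiency(EMPTY4, 2) == 0.0

    def test_triangle_local_efficiency(self):
        assert nodal_local_efficiency(K3, 0) == pytest.approx(1.0)
        assert local_efficiency(K3) == pytest.approx(1.0)

    def test_degree_one_node_scores_zero(self):
        assert nodal_local_efficiency(P3, 0) == 0.0

    def test_invalid_node_rejected(self):
        with pytest.raises(ValueError):
            nodal_global_efficiency(K3, 5)
        with pytest.raises(ValueError):
            nodal_local_efficiency(K3, -1)


class TestOracleEquivalence:
    def test_all_four_metrics_match_brute_force(self):
        # exhaustive Floyd-Warshall + direct formula evaluation on small
        # random graphs; tolerance is machine-level
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 13))
            A = random_adjacency(rng, n, rng.uniform(0.1, 0.9))
            assert global_efficiency(A) == pytest.approx(oracle_global_eff(A), abs=1e-12)
            assert local_efficiency(A) == pytest.approx(oracle_local_eff(A), abs=1e-12)
            i = int(rng.integers(n))
            assert nodal_global_efficiency(A, i) == pytest.approx(oracle_nodal_global_eff(A, i), abs=1e-12)
            assert nodal_local_efficiency(A, i) == pytest.approx(oracle_nodal_local_eff(A, i), abs=1e-12)


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_metrics_bounded_and_monotone_under_edge_addition(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        A = random_adjacency(rng, n, 0.4)
        e1 = global_efficiency(A)
        assert 0.0 <= e1 <= 1.0
        assert 0.0 <= local_efficiency(A) <= 1.0
        missing = np.argwhere(np.triu(A == 0, 1))
        if len(missing):
            i, j = missing[rng.integers(len(missing))]
            B = A.copy()
            B[i, j] = B[j, i] = 1
            assert global_efficiency(B) >= e1 - 1e-12

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        A = random_adjacency(rng, n, 0.5)
        perm = rng.permutation(n)
        B = A[np.ix_(perm, perm)]
        assert global_efficiency(B) == pytest.approx(global_efficiency(A), abs=1e-12)
        np.testing.assert_allclose(
            nodal_global_efficiency(B), nodal_global_efficiency(A)[perm], atol=1e-12
        )
        np.testing.assert_allclose(
            nodal_local_efficiency(B), nodal_local_efficiency(A)[perm], atol=1e-12
        )


class TestAuc:
    def test_constant_unit_metric(self):
        grid = sparsity_grid()
        assert auc_over_sparsity(grid, np.ones_like(grid)) == pytest.approx(0.3)
        assert auc_over_sparsity(grid, np.zeros_like(grid)) == 0.0

    def test_linear_metric_exact(self):
        grid = sparsity_grid()
        assert auc_over_sparsity(grid, grid) == pytest.approx((0.4**2 - 0.1**2) / 2)

    def test_mapping_input(self):
        assert auc_over_sparsity({0.1: 1.0, 0.4: 1.0}) == pytest.approx(0.3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            auc_over_sparsity({0.1: 1.0})


class TestProfileSubject:
    def test_counting_contract(self, atlas12):
        rng = np.random.default_rng(1)
        w = rng.standard_normal((12, 12))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        graphs = sparsity_sweep(ConnectivityMatrix(w, tuple(atlas12.node_ids)))
        prof = profile_subject(graphs, atlas12)
        counts = prof.scope_type.value_counts()
        assert counts["whole_brain"] == 2
        assert counts["subnetwork"] == 12
        assert counts["node"] == 2 * 12
        assert counts["subnetwork_node"] == 2 * 12
        s_cols = [c for c in prof.columns if c.startswith("s_")]
        assert len(s_cols) == 31
        assert prof.auc.between(0, 0.3 + 1e-12).all()

    def test_complete_graphs_give_auc_point_three(self, atlas12):
        full = np.ones((12, 12), dtype=np.int8) - np.eye(12, dtype=np.int8)
        graphs = [BinaryGraph(full, s, tuple(atlas12.node_ids)) for s in (0.1, 0.2, 0.3, 0.4)]
        prof = profile_subject(graphs, atlas12)
        glob = prof[(prof.metric == "global") & (prof.scope_type == "whole_brain")]
        assert glob.auc.iloc[0] == pytest.approx(0.3)

    def test_removing_fpn_edges_lowers_fpn_auc(self):
        atlas = generate_atlas(24)
        rng = np.random.default_rng(2)
        intact = random_adjacency(rng, 24, 0.4)
        fpn = atlas.indices_of("FPN")
        intact[np.ix_(fpn, fpn)] = 1 - np.eye(len(fpn), dtype=np.int8)  # fully wired FPN
        damaged = intact.copy()
        damaged[np.ix_(fpn, fpn)] = 0
        svals = (0.1, 0.4)
        prof_a = profile_subject([BinaryGraph(intact, s) for s in svals], atlas)
        prof_b = profile_subject([BinaryGraph(damaged, s) for s in svals], atlas)

        def fpn_auc(p):
            return p[(p.scope == "FPN") & (p.scope_type == "subnetwork") & (p.metric == "global")].auc.iloc[0]

        assert fpn_auc(prof_b) < fpn_auc(prof_a)

    def test_sweep_monotonicity_of_global_efficiency(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        graphs = sparsity_sweep(ConnectivityMatrix(w))
        effs = [global_efficiency(g) for g in graphs]
        assert (np.diff(effs) >= -1e-12).all()
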