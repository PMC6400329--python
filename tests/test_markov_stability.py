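"""Diffusion kernel, stability objective, Louvain ensemble, VI and scale
selection."""

import numpy as np
import pytest

from conftest import exhaustive_max_stability, make_graph

from mstopics.markov_stability import (
    MSScanResult,
    Partition,
    ScanConfig,
    clustered_autocovariance,
    diffusion_operator,
    optimise_partition,
    scan,
    select_scales,
    stability,
    stability_matrix,
    transition_kernel,
    variation_of_information,
)


class TestDiffusionOperator:
    def test_cycle_uniform_stationary(self, small_graphs):
        op = diffusion_operator(small_graphs["cycle7"])
        assert np.allclose(op.pi, 1 / 7)
        assert np.allclose(op.L_rw.sum(axis=1), 0.0, atol=1e-14)

    def test_star_degree_proportional(self, small_graphs):
        op = diffusion_operator(small_graphs["star6"])
        assert op.pi[0] == pytest.approx(5 / 10)
        assert np.allclose(op.pi[1:], 1 / 10)

    def test_two_node_half_half(self):
        op = diffusion_operator(make_graph(np.array([[0.0, 0.7], [0.7, 0.0]])))
        assert np.allclose(op.pi, 0.5)

    def test_isolated_node_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="isolated"):
            diffusion_operator(make_graph(A))


class TestTransitionKernel:
    def test_zero_time_identity(self, small_graphs):
        op = diffusion_operator(small_graphs["path5"])
        assert np.array_equal(transition_kernel(op, 0.0), np.eye(5))

    def test_negative_time_rejected(self, small_graphs):
        op = diffusion_operator(small_graphs["path5"])
        with pytest.raises(ValueError):
            transition_kernel(op, -0.1)

    def test_two_node_closed_form(self):
        op = diffusion_operator(make_graph(np.array([[0.0, 1.0], [1.0, 0.0]])))
        for t in (0.05, 0.5, 2.0, 7.0):
            P = transition_kernel(op, t)
            a = (1 + np.exp(-2 * t)) / 2
            b = (1 - np.exp(-2 * t)) / 2
            assert np.allclose(P, [[a, b], [b, a]], atol=1e-12)

    def test_rows_stochastic_nonnegative(self, small_graphs):
        for G in small_graphs.values():
            op = diffusion_operator(G)
            P = transition_kernel(op, 1.3)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12

    def test_ergodic_limit_reaches_stationary(self, small_graphs):
        op = diffusion_operator(small_graphs["barbell8"])
        P = transition_kernel(op, 1e3)
        assert np.allclose(P, np.tile(op.pi, (8, 1)), atol=1e-6)

    def test_stationarity_of_pi(self, small_graphs):
        for G in small_graphs.values():
            op = diffusion_operator(G)
            for t in (0.1, 1.0, 10.0):
                P = transition_kernel(op, t)
                assert np.allclose(op.pi @ P, op.pi, atol=1e-10)


class TestStability:
    def test_single_community_zero(self, small_graphs):
        for G in small_graphs.values():
            op = diffusion_operator(G)
            part = Partition(np.zeros(op.n_nodes, dtype=int))
            P = transition_kernel(op, 2.0)
            assert stability(op, P, part) == pytest.approx(0.0, abs=1e-12)
            assert clustered_autocovariance(op, P, part) == pytest.approx(0.0, abs=1e-12)

    def test_singletons_at_zero_time(self, small_graphs):
        for G in small_graphs.values():
            op = diffusion_operator(G)
            part = Partition(np.arange(op.n_nodes))
            r = stability(op, transition_kernel(op, 0.0), part)
            assert r == pytest.approx(1 - np.sum(op.pi**2), abs=1e-12)

    def test_singleton_autocov_at_zero_time(self, small_graphs):
        op = diffusion_operator(small_graphs["K4"])
        R = clustered_autocovariance(
            op, transition_kernel(op, 0.0), Partition(np.arange(4))
        )
        assert np.allclose(R, np.diag(op.pi) - np.outer(op.pi, op.pi), atol=1e-14)

    def test_disconnected_cliques_dense_oracle(self, two_cliques_graph):
        # P(t) is block diagonal, so the cross-community Pi P mass is zero
        # and the off-diagonal of R is exactly -(pi_A)(pi_B) = -1/4
        op = diffusion_operator(two_cliques_graph)
        P = transition_kernel(op, 1.0)
        part = Partition(np.array([0, 0, 0, 1, 1, 1]))
        R = clustered_autocovariance(op, P, part)
        dense = part.H.T @ (np.diag(op.pi) @ P - np.outer(op.pi, op.pi)) @ part.H
        assert np.allclose(R, dense, atol=1e-14)
        assert R[0, 1] == pytest.approx(-0.25, abs=1e-12)
        assert R.sum() == pytest.approx(0.0, abs=1e-12)

    def test_conservation_and_relabelling(self, small_graphs):
        rng = np.random.default_rng(3)
        for G in small_graphs.values():
            op = diffusion_operator(G)
            P = transition_kernel(op, 0.7)
            m = rng.integers(0, 3, size=op.n_nodes)
            part = Partition(m)
            R = clustered_autocovariance(op, P, part)
            assert R.sum() == pytest.approx(0.0, abs=1e-10)
            perm = rng.permutation(part.n_communities)
            relabelled = Partition(perm[part.membership])
            assert stability(op, P, relabelled) == pytest.approx(
                stability(op, P, part), abs=1e-12
            )

    def test_barbell_clique_split_is_global_optimum(self, small_graphs):
        op = diffusion_operator(small_graphs["barbell8"])
        P = transition_kernel(op, 1.0)
        part = Partition(np.array([0] * 4 + [1] * 4))
        r = stability(op, P, part)
        assert r == pytest.approx(exhaustive_max_stability(op, 1.0), abs=1e-12)


class TestOptimisePartition:
    def test_two_cliques_recovered(self, two_cliques_graph):
        op = diffusion_operator(two_cliques_graph)
        best, _, r = optimise_partition(op, 1.0, n_runs=50, n_top=10, seed=0)
        assert best == Partition(np.array([0, 0, 0, 1, 1, 1]))
        assert r[0] == pytest.approx(exhaustive_max_stability(op, 1.0), abs=1e-10)

    def test_k4_small_time_singletons(self, small_graphs):
        op = diffusion_operator(small_graphs["K4"])
        best, _, r = optimise_partition(op, 0.01, n_runs=20, n_top=5, seed=0)
        assert r[0] == pytest.approx(exhaustive_max_stability(op, 0.01), abs=1e-10)
        assert best.n_communities == 4

    def test_deterministic_given_seed(self, small_graphs):
        op = diffusion_operator(small_graphs["barbell8"])
        b1, _, _ = optimise_partition(op, 1.0, n_runs=1, n_top=1, seed=13)
        b2, _, _ = optimise_partition(op, 1.0, n_runs=1, n_top=1, seed=13)
        assert b1 == b2

    def test_oracle_equivalence_all_fixtures(self, small_graphs):
        for name, G in small_graphs.items():
            op = diffusion_operator(G)
            for t in (0.1, 1.0, 10.0):
                _, _, r = optimise_partition(op, t, n_runs=30, n_top=5, seed=0)
                oracle = exhaustive_max_stability(op, t)
                assert r[0] == pytest.approx(oracle, abs=1e-10), (name, t)

    def test_n_top_bounds(self, small_graphs):
        op = diffusion_operator(small_graphs["K4"])
        with pytest.raises(ValueError):
            optimise_partition(op, 1.0, n_runs=2, n_top=5)


class TestVariationOfInformation:
    def test_identical_zero(self):
        p = Partition(np.array([0, 1, 1, 0]))
        assert variation_of_information(p, p) == 0.0

    def test_one_vs_singletons_ln4(self):
        c = Partition(np.zeros(4, dtype=int))
        d = Partition(np.arange(4))
        assert variation_of_information(c, d) == pytest.approx(np.log(4), abs=1e-12)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c = (
                Partition(rng.integers(0, 5, size=50)) for _ in range(3)
            )
            assert variation_of_information(a, b) == pytest.approx(
                variation_of_information(b, a), abs=1e-12
            )
            assert variation_of_information(a, b) <= (
                variation_of_information(a, c)
                + variation_of_information(c, b)
                + 1e-12
            )

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information(
                Partition(np.array([0, 1])), Partition(np.array([0, 1, 2]))
            )


@pytest.fixture(scope="module")
def planted_scan(planted_graph):
    G, _, _ = planted_graph
    cfg = ScanConfig(n_times=50, n_runs=50, n_top=10, master_seed=0)
    return scan(G, cfg=cfg), cfg


class TestScanAndSelect:
    def test_two_scale_recovery(self, planted_scan, planted_graph):
        from mstopics.evaluation import nmi

        _, cliques, groups = planted_graph
        res, cfg = planted_scan
        scales = select_scales(res, cfg)
        by_c = {p.n_communities: (t, p) for t, p in scales}
        assert set(by_c) == {4, 2}
        assert nmi(by_c[4][1], Partition.from_labels(cliques)) == pytest.approx(1.0)
        assert nmi(by_c[2][1], Partition.from_labels(groups)) == pytest.approx(1.0)

    def test_vi_zero_on_plateaus(self, planted_scan):
        res, cfg = planted_scan
        for t, _ in select_scales(res, cfg):
            i = int(np.argmin(np.abs(res.times - t)))
            assert res.vi_ensemble[i] == pytest.approx(0.0, abs=1e-12)

    def test_coarsening_across_selected_scales(self, planted_scan, planted_graph):
        res, cfg = planted_scan
        chosen = sorted(select_scales(res, cfg))
        n_comms = [p.n_communities for _, p in chosen]
        assert n_comms == sorted(n_comms, reverse=True)

    def test_vi_cross_diagonal_zero(self, planted_scan):
        res, _ = planted_scan
        assert np.allclose(np.diag(res.vi_cross), 0.0)

    def test_single_time_two_cliques(self, two_cliques_graph):
        cfg = ScanConfig(n_runs=10, n_top=3, master_seed=0)
        res = scan(two_cliques_graph, times=np.array([1.0]), cfg=cfg)
        assert res.n_comms[0] == 2

    def test_stable_single_partition_gives_one_scale(self, two_cliques_graph):
        cfg = ScanConfig(n_times=20, n_runs=10, n_top=3, master_seed=0)
        res = scan(two_cliques_graph, cfg=cfg)
        scales = select_scales(res, cfg)
        assert len(scales) == 1
        assert scales[0][1].n_communities == 2

    def test_empty_grid_rejected(self, two_cliques_graph):
        with pytest.raises(ValueError):
            scan(two_cliques_graph, times=np.array([]))

    def test_r_best_consistent_with_partition(self, planted_scan, planted_graph):
        G, _, _ = planted_graph
        res, _ = planted_scan
        op = diffusion_operator(G)
        for i in (0, len(res.times) // 2, len(res.times) - 1):
            P = transition_kernel(op, res.times[i])
            r = stability(op, P, res.best_partition[i])
            assert r == pytest.approx(res.r_best[i], abs=1e-9)


def test_partition_canonical_labels():
    p = Partition(np.array([5, 5, 2, 7, 2]))
    assert p.membership.tolist() == [0, 0, 1, 2, 1]
    assert p.n_communities == 3
    assert p.H.shape == (5, 3)
    assert Partition.from_labels(["b", "b", "a"]).membership.tolist() == [0, 0, 1]
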