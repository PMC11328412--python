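"""Cluster graph, LTRW pseudotime, forward bias, root/terminal detection."""

import numpy as np
import pytest

import celltrail as ct
from celltrail import cluster as cl
from celltrail.cluster import LtrwParams, ltrw_transition_matrix


def path_hitting_time_oracle(n, j):
    """Closed form: on a path 0..n-1 with unit weights, E_0[T_j] = j^2."""
    return float(j ** 2)


def star_hitting_time_oracle(m):
    """Closed form: center of an m-leaf star to a given leaf = 2m - 1."""
    return float(2 * m - 1)


class TestClusterCells:
    def test_user_labels_pass_through(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 3))
        g = ct.build_knn_graph(X, ct.GraphParams(k=3))
        labels = np.repeat(["x", "y", "z"], 10)
        out = ct.cluster_cells(g, labels=labels)
        # recoded to consecutive ints, grouping preserved
        assert len(np.unique(out)) == 3
        assert (out[:10] == out[0]).all()
        with pytest.raises(ValueError, match="length"):
            ct.cluster_cells(g, labels=labels[:5])

    def test_determinism(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((120, 4))
        g = ct.build_knn_graph(X, ct.GraphParams(k=8))
        a = ct.cluster_cells(g, seed=3)
        b = ct.cluster_cells(g, seed=3)
        assert np.array_equal(a, b)

    def test_recovers_branches_at_low_noise(self):
        """At tiny noise, clusters should align with true branches
        (ARI >= 0.9 after merging clusters by majority branch)."""
        from sklearn.metrics import adjusted_rand_score

        topo = ct.TrajectoryTopology.y(n_features=12)
        t = ct.generate_branching_atlas(topo, n_cells=600, seed=2,
                                        noise_sd=0.01)
        g = ct.build_knn_graph(t.expression, ct.GraphParams(k=10))
        lab = ct.cluster_cells(g, resolution=1.0, seed=2)
        # merge clusters to their majority branch, then compare
        _, coded = np.unique(lab, return_inverse=True)
        merged = np.empty(len(lab), dtype=object)
        for c in np.unique(coded):
            vals, counts = np.unique(t.truth_branch[coded == c],
                                     return_counts=True)
            merged[coded == c] = vals[np.argmax(counts)]
        assert adjusted_rand_score(t.truth_branch, merged) >= 0.9


class TestBuildClusterGraph:
    def test_single_edge_weight(self):
        import scipy.sparse as sp
        W = sp.csr_matrix((4, 4))
        W = W.tolil()
        W[0, 2] = W[2, 0] = 1.0    # one unit edge across the two clusters
        W[0, 1] = W[1, 0] = 5.0    # intra-cluster
        W[2, 3] = W[3, 2] = 5.0
        g = ct.AugmentedGraph(weights=W.tocsr(),
                              provenance=(W.tocsr() > 0).astype(np.uint8),
                              k=1)
        cg = ct.build_cluster_graph(g, np.array([0, 0, 1, 1]))
        assert cg.W[0, 1] == pytest.approx(1.0)

    def test_no_intercluster_edges_warns(self):
        import scipy.sparse as sp
        W = sp.lil_matrix((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        g = ct.AugmentedGraph(weights=W.tocsr(),
                              provenance=(W.tocsr() > 0).astype(np.uint8),
                              k=1)
        with pytest.warns(UserWarning, match="no inter-cluster"):
            cg = ct.build_cluster_graph(g, np.array([0, 0, 1, 1]))
        assert cg.W[0, 1] == 0

    def test_matches_brute_force_accumulation(self):
        """Cluster weights must equal an O(E) double loop over cell
        edges."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 3))
        g = ct.build_knn_graph(X, ct.GraphParams(k=5))
        labels = rng.integers(0, 3, size=50)
        cg = ct.build_cluster_graph(g, labels)
        brute = np.zeros((3, 3))
        coo = g.weights.tocoo()
        for u, v, w in zip(coo.row, coo.col, coo.data):
            if labels[u] != labels[v]:
                brute[labels[u], labels[v]] += w
        brute = (brute + brute.T) / 2   # each undirected edge counted twice
        assert np.allclose(cg.W, brute)


class TestLtrwPseudotime:
    def test_transition_rows_sum_to_one(self, chain_graph):
        for lz, tp in [(0.0, 0.0), (0.3, 0.1), (0.0, 0.2)]:
            P = ltrw_transition_matrix(chain_graph,
                                       LtrwParams(laziness=lz, teleport=tp))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_root_pseudotime_zero_and_range(self, chain_graph):
        pt = ct.ltrw_pseudotime(chain_graph, 0,
                                LtrwParams(n_mcmc=200, seed=0))
        assert pt[0] == 0.0
        assert pt.max() == pytest.approx(1.0)

    def test_chain_hand_solved_hitting_times(self, chain_graph):
        """Analytic hitting times on the unit chain match the closed-form
        birth-death values E_a[T_b]=1, E_a[T_c]=4."""
        raw = ct.ltrw_pseudotime(chain_graph, 0,
                                 LtrwParams(laziness=0.0, teleport=0.0),
                                 return_raw=True)
        assert raw[1] == pytest.approx(path_hitting_time_oracle(3, 1),
                                       abs=1e-10)
        assert raw[2] == pytest.approx(path_hitting_time_oracle(3, 2),
                                       abs=1e-10)

    def test_laziness_doubles_hitting_times(self, chain_graph):
        raw0 = ct.ltrw_pseudotime(chain_graph, 0,
                                  LtrwParams(laziness=0.0, teleport=0.0),
                                  return_raw=True)
        raw5 = ct.ltrw_pseudotime(chain_graph, 0,
                                  LtrwParams(laziness=0.5, teleport=0.0),
                                  return_raw=True)
        assert np.allclose(raw5, 2 * raw0, atol=1e-10)

    def test_star_closed_form(self):
        m = 5
        edges = [("c", f"l{i}", 1.0) for i in range(m)]
        cg = ct.generate_toy_cluster_graph(["c"] + [f"l{i}" for i in range(m)],
                                           edges, root="c")
        raw = ct.ltrw_pseudotime(cg, 0, LtrwParams(laziness=0, teleport=0),
                                 return_raw=True)
        assert np.allclose(raw[1:], star_hitting_time_oracle(m), atol=1e-10)

    def test_scale_invariance(self, chain_graph):
        pt1 = ct.ltrw_pseudotime(chain_graph, 0, LtrwParams(seed=1))
        scaled = ct.ClusterGraph(W=chain_graph.W * 7.5,
                                 names=chain_graph.names)
        pt2 = ct.ltrw_pseudotime(scaled, 0, LtrwParams(seed=1))
        assert np.allclose(pt1, pt2, atol=1e-12)

    def test_path_graph_monotone(self):
        n = 6
        edges = [(i, i + 1, 1.0) for i in range(n - 1)]
        cg = ct.generate_toy_cluster_graph(list(range(n)), edges, root=0)
        raw = ct.ltrw_pseudotime(cg, 0, LtrwParams(laziness=0, teleport=0),
                                 return_raw=True)
        assert (np.diff(raw) > 0).all()

    def test_mcmc_agrees_with_analytic(self):
        """MCMC first-hit estimates agree with the analytic linear solve
        within 3 standard errors on small graphs."""
        from celltrail.cluster import (_analytic_hitting_times,
                                       _mcmc_hitting_times)

        rng = np.random.default_rng(0)
        from conftest import random_toy_graph
        for gi in range(3):
            cg = random_toy_graph(rng, int(rng.integers(4, 10)))
            params = LtrwParams(n_mcmc=5000, max_steps=5000, seed=gi,
                                teleport=0.05)
            P = ltrw_transition_matrix(cg, params)
            analytic = _analytic_hitting_times(P, 0)
            mcmc, se = _mcmc_hitting_times(P, 0, params)
            ok = ~np.isnan(mcmc)
            assert (np.abs(mcmc[ok] - analytic[ok])
                    <= 3 * se[ok] + 1e-9).all()

    def test_disconnected_without_teleport_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        cg = ct.ClusterGraph(W=W)
        with pytest.raises(ValueError, match="disconnected|unreachable"):
            ct.ltrw_pseudotime(cg, 0, LtrwParams(teleport=0.0))


class TestForwardBias:
    def test_equal_pseudotime_splits_evenly(self, chain_graph):
        pt = np.array([0.5, 0.5, 0.5])
        out = cl.forward_bias(chain_graph, pt, None,
                              LtrwParams(velocity_weight=0.0))
        assert out.directed_W[0, 1] == pytest.approx(0.5)
        assert out.directed_W[1, 0] == pytest.approx(0.5)

    def test_large_delta_saturates(self):
        """A pseudotime jump much larger than the typical edge difference
        sends nearly all of the edge's mass forward."""
        n = 12
        edges = [(i, i + 1, 1.0) for i in range(n - 1)]
        cg = ct.generate_toy_cluster_graph(list(range(n)), edges)
        pt = np.linspace(0, 0.1, n).copy()
        pt[-1] = 50.0                      # one huge forward jump
        out = cl.forward_bias(cg, pt, None, LtrwParams(velocity_weight=0.0))
        fwd, back = out.directed_W[n - 2, n - 1], out.directed_W[n - 1, n - 2]
        assert fwd + back == pytest.approx(1.0)
        assert fwd / max(back, 1e-300) > 20

    def test_mass_conservation_without_velocity(self):
        rng = np.random.default_rng(2)
        from conftest import random_toy_graph
        cg = random_toy_graph(rng, 7)
        pt = rng.uniform(0, 1, 7)
        out = cl.forward_bias(cg, pt, None, LtrwParams(velocity_weight=0.0))
        assert np.allclose(out.directed_W + out.directed_W.T, cg.W,
                           atol=1e-12)

    def test_pure_velocity_triangle(self):
        """With velocity_weight=1 the directed rows equal w-scaled
        velocity-transition rows (renormalized to the pseudotime row
        sum)."""
        cg = ct.generate_toy_cluster_graph(
            "abc", [("a", "b", 2.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        vt = np.array([[0.0, 0.75, 0.25],
                       [0.5, 0.0, 0.5],
                       [0.0, 1.0, 0.0]])
        pt = np.array([0.0, 0.5, 1.0])
        out = cl.forward_bias(cg, pt, vt, LtrwParams(velocity_weight=1.0))
        expect = cg.W * vt
        # rows are rescaled; compare normalized row directions
        for i in range(3):
            got, exp = out.directed_W[i], expect[i]
            if exp.sum() > 0:
                assert np.allclose(got / got.sum(), exp / exp.sum(),
                                   atol=1e-12)

    def test_rejects_bad_velocity_weight(self):
        with pytest.raises(ValueError):
            LtrwParams(velocity_weight=1.5)


class TestRootAndTerminals:
    def test_directed_chain_root_is_source(self):
        vt = np.array([[0, 1, 0], [0, 0, 1], [0, 0, 1.0]])
        cg = ct.generate_toy_cluster_graph(
            "abc", [("a", "b", 1.0), ("b", "c", 1.0)])
        assert cl.detect_root(cg, vt) == 0

    def test_symmetric_tie_warns_smallest(self):
        vt = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        cg = ct.generate_toy_cluster_graph(
            "abc", [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
        with pytest.warns(UserWarning, match="tie"):
            assert cl.detect_root(cg, vt) == 0

    def test_requires_velocity(self, chain_graph):
        with pytest.raises(ValueError, match="velocity"):
            cl.detect_root(chain_graph, None)

    def test_terminals_directed_chain(self, directed_chain):
        assert cl.detect_terminals(directed_chain) == [2]

    def test_terminals_star_outward(self):
        m = 4
        edges = [("c", f"l{i}", 1.0) for i in range(m)]
        cg = ct.generate_toy_cluster_graph(["c"] + [f"l{i}" for i in range(m)],
                                           edges, root="c")
        D = np.zeros((m + 1, m + 1))
        D[0, 1:] = 1.0
        cg.directed_W = D
        cg.pseudotime = np.array([0.0] + [1.0] * m)
        terms = cl.detect_terminals(cg)
        assert set(terms) == set(range(1, m + 1))

    def test_fallback_returns_latest_node(self, chain_graph):
        cg = chain_graph
        cg.directed_W = cg.W.copy()     # symmetric: no clear sink
        cg.pseudotime = np.array([0.0, 0.4, 1.0])
        with pytest.warns(UserWarning, match="falling back"):
            terms = cl.detect_terminals(cg, theta_out=0.0)
        assert terms == [2]
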