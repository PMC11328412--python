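"""Second-order walk probabilities, simulation, exact oracle, lineages."""

import numpy as np
import pytest
from conftest import bias_toy_graph, random_toy_graph

import celltrail as ct
from celltrail.walks import (MemoryConfig, enumerate_walk_distribution,
                             first_order_probs, second_order_probs,
                             simulate_walks, step_distribution,
                             walk_pseudotime)


def make_y_toy():
    """Toy 'Y' cluster graph: chain r-j splitting into two 2-node arms."""
    cg = ct.generate_toy_cluster_graph(
        ["r", "j", "a1", "a2", "b1", "b2"],
        [("r", "j", 1.0), ("j", "a1", 1.0), ("a1", "a2", 1.0),
         ("j", "b1", 1.0), ("b1", "b2", 1.0)], root="r")
    pt = np.array([0.0, 0.25, 0.6, 1.0, 0.6, 1.0])
    from celltrail.cluster import LtrwParams, forward_bias
    cg = forward_bias(cg, pt, None, LtrwParams(velocity_weight=0.0))
    cg.root = 0
    cg.terminals = [3, 5]
    return cg


class TestFirstOrder:
    def test_weight_normalization(self):
        cg = ct.generate_toy_cluster_graph(
            "abcd", [("a", "b", 2.0), ("a", "c", 1.0), ("a", "d", 1.0)])
        p = first_order_probs(cg, 0)
        assert np.allclose(p[[1, 2, 3]], [0.5, 0.25, 0.25])

    def test_single_neighbor_and_uniform(self, chain_graph):
        assert first_order_probs(chain_graph, 0)[1] == 1.0
        cg = ct.generate_toy_cluster_graph(
            "abcd", [("a", "b", 1.0), ("a", "c", 1.0), ("a", "d", 1.0)])
        assert np.allclose(first_order_probs(cg, 0)[[1, 2, 3]], 1 / 3)

    def test_sink_rejected(self, directed_chain):
        with pytest.raises(ValueError, match="out-neighbors"):
            first_order_probs(directed_chain, 2)


class TestSecondOrder:
    def test_memory_one_equals_first_order(self):
        """With memory=1 the second-order distribution is exactly the
        memoryless one, for every edge of random graphs."""
        rng = np.random.default_rng(0)
        cfg = MemoryConfig(memory=1.0)
        for _ in range(10):
            cg = random_toy_graph(rng, int(rng.integers(4, 10)))
            iu, ju = np.nonzero(cg.W)
            for u, v in zip(iu, ju):
                p1 = first_order_probs(cg, v)
                p2 = second_order_probs(cg, u, v, cfg)
                assert np.max(np.abs(p1 - p2)) == 0.0

    def test_square_worked_example(self):
        """Square a-b-c-d-a, unit weights, memory=2 at (prev=a, cur=b):
        return to a keeps bias 1, c (not adjacent to a) is halved, so
        p = (2/3, 1/3)."""
        cg = ct.generate_toy_cluster_graph(
            "abcd", [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0),
                     ("d", "a", 1.0)])
        p = second_order_probs(cg, 0, 1, MemoryConfig(memory=2.0))
        assert p[0] == pytest.approx(2 / 3)
        assert p[2] == pytest.approx(1 / 3)
        assert p[1] == 0.0 and p[3] == 0.0

    def test_single_neighbor_any_memory(self, chain_graph):
        for mem in (1, 2, 100):
            p = second_order_probs(chain_graph, 1, 0, MemoryConfig(memory=mem))
            assert p[1] == 1.0

    def test_rejects_memory_below_one(self):
        with pytest.raises(ValueError):
            MemoryConfig(memory=0.5)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            cg = random_toy_graph(rng, 6)
            iu, ju = np.nonzero(cg.W)
            for u, v in zip(iu, ju):
                for mem in (1, 3, 50):
                    p = second_order_probs(cg, u, v,
                                           MemoryConfig(memory=mem))
                    assert abs(p.sum() - 1) < 1e-12

    def test_step_distribution_reduces_to_pure_probs(self):
        cg = make_y_toy()
        cfg = MemoryConfig(memory=5.0, laziness=0.0, teleport=0.0)
        p = step_distribution(cg, 0, 1, cfg)
        q = second_order_probs(cg, 0, 1, cfg)
        assert np.allclose(p, q, atol=1e-15)
        p0 = step_distribution(cg, -1, 0, cfg)
        assert np.allclose(p0, first_order_probs(cg, 0), atol=1e-15)


class TestSimulateWalks:
    def test_directed_chain_deterministic_path(self, directed_chain):
        ens = simulate_walks(directed_chain, 0,
                             MemoryConfig(n_walks=50, teleport=0.0, seed=0))
        assert all(w == [0, 1, 2] for w in ens.walks)
        assert (ens.terminal_hit == 2).all()
        assert np.allclose(ens.visitation[2], 1.0)

    def test_unreachable_terminal_warns(self, directed_chain):
        cg = directed_chain
        cg.terminals = [2]
        D = cg.directed_W.copy()
        D[1, 2] = 0.0                      # cut the only path
        D[1, 0] = 1.0
        cg.directed_W = D
        with pytest.warns(UserWarning, match="reached"):
            ens = simulate_walks(cg, 0, MemoryConfig(n_walks=30, teleport=0.0,
                                                     max_steps=20, seed=0))
        assert (ens.terminal_hit == -1).all()

    def test_seed_determinism(self):
        cg = make_y_toy()
        a = simulate_walks(cg, 0, MemoryConfig(n_walks=200, seed=5))
        b = simulate_walks(cg, 0, MemoryConfig(n_walks=200, seed=5))
        assert a.walks == b.walks
        assert np.array_equal(a.terminal_hit, b.terminal_hit)

    def test_hit_fractions_match_enumeration(self):
        """Monte-Carlo absorption fractions agree with the exact DP
        within 3 binomial standard errors on the toy 'Y'."""
        cg = make_y_toy()
        cfg = MemoryConfig(n_walks=20000, memory=5.0, seed=3)
        ens = simulate_walks(cg, 0, cfg)
        exact = enumerate_walk_distribution(cg, 0, cfg)
        for t, p in exact["absorption"].items():
            se = np.sqrt(max(p * (1 - p), 1e-12) / cfg.n_walks)
            assert abs(ens.hit_fraction(t) - p) <= 3 * se + 1e-9


class TestEnumerate:
    def test_chain_absorbs_fully(self, directed_chain):
        out = enumerate_walk_distribution(
            directed_chain, 0, MemoryConfig(teleport=0.0), horizon=10)
        assert out["absorption"][2] == pytest.approx(1.0)
        assert np.allclose(out["visitation"][2], 1.0)

    def test_symmetric_y_splits_evenly(self):
        """Equal-weight symmetric arms: absorption 1/2 each at memory=1."""
        cg = make_y_toy()
        out = enumerate_walk_distribution(
            cg, 0, MemoryConfig(memory=1.0, teleport=0.0), horizon=400)
        a, b = out["absorption"][3], out["absorption"][5]
        assert a == pytest.approx(b, abs=1e-9)
        assert a + b == pytest.approx(1.0, abs=1e-6)

    def test_memory_changes_absorption_smoothly(self):
        cg = make_y_toy()
        # perturb one arm so absorption is asymmetric and memory-dependent
        cg.directed_W[1, 2] *= 1.5
        vals = []
        for mem in (1, 10):
            out = enumerate_walk_distribution(
                cg, 0, MemoryConfig(memory=mem, teleport=0.0), horizon=400)
            vals.append(out["absorption"][3])
        assert vals[0] != pytest.approx(vals[1], abs=1e-6)

    def test_rejects_large_graphs(self):
        W = np.zeros((30, 30))
        for i in range(29):
            W[i, i + 1] = W[i + 1, i] = 1.0
        cg = ct.ClusterGraph(W=W)
        cg.terminals = [29]
        with pytest.raises(ValueError, match="25"):
            enumerate_walk_distribution(cg, 0, MemoryConfig())


class TestLineageProbabilities:
    def test_chain_all_ones(self, directed_chain):
        ens = simulate_walks(directed_chain, 0,
                             MemoryConfig(n_walks=100, teleport=0.0, seed=0))
        field = ct.lineage_probabilities(ens, directed_chain)
        assert np.allclose(field.cluster_probs[2], 1.0)

    def test_off_branch_lower_than_trunk(self):
        cg = make_y_toy()
        ens = simulate_walks(cg, 0, MemoryConfig(n_walks=5000, seed=1))
        field = ct.lineage_probabilities(ens, cg)
        f = field.cluster_probs[3]         # fate = tip of arm a
        assert f[4] < f[1] and f[5] < f[1]  # arm-b nodes below junction
        assert f[0] == pytest.approx(1.0)   # root visited by every walk

    def test_zero_hit_fate_warns_all_zero(self, directed_chain):
        cg = directed_chain
        cg.terminals = [2, 0]              # root cannot be re-entered
        ens = simulate_walks(cg, 0, MemoryConfig(n_walks=50, teleport=0.0,
                                                 seed=0))
        with pytest.warns(UserWarning, match="all-zero"):
            field = ct.lineage_probabilities(ens, cg)
        assert np.allclose(field.cluster_probs[0], 0.0)

    def test_cell_level_smoothing_bounds(self, tri_atlas_ti):
        d = tri_atlas_ti
        ens = simulate_walks(d["cg"], d["root"],
                             MemoryConfig(n_walks=500, seed=2))
        field = ct.lineage_probabilities(ens, d["cg"], labels=d["labels"],
                                         knn=d["graph"])
        for t in field.fates:
            v = field.cell_probs[t]
            assert v.min() >= 0 and v.max() <= 1 + 1e-12


class TestMemoryScan:
    def test_default_grid_and_positive_correlation(self, y_atlas_small):
        _, table = y_atlas_small
        df = ct.memory_scan(table,
                            walk_config=MemoryConfig(n_walks=400, seed=4))
        assert df["memory"].tolist() == [1, 5, 10, 50, 100]
        assert (df["pearson_r"] > 0).all()

    def test_single_value_matches_direct_run(self, y_atlas_small):
        _, table = y_atlas_small
        cfg = MemoryConfig(n_walks=400, seed=4)
        df = ct.memory_scan(table, memories=[10], walk_config=cfg)
        df2 = ct.memory_scan(table, memories=[10, 10], walk_config=cfg)
        assert len(df) == 1
        assert df["pearson_r"][0] == pytest.approx(df2["pearson_r"][0])

    def test_rejects_memory_below_one(self, y_atlas_small):
        _, table = y_atlas_small
        with pytest.raises(ValueError, match=">= 1"):
            ct.memory_scan(table, memories=[0.5, 2])


class TestGeneTrend:
    def _field(self, n, fate=0):
        f = ct.LineageProbabilityField(cluster_probs={fate: np.ones(1)})
        f.cell_probs[fate] = np.ones(n)
        return f

    def test_constant_gene_constant_trend(self):
        n = 200
        rng = np.random.default_rng(0)
        pt = rng.uniform(0, 1, n)
        trend = ct.gene_trend_along_lineage(np.full(n, 3.5), pt,
                                            self._field(n), 0, n_grid=20)
        assert np.allclose(trend, 3.5)

    def test_uniform_weights_reduce_to_sliding_mean(self):
        n = 300
        rng = np.random.default_rng(1)
        pt = rng.uniform(0, 1, n)
        x = np.sin(2 * np.pi * pt) + rng.normal(0, 0.01, n)
        t1 = ct.gene_trend_along_lineage(x, pt, self._field(n), 0, n_grid=15)
        half = ct.LineageProbabilityField(cluster_probs={0: np.ones(1)})
        half.cell_probs[0] = np.full(n, 0.5)
        t2 = ct.gene_trend_along_lineage(x, pt, half, 0, n_grid=15)
        assert np.allclose(t1, t2)          # constant weights cancel

    def test_sparse_window_warns(self):
        n = 30
        pt = np.concatenate([np.zeros(29), [1.0]])
        with pytest.warns(UserWarning, match="effective"):
            ct.gene_trend_along_lineage(np.ones(n), pt, self._field(n), 0,
                                        n_grid=10, bandwidth=0.01)


class TestWalkPseudotime:
    def test_monotone_on_directed_chain(self, directed_chain):
        pt = walk_pseudotime(directed_chain, 0,
                             MemoryConfig(n_walks=200, teleport=0.0, seed=0))
        assert pt.tolist() == [0.0, 0.5, 1.0]
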