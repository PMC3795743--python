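"""Telescoped weights, graph structure, min-cut vs exhaustive oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import spherecut as sc
from spherecut.errors import ParameterError, SizeError

from conftest import cost_field, triangle_template

def infinite_arc_count(graph):
    data = graph.capacities.data
    return int(np.count_nonzero(data >= data.max() // 2 + 1))


class TestNodeWeights:
    def test_stated_example(self):
        w = sc.node_weights(cost_field([[5.0, 3.0, 7.0]] * 12)).w
        np.testing.assert_array_equal(w[0], [5.0, -2.0, 4.0])

    def test_constant_ray(self):
        w = sc.node_weights(cost_field(np.full((12, 4), 3.25))).w
        np.testing.assert_array_equal(w[:, 0], 3.25)
        np.testing.assert_array_equal(w[:, 1:], 0.0)

    @given(arrays(np.float64, (5, 6), elements=st.floats(0, 1e6, allow_nan=False)))
    def test_prefix_sums_recover_costs(self, c):
        """Telescoping: sum_{z<=k} w(r,z) == c(r,k)."""
        w = sc.node_weights(cost_field(c)).w
        np.testing.assert_allclose(np.cumsum(w, axis=1), c, atol=1e-9)


class TestBuildGraph:
    def test_arc_counts_icosahedron(self, icosahedron):
        # |A_z| = R(Z-1) = 36, |A_r| = 2 * 30 pairs * 4 layers = 240,
        # base arcs = R = 12; all carry the BIG capacity
        costs = cost_field(np.random.default_rng(0).uniform(1, 2, (12, 4)))
        g = sc.build_graph(sc.node_weights(costs), icosahedron, delta_r=1)
        assert infinite_arc_count(g) == 36 + 240 + 12

    def test_delta_zero_connects_equal_layers(self, icosahedron):
        costs = cost_field(np.ones((12, 4)))
        g = sc.build_graph(sc.node_weights(costs), icosahedron, delta_r=0)
        R, Z = 12, 4
        cap = g.capacities.toarray()
        big = cap.max()
        for a, b in icosahedron.neighbor_pairs:
            for z in range(Z):
                assert cap[a * Z + z, b * Z + z] >= big // 2
                assert cap[b * Z + z, a * Z + z] >= big // 2

    def test_negative_delta_rejected(self, icosahedron):
        costs = cost_field(np.ones((12, 3)))
        with pytest.raises(ParameterError):
            sc.build_graph(sc.node_weights(costs), icosahedron, delta_r=-1)


class TestMinCut:
    def test_zero_costs_take_outermost_layer(self, icosahedron):
        """Uniform zero cost: maximal tie-breaking retains everything."""
        costs = cost_field(np.zeros((12, 5)))
        g = sc.build_graph(sc.node_weights(costs), icosahedron, delta_r=1)
        cut = sc.min_cut_surface(g, costs)
        assert np.all(cut.k == 4)
        assert cut.total_cost == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_delta_zero_gives_best_sphere(self, icosahedron, seed):
        """delta_r = 0 constrains the result to a constant layer, and the
        cut picks the layer minimizing the summed cost."""
        rng = np.random.default_rng(seed)
        costs = cost_field(rng.uniform(0, 1, (12, 6)))
        g = sc.build_graph(sc.node_weights(costs), icosahedron, delta_r=0)
        cut = sc.min_cut_surface(g, costs)
        assert len(set(cut.k.tolist())) == 1
        layer_sums = costs.c.sum(axis=0)
        assert cut.k[0] == max(np.flatnonzero(layer_sums == layer_sums.min()))
        assert cut.total_cost == pytest.approx(layer_sums.min(), abs=1e-9)

    def test_three_ray_instance_matches_enumeration(self, three_rays):
        """R=3, Z=3, delta_r=1: exhaustive check over all 27 assignments."""
        rng = np.random.default_rng(42)
        c = rng.uniform(0, 1, (3, 3))
        costs = cost_field(c)
        g = sc.build_graph(sc.node_weights(costs), three_rays, delta_r=1)
        cut = sc.min_cut_surface(g, costs)

        feasible_costs = [
            c[0, i] + c[1, j] + c[2, k]
            for i in range(3) for j in range(3) for k in range(3)
            if abs(i - j) <= 1 and abs(i - k) <= 1 and abs(j - k) <= 1
        ]
        assert cut.total_cost == pytest.approx(min(feasible_costs), abs=1e-9)
        assert cut.is_feasible(three_rays, 1)

    @pytest.mark.parametrize("Z", [3, 4, 5])
    @pytest.mark.parametrize("delta_r", [0, 1, 2])
    def test_oracle_equivalence(self, icosahedron, Z, delta_r):
        """Min-cut total cost equals the exhaustive-search optimum."""
        rng = np.random.default_rng(1000 + 10 * Z + delta_r)
        for _ in range(12):
            costs = cost_field(rng.uniform(0, 1, (12, Z)))
            g = sc.build_graph(sc.node_weights(costs), icosahedron, delta_r)
            cut = sc.min_cut_surface(g, costs)
            oracle = sc.brute_force_surface(costs, icosahedron, delta_r)
            assert cut.total_cost == pytest.approx(oracle.total_cost, abs=1e-9)
            assert cut.is_feasible(icosahedron, delta_r)

    def test_monotone_in_delta(self, icosahedron):
        """The optimum is non-increasing as the feasible set grows."""
        rng = np.random.default_rng(3)
        costs = cost_field(rng.uniform(0, 1, (12, 5)))
        w = sc.node_weights(costs)
        totals = [
            sc.min_cut_surface(sc.build_graph(w, icosahedron, d), costs).total_cost
            for d in (0, 1, 2, 5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))

    def test_scale_equivariance(self, icosahedron):
        rng = np.random.default_rng(4)
        c = rng.uniform(0, 1, (12, 4))
        lam = 37.5
        base = sc.min_cut_surface(
            sc.build_graph(sc.node_weights(cost_field(c)), icosahedron, 1),
            cost_field(c),
        )
        scaled = sc.min_cut_surface(
            sc.build_graph(sc.node_weights(cost_field(lam * c)), icosahedron, 1),
            cost_field(lam * c),
        )
        assert scaled.total_cost == pytest.approx(lam * base.total_cost, rel=1e-9)
        np.testing.assert_array_equal(base.k, scaled.k)


class TestBruteForce:
    def test_unconstrained_takes_per_ray_minima(self, three_rays):
        c = np.array([[0.3, 0.1, 0.5], [0.2, 0.2, 0.9], [0.4, 0.4, 0.4]])
        cut = sc.brute_force_surface(cost_field(c), three_rays, delta_r=3)
        # largest index on ties
        np.testing.assert_array_equal(cut.k, [1, 1, 2])
        assert cut.total_cost == pytest.approx(0.1 + 0.2 + 0.4)

    def test_zero_costs_tie_break_outermost(self, icosahedron):
        cut = sc.brute_force_surface(cost_field(np.zeros((12, 4))), icosahedron, 1)
        np.testing.assert_array_equal(cut.k, 3)

    def test_size_guard(self):
        big = sc.build_template(2)  # R = 162
        costs = cost_field(np.zeros((162, 8)))
        with pytest.raises(SizeError):
            sc.brute_force_surface(costs, big, delta_r=1)
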