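import math

import networkx as nx
import numpy as np
import pytest

from oracles import (
    bh_adjust,
    betweenness_closeness,
    ols_normal_equations,
    welch_t,
)
from syntelink.topology_compare import (
    PARAMETERS,
    TopologyRecord,
    bootstrap_coefficients,
    compare_coefficients,
    component_topology,
    fit_family_regressions,
)


def _weighted(g, w=1.0):
    for e in g.edges:
        g.edges[e]["weight"] = w
    return g


class TestComponentTopology:
    def test_k4_closed_forms(self):
        rec = component_topology(_weighted(nx.complete_graph(4)))
        p = rec.parameters
        assert p["mean_distance"] == 1.0
        assert p["diameter"] == 1.0
        assert p["closeness_norm_min"] == 1.0
        assert p["closeness_norm_max"] == 1.0
        assert p["betweenness_norm_max"] == 0.0
        assert p["degree_norm_min"] == 1.0

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_invariants(self, n):
        rec = component_topology(_weighted(nx.complete_graph(n)))
        p = rec.parameters
        assert p["mean_distance"] == 1.0
        assert p["diameter"] == 1.0
        assert p["closeness_norm_min"] == p["closeness_norm_max"] == 1.0
        assert p["betweenness_norm_max"] == 0.0
        assert p["distances_max"] == p["diameter"]

    def test_star_closed_forms(self):
        rec = component_topology(_weighted(nx.star_graph(4)))  # hub + 4
        p = rec.parameters
        assert p["diameter"] == 2.0
        assert p["betweenness_norm_max"] == 1.0  # the hub
        assert p["degree_norm_min"] == 0.25  # leaves
        assert p["eccentricity_min"] == 1.0
        assert p["neighborhood_size_max"] == 5.0

    def test_random_graphs_match_bruteforce_centralities(self):
        master = np.random.default_rng(31)
        done = 0
        while done < 20:
            n = int(master.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.5,
                                    seed=int(master.integers(2**31)))
            if not (g.number_of_nodes() >= 3 and nx.is_connected(g)):
                continue
            done += 1
            rec = component_topology(_weighted(g))
            bet, clo = betweenness_closeness(g.nodes, g.edges)
            assert rec.parameters["betweenness_norm_max"] == pytest.approx(
                max(bet.values())
            )
            assert rec.parameters["closeness_norm_min"] == pytest.approx(
                min(clo.values())
            )
            assert rec.parameters["closeness_norm_max"] == pytest.approx(
                max(clo.values())
            )

    def test_eigen_value_is_leading_weighted_eigenvalue(self):
        g = _weighted(nx.complete_graph(4), w=0.5)
        rec = component_topology(g)
        # K4 adjacency with 0.5 weights: leading eigenvalue 1.5
        assert rec.parameters["eigen_value"] == pytest.approx(1.5)
        assert rec.parameters["strength_min"] == pytest.approx(1.5)
        assert rec.parameters["eigen_centrality_max"] == 1.0

    def test_mean_distance_diameter_ordering(self):
        g = _weighted(nx.path_graph(6))
        rec = component_topology(g)
        p = rec.parameters
        assert 1.0 <= p["mean_distance"] <= p["diameter"]
        assert p["distances_max"] == p["diameter"]

    def test_small_or_disconnected_rejected(self):
        with pytest.raises(ValueError, match="3 nodes"):
            component_topology(_weighted(nx.complete_graph(2)))
        g = _weighted(nx.Graph([(0, 1), (2, 3)]))
        with pytest.raises(ValueError, match="connected"):
            component_topology(g)


def _records(points, family="A", parameter="mean_distance"):
    out = []
    for i, (x, y) in enumerate(points):
        params = {p: float("nan") for p in PARAMETERS}
        params[parameter] = y
        out.append(
            TopologyRecord(f"c{i}", family, int(x), int(x), params)
        )
    return out


class TestRegressions:
    def test_exact_line(self):
        recs = _records([(3, 1), (5, 2), (7, 3)])
        fit = fit_family_regressions(recs)
        intercept, slope = fit["mean_distance"]
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(-0.5)

    def test_constant_response_zero_slope(self):
        recs = _records([(3, 2), (5, 2), (9, 2)])
        _, slope = fit_family_regressions(recs)["mean_distance"]
        assert slope == pytest.approx(0.0)

    def test_agrees_with_normal_equations(self, rng):
        x = rng.integers(3, 40, size=15)
        y = rng.normal(size=15)
        recs = _records(list(zip(x, y)))
        intercept, slope = fit_family_regressions(recs)["mean_distance"]
        oi, os_ = ols_normal_equations(list(map(float, x)), list(y))
        assert intercept == pytest.approx(oi)
        assert slope == pytest.approx(os_)

    def test_identical_design_rejected(self):
        recs = _records([(5, 1), (5, 2), (5, 3)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_family_regressions(recs)


class TestBootstrap:
    def test_default_replicate_count_equals_component_count(self, rng):
        recs = _records([(3, 1), (5, 2), (7, 3), (9, 5), (11, 4)])
        boot = bootstrap_coefficients(recs, rng=rng)
        assert boot["mean_distance"].shape == (5, 2)

    def test_noiseless_line_gives_identical_replicates(self, rng):
        recs = _records([(3, 1.0), (5, 2.0), (7, 3.0), (9, 4.0)])
        boot = bootstrap_coefficients(recs, n_boot=10, rng=rng)
        coeffs = boot["mean_distance"]
        assert np.allclose(coeffs[:, 0], -0.5)
        assert np.allclose(coeffs[:, 1], 0.5)

    def test_bootstrap_mean_close_to_full_sample_slope(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(3, 30, size=12)
            y = 0.1 * x + rng.normal(scale=0.3, size=12)
            recs = _records(list(zip(x, y)))
            _, slope = fit_family_regressions(recs)["mean_distance"]
            boot = bootstrap_coefficients(recs, n_boot=200, rng=rng)
            slopes = boot["mean_distance"][:, 1]
            se = slopes.std(ddof=1)
            if abs(slopes.mean() - slope) <= 2 * se:
                hits += 1
        assert hits >= 18

    def test_persistent_degeneracy_rejected(self, rng):
        recs = _records([(5, 1), (5, 2), (5, 3)])
        with pytest.raises(ValueError, match="degenerate"):
            bootstrap_coefficients(recs, rng=rng)


class TestCompareCoefficients:
    def _boot(self, values):
        arr = np.column_stack([values, values]).astype(float)
        return {"mean_distance": arr}

    def test_identical_samples_t_zero_p_one(self):
        a = self._boot([1.0, 2.0, 3.0])
        comps = compare_coefficients(a, self._boot([1.0, 2.0, 3.0]))
        for c in comps:
            assert c.t_statistic == pytest.approx(0.0)
            assert c.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        comps = compare_coefficients(self._boot(a), self._boot(b))
        t, df = welch_t(a, b)
        for c in comps:
            assert c.t_statistic == pytest.approx(t)
            assert c.welch_df == pytest.approx(df)

    def test_bh_step_up_definition(self):
        pvals = [0.01, 0.02, 0.04, 0.5]
        expected = bh_adjust(pvals)
        assert expected == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])
        # feed four parameters whose Welch p-values are then BH adjusted
        rng = np.random.default_rng(0)
        samples_a, samples_b = {}, {}
        for i, name in enumerate(["p1", "p2", "p3", "p4"]):
            a = rng.normal(size=30)
            samples_a[name] = np.column_stack([a, a])
            b = rng.normal(size=30)
            samples_b[name] = np.column_stack([b, b])
        comps = compare_coefficients(samples_a, samples_b)
        slopes = [c for c in comps if c.coefficient == "slope"]
        raw = [c.p_value for c in slopes]
        adj = [c.adj_p_value for c in slopes]
        assert adj == pytest.approx(bh_adjust(raw))
        for c in comps:
            assert c.adj_p_value >= c.p_value - 1e-12

    def test_zero_variance_reported_as_undefined(self):
        a = self._boot([2.0, 2.0, 2.0])
        comps = compare_coefficients(a, self._boot([2.0, 2.0, 2.0]))
        for c in comps:
            assert math.isnan(c.t_statistic)
            assert math.isnan(c.p_value)
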