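"""Vessel summaries, responders, assortativity, resistance, efficiency."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvgraph import (assortativity, capillary_efficiency, classify_responders,
                     compute_morphometrics, edge_resistance, efficiency_change,
                     summarize_vessels, vessel_line_graph)
from mvgraph.netmetrics import EfficiencyResult

from conftest import make_metric_graph


def _summary_row(delta, sd, length=60.0, base=3.0):
    return {"edge": 0, "length": length, "baseline_radius_mean": base,
            "baseline_radius_sd": sd, "delta_radius": delta,
            "mean_depth": 100.0, "terminal": False,
            "size_class": "capillary" if base < 5 else "large"}


def _line_graph_from(values, links):
    lg = nx.Graph()
    for node, val in values.items():
        lg.add_node(node, value=float(val))
    lg.add_edges_from(links)
    return lg


class TestClassifyResponders:
    @pytest.mark.parametrize("delta,sd,length,expected", [
        (0.5, 0.2, 60.0, "dilator"),      # 0.5 > 2×0.2
        (0.3, 0.2, 60.0, "none"),         # 0.3 < 0.4
        (-0.5, 0.2, 15.0, "none"),        # too short
        (-0.5, 0.2, 60.0, "constrictor"),
        (0.41, 0.2, 20.0, "none"),        # exactly 20 μm is not longer than
        (0.4, 0.2, 60.0, "none"),         # gate is strict: 0.4 is not > 0.4
    ])
    def test_gate_semantics(self, delta, sd, length, expected):
        df = pd.DataFrame([_summary_row(delta, sd, length)])
        out = classify_responders(df)
        assert out["responder"].iloc[0] == expected

    def test_single_baseline_frame_excluded_with_warning(self):
        df = pd.DataFrame([_summary_row(1.0, np.nan)])
        with pytest.warns(UserWarning, match="baseline"):
            out = classify_responders(df)
        assert out["responder"].iloc[0] == "excluded"


class TestLineGraph:
    def test_y_junction_all_pairs(self):
        vg = make_metric_graph([(0, 1, 30), (0, 2, 30), (0, 3, 30)])
        lg = vessel_line_graph(vg, {0: 1.0, 1: 2.0, 2: 3.0})
        assert lg.number_of_nodes() == 3
        assert lg.number_of_edges() == 3

    def test_chain_single_link(self):
        vg = make_metric_graph([(0, 1, 30), (1, 2, 30)])
        lg = vessel_line_graph(vg, {0: 1.0, 1: 2.0})
        assert lg.number_of_nodes() == 2
        assert lg.number_of_edges() == 1

    def test_disconnected_vessels_unlinked(self):
        vg = make_metric_graph([(0, 1, 30), (2, 3, 30)])
        lg = vessel_line_graph(vg, {0: 1.0, 1: 2.0})
        assert lg.number_of_edges() == 0


class TestAssortativity:
    def test_identical_dumbbells_perfectly_assortative(self):
        lg = _line_graph_from({0: 1, 1: 1, 2: 5, 3: 5}, [(0, 1), (2, 3)])
        assert assortativity(lg) == pytest.approx(1.0, abs=1e-12)

    def test_star_with_opposite_leaves_disassortative(self):
        lg = _line_graph_from({0: 1, 1: -1, 2: -1, 3: -1},
                              [(0, 1), (0, 2), (0, 3)])
        assert assortativity(lg) == pytest.approx(-1.0, abs=1e-12)

    def test_linear_gradient_uncorrelated(self):
        lg = _line_graph_from({0: 1, 1: 2, 2: 3}, [(0, 1), (1, 2)])
        assert assortativity(lg) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        lg = _line_graph_from({0: 2, 1: 2, 2: 2}, [(0, 1), (1, 2)])
        with pytest.raises(ValueError):
            assortativity(lg)

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=8)
        links = [(i, (i + 1) % 8) for i in range(8)] + [(0, 4), (2, 6)]
        lg = _line_graph_from(dict(enumerate(vals)), links)
        lg2 = _line_graph_from(dict(enumerate(vals * scale + shift)), links)
        assert assortativity(lg2) == pytest.approx(assortativity(lg), abs=1e-9)

    def test_matches_networkx_numeric_assortativity(self):
        rng = np.random.default_rng(3)
        g = nx.gnm_random_graph(10, 18, seed=4)
        for n in g.nodes:
            g.nodes[n]["value"] = float(rng.normal())
        ours = assortativity(g)
        theirs = nx.numeric_assortativity_coefficient(g, "value")
        assert ours == pytest.approx(theirs, abs=1e-9)


class TestEdgeResistance:
    def test_reference_value(self):
        rho = edge_resistance(100.0, 4.0, 4.0)
        assert rho == pytest.approx(8 * 0.004 * 1e-4 / (np.pi * (4e-6) ** 4),
                                    rel=1e-12)
        assert rho == pytest.approx(3.98e15, rel=0.01)

    def test_linear_in_length(self):
        assert edge_resistance(200.0, 4.0) == pytest.approx(
            2 * edge_resistance(100.0, 4.0))

    def test_inverse_fourth_power_in_radius(self):
        assert edge_resistance(100.0, 8.0) == pytest.approx(
            edge_resistance(100.0, 4.0) / 16)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            edge_resistance(100.0, 0.0)


def _brute_efficiency(vg, radii, max_diameter=10.0, viscosity=4.0):
    """Oracle: exhaustive simple-path enumeration, min resistance per pair."""
    g = nx.MultiGraph()
    for eid, (u, v, k, data) in enumerate(vg.edges()):
        r = radii.get(eid)
        if r is None or 2 * r > max_diameter:
            continue
        g.add_edge(u, v, resistance=edge_resistance(data["length"], r,
                                                    viscosity))
    nodes = list(g.nodes)
    n = len(nodes)
    total = 0.0
    for i, j in itertools.permutations(nodes, 2):
        best = np.inf
        # enumerate simple paths on the underlying simple graph, then expand
        # parallel-edge choices
        for path in nx.all_simple_paths(nx.Graph(g), i, j):
            options = []
            for a, b in zip(path, path[1:]):
                options.append([d["resistance"] for d in g[a][b].values()])
            for combo in itertools.product(*options):
                best = min(best, sum(combo))
        # direct parallel edges i-j count as paths of length 1 already
        if np.isfinite(best) and best > 0:
            total += 1.0 / best
    return total / (n * (n - 1))


class TestEfficiency:
    def test_single_capillary_pair(self):
        vg = make_metric_graph([(0, 1, 80.0)])
        rho = edge_resistance(80.0, 3.0)
        res = capillary_efficiency(vg, {0: 3.0})
        assert res.value == pytest.approx(1.0 / rho, rel=1e-12)

    def test_three_node_path_enumeration(self):
        vg = make_metric_graph([(0, 1, 50.0), (1, 2, 70.0)])
        r1 = edge_resistance(50.0, 2.5)
        r2 = edge_resistance(70.0, 3.5)
        expected = (2 / r1 + 2 / r2 + 2 / (r1 + r2)) / 6
        res = capillary_efficiency(vg, {0: 2.5, 1: 3.5})
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_wide_vessels_excluded(self):
        vg = make_metric_graph([(0, 1, 50.0), (1, 2, 70.0)])
        res = capillary_efficiency(vg, {0: 2.5, 1: 5.5})  # 11 μm diameter
        assert res.n_nodes == 2
        assert res.value == pytest.approx(1.0 / edge_resistance(50.0, 2.5))

    def test_monotone_in_single_radius(self):
        edges = [(0, 1, 40.0), (1, 2, 40.0), (2, 0, 40.0)]
        vg = make_metric_graph(edges)
        base = capillary_efficiency(vg, {0: 2.0, 1: 2.5, 2: 3.0})
        up = capillary_efficiency(vg, {0: 2.4, 1: 2.5, 2: 3.0},
                                  nodes=base.nodes)
        assert up.value > base.value

    def test_disconnected_pairs_contribute_zero(self):
        vg = make_metric_graph([(0, 1, 40.0), (2, 3, 40.0)])
        res = capillary_efficiency(vg, {0: 3.0, 1: 3.0})
        rho = edge_resistance(40.0, 3.0)
        # nodes {0,1,2,3}; only (0,1) pairs connect
        assert res.n_nodes == 4
        assert res.value == pytest.approx((2 / rho) / 12)

    def test_single_junction_rejected(self):
        vg = make_metric_graph([(0, 0, 40.0)])
        with pytest.raises(ValueError):
            capillary_efficiency(vg, {0: 3.0})

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(3, 8)
            m = rng.integers(n - 1, n + 3)
            edges = []
            for eid in range(m):
                u, v = rng.integers(0, n, size=2)
                if u == v:
                    continue
                edges.append((int(u), int(v), float(rng.uniform(20, 120))))
            if len(edges) < 2:
                continue
            vg = make_metric_graph(edges)
            radii = {i: float(rng.uniform(1.5, 4.5)) for i in range(len(edges))}
            ours = capillary_efficiency(vg, radii).value
            oracle = _brute_efficiency(vg, radii)
            assert ours == pytest.approx(oracle, rel=1e-9)


class TestEfficiencyChange:
    def test_identical_radii_zero_change(self):
        vg = make_metric_graph([(0, 1, 50.0), (1, 2, 70.0)])
        a = capillary_efficiency(vg, {0: 2.5, 1: 3.5})
        b = capillary_efficiency(vg, {0: 2.5, 1: 3.5}, nodes=a.nodes)
        out = efficiency_change(a, b)
        assert out["delta"] == 0.0

    def test_uniform_dilation_fourth_power_law(self):
        edges = [(0, 1, 40.0), (1, 2, 55.0), (2, 0, 70.0), (2, 3, 30.0)]
        vg = make_metric_graph(edges)
        radii = {0: 2.0, 1: 2.5, 2: 3.0, 3: 1.8}
        base = capillary_efficiency(vg, radii)
        up = capillary_efficiency(vg, {k: 1.1 * v for k, v in radii.items()},
                                  nodes=base.nodes)
        down = capillary_efficiency(vg, {k: 0.9 * v for k, v in radii.items()},
                                    nodes=base.nodes)
        assert efficiency_change(base, up)["pct_change"] == pytest.approx(
            100 * (1.1**4 - 1), rel=1e-9)
        assert efficiency_change(base, down)["pct_change"] == pytest.approx(
            100 * (0.9**4 - 1), rel=1e-9)

    def test_differing_node_sets_rejected(self):
        vg = make_metric_graph([(0, 1, 50.0), (1, 2, 70.0)])
        a = capillary_efficiency(vg, {0: 2.5, 1: 3.5})
        b = capillary_efficiency(vg, {0: 2.5, 1: 5.5})  # one edge dropped
        with pytest.raises(ValueError):
            efficiency_change(a, b)


class TestSummaries:
    def _vertex_table(self):
        rows = []
        for eid, radii in ((0, [3.0, 3.1, 2.9, 3.6]), (1, [2.0, 2.0, 2.0, 2.0])):
            for vi in range(5):
                rows.append({"edge": eid, "vertex": vi, "z": 10.0 * eid + vi,
                             "y": 0.0, "x": float(vi),
                             **{f"radius_t{t}": radii[t] for t in range(4)}})
        return pd.DataFrame(rows)

    def test_baseline_and_delta_aggregation(self):
        vg = make_metric_graph([(0, 1, 60.0), (1, 2, 45.0)])
        s = summarize_vessels(self._vertex_table(), vg, [0, 1, 2], [3])
        row0 = s[s.edge == 0].iloc[0]
        assert row0["baseline_radius_mean"] == pytest.approx(3.0)
        assert row0["delta_radius"] == pytest.approx(0.6)
        assert row0["baseline_radius_sd"] == pytest.approx(0.1)
        assert row0["size_class"] == "capillary"

    def test_morphometrics_counts_and_densities(self, y_phantom):
        vg = make_metric_graph([(0, 1, 100.0)])
        table = pd.DataFrame([
            {"edge": 0, "vertex": i, "z": 0.0, "y": 0.0, "x": float(i),
             "radius_t0": 3.0} for i in range(101)])
        s = summarize_vessels(table, vg, [0], [0])
        rep = compute_morphometrics(vg, s, table, fov_volume_mm3=0.001)
        assert rep["vessel_count"] == 1
        assert rep["cumulative_length_density_m_per_mm3"] == pytest.approx(0.1)
        # vascular volume: π·3²·100 μm³ in 0.001 mm³ = 1e9 μm³·0.001...
        assert rep["vascular_volume_density"] == pytest.approx(
            np.pi * 9 * 100 / 1e9 / 0.001, rel=1e-6)

    def test_zero_fov_rejected(self):
        vg = make_metric_graph([(0, 1, 100.0)])
        table = pd.DataFrame([{"edge": 0, "vertex": 0, "z": 0, "y": 0, "x": 0,
                               "radius_t0": 3.0}])
        s = summarize_vessels(table, vg, [0], [0])
        with pytest.raises(ValueError):
            compute_morphometrics(vg, s, table, fov_volume_mm3=0.0)
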