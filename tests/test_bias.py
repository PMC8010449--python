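"""Hamming distance, ERGM pseudo-likelihood fits and bias trimming."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cambronet.bias import (
    BiasCalibration,
    bias_series_and_trim,
    edge_normalized_alteration,
    fit_ergm,
    hamming_distance,
)
from cambronet.io import StratWindow
from cambronet.synthetic import generate_assemblage


def graph(nodes, edges):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestHamming:
    def test_identity(self):
        g = graph("abcd", [("a", "b")])
        assert hamming_distance(g, g) == 0.0

    def test_empty_vs_complete(self):
        nodes = "abcd"
        empty = graph(nodes, [])
        complete = graph(nodes, itertools.combinations(nodes, 2))
        assert hamming_distance(empty, complete) == 1.0

    def test_enumeration_oracle(self):
        g1 = graph("ABCD", [("A", "B"), ("B", "C")])
        g2 = graph("ABCD", [("A", "B"), ("C", "D")])
        # enumerate all 6 pairs: BC and CD differ
        assert hamming_distance(g1, g2) == pytest.approx(2 / 6)

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hamming_distance(graph("abc", []), graph("abd", []))

    def test_metric_properties_on_random_graphs(self):
        rng = np.random.default_rng(0)
        nodes = list(range(8))
        for _ in range(20):
            gs = [
                graph(nodes, [e for e in itertools.combinations(nodes, 2)
                              if rng.random() < 0.3])
                for _ in range(3)
            ]
            d01 = hamming_distance(gs[0], gs[1])
            d12 = hamming_distance(gs[1], gs[2])
            d02 = hamming_distance(gs[0], gs[2])
            assert d01 == hamming_distance(gs[1], gs[0])
            assert d02 <= d01 + d12 + 1e-12

    def test_edge_normalized_range(self):
        g1 = graph("abcd", [("a", "b"), ("c", "d")])
        g2 = graph("abcd", [("a", "c"), ("b", "d")])
        assert edge_normalized_alteration(g1, g2) == 1.0
        assert edge_normalized_alteration(g1, g1) == 0.0


class TestERGM:
    def labels_for(self, nodes, cats=("x", "y", "z")):
        return {n: cats[i % len(cats)] for i, n in enumerate(sorted(nodes))}

    def test_empty_graph_degenerate_delta_zero(self):
        g = graph(range(6), [])
        fit = fit_ergm(g, self.labels_for(g.nodes))
        assert fit.degenerate
        assert fit.delta == 0.0

    def test_complete_graph_degenerate(self):
        g = graph(range(6), itertools.combinations(range(6), 2))
        assert fit_ergm(g, self.labels_for(g.nodes)).degenerate

    def test_random_labels_small_delta(self):
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(30):
            edges = [e for e in itertools.combinations(range(12), 2)
                     if rng.random() < 0.25]
            g = graph(range(12), edges)
            labels = {n: rng.choice(["x", "y", "z"]) for n in g.nodes}
            if len(set(labels.values())) < 2 or not edges:
                continue
            deltas.append(fit_ergm(g, labels).delta)
        # chi-square-scale noise per dyad: df about 5 over 66 dyads
        assert np.median(deltas) < 0.15

    def test_clique_structure_large_homophily(self):
        nodes = [f"n{i}" for i in range(12)]
        g = graph(nodes, [])
        labels = {n: ("hard" if i < 6 else "soft") for i, n in enumerate(nodes)}
        for a, b in itertools.combinations(nodes[:6], 2):
            g.add_edge(a, b)
        fit = fit_ergm(g, labels)
        assert fit.coefficients["match.hard"] > 1.0
        assert fit.delta > 0.3

    def test_missing_label_rejected(self):
        g = graph("abcde", [("a", "b")])
        with pytest.raises(KeyError):
            fit_ergm(g, {"a": "x", "b": "y", "c": "x", "d": "y"})

    def test_relabeling_within_categories_invariant(self):
        rng = np.random.default_rng(2)
        edges = [e for e in itertools.combinations(range(10), 2) if rng.random() < 0.3]
        g = graph(range(10), edges)
        labels = {n: ("a" if n < 5 else "b") for n in g.nodes}
        renamed = {n: ("alpha" if v == "a" else "beta") for n, v in labels.items()}
        assert fit_ergm(g, labels).delta == pytest.approx(
            fit_ergm(g, renamed).delta, abs=1e-9
        )


class TestCalibrationObject:
    def cal(self):
        return BiasCalibration(
            effect_grid=np.array([0.0, 1.0, 2.0, 4.0]),
            alt_fitted=np.array([0.05, 0.1, 0.3, 0.4]),
            floor=0.05,
            ceil=0.4,
        )

    def test_monotone_lookup(self):
        cal = self.cal()
        xs = np.linspace(-1, 10, 50)
        ys = [cal.expected_alteration(x) for x in xs]
        assert all(b >= a - 1e-12 for a, b in zip(ys, ys[1:]))

    def test_coefficient_range_and_extremes(self):
        cal = self.cal()
        assert cal.coefficient(0.0) == 0.0
        assert cal.coefficient(4.0) == 1.0
        assert cal.coefficient(100.0) == 1.0
        assert 0.0 <= cal.coefficient(1.5) <= 1.0

    def test_flat_calibration_returns_zero(self):
        cal = BiasCalibration(
            effect_grid=np.array([0.0]), alt_fitted=np.array([0.0]),
            floor=0.0, ceil=0.0, flat=True,
        )
        assert cal.coefficient(5.0) == 0.0


class TestTrim:
    def windows_and_networks(self, coefficient_pattern):
        """Fabricate windows whose ERGM structure forces given flags."""
        asm = generate_assemblage(n_taxa=12, n_levels=10, seed=0)
        windows = [
            StratWindow(window_id=i, level_indices=(i,), depth_span_cm=(i * 10, i * 10 + 10))
            for i in range(len(coefficient_pattern))
        ]
        return asm, windows

    def test_nothing_trimmed_when_unbiased(self):
        asm, windows = self.windows_and_networks([0, 0, 0])
        cal = BiasCalibration(
            effect_grid=np.array([0.0, 5.0]), alt_fitted=np.array([0.0, 0.5]),
            floor=0.0, ceil=0.5,
        )
        nets = []
        for _ in windows:
            g = nx.Graph()
            g.add_nodes_from(asm.abundance.taxon_names)
            nets.append(g)  # empty network: degenerate fit, effect 0
        series, retained, trims = bias_series_and_trim(
            windows, nets, asm.traits, cal, threshold=0.5
        )
        assert series.excluded_windows() == ()
        assert retained == tuple(w.window_id for w in windows)
        assert trims == {"bottom": [], "top": []}

    def test_threshold_zero_trims_everything_flagged(self):
        asm, windows = self.windows_and_networks([1, 1])
        cal = BiasCalibration(
            effect_grid=np.array([0.0, 1.0]), alt_fitted=np.array([0.1, 0.5]),
            floor=0.0, ceil=0.5,
        )
        nets = []
        rng = np.random.default_rng(0)
        for _ in windows:
            g = nx.Graph()
            g.add_nodes_from(asm.abundance.taxon_names)
            names = list(asm.abundance.taxon_names)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    if rng.random() < 0.3:
                        g.add_edge(names[i], names[j])
            nets.append(g)
        series, retained, trims = bias_series_and_trim(
            windows, nets, asm.traits, cal, threshold=-0.01
        )
        assert retained == ()
        assert trims["bottom"] == [w.window_id for w in windows]

    def test_one_network_per_window_required(self):
        asm, windows = self.windows_and_networks([0, 0])
        cal = BiasCalibration(
            effect_grid=np.array([0.0]), alt_fitted=np.array([0.0]),
            floor=0.0, ceil=0.0, flat=True,
        )
        with pytest.raises(ValueError):
            bias_series_and_trim(windows, [nx.Graph()], asm.traits, cal)
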