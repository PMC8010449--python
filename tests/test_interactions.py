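"""Consensus interactions, literature comparison and control analyses."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cambronet.corrnet import CorrelationSet
from cambronet.interactions import (
    categorize_pairs,
    compare_to_literature,
    consensus_interactions,
    fit_sbm,
    habitat_chisq,
    sbm_equitability,
)
from cambronet.mixture import CategoryScheme, GaussianComponent


def make_cs(rows):
    pairs = pd.DataFrame(
        rows, columns=["taxon_a", "taxon_b", "r", "p", "q", "n_levels", "co_occurrence"]
    )
    taxa = tuple(sorted(set(pairs.taxon_a) | set(pairs.taxon_b)))
    return CorrelationSet(taxa=taxa, pairs=pairs)


def scheme4():
    comps = tuple(
        (GaussianComponent(m, 0.05, 1.0),) for m in (-0.5, 0.0, 0.35, 0.7)
    )
    iv = ((-0.55, -0.45), (-0.1, 0.1), (0.3, 0.4), (0.6, 0.8))
    return CategoryScheme(clusters=comps, intervals=iv, assignment_intervals=iv)


class TestCategorize:
    def test_below_all_intervals_uncategorized(self):
        cs = make_cs([("a", "b", -0.9, 1e-4, 1e-3, 50, 40)])
        assert categorize_pairs(cs, scheme4()) == {}

    def test_inside_top_interval(self):
        cs = make_cs([("a", "b", 0.7, 1e-4, 1e-3, 50, 40)])
        assert categorize_pairs(cs, scheme4()) == {frozenset(("a", "b")): 4}

    def test_insignificant_pairs_skipped(self):
        cs = make_cs([("a", "b", 0.7, 0.5, 0.9, 50, 40)])
        assert categorize_pairs(cs, scheme4()) == {}


class TestConsensus:
    def test_majority_rule(self):
        pair = frozenset(("a", "b"))
        per_stratum = [{pair: 4}, {pair: 4}, {pair: 4}, {pair: 2}]
        cooc = [{pair}] * 4
        (rec,) = consensus_interactions(per_stratum, cooc)
        assert rec.category == 4
        assert rec.fraction == pytest.approx(0.75)

    def test_exact_half_is_no_consensus(self):
        pair = frozenset(("a", "b"))
        per_stratum = [{pair: 4}, {pair: 4}, {pair: 2}, {pair: 2}]
        cooc = [{pair}] * 4
        (rec,) = consensus_interactions(per_stratum, cooc)
        assert rec.category is None

    def test_never_co_occurring_pair_excluded(self):
        pair = frozenset(("a", "b"))
        records = consensus_interactions([{pair: 3}], [set()])
        assert records == []

    def test_stratum_order_invariance(self):
        pair = frozenset(("a", "b"))
        per = [{pair: 4}, {pair: 2}, {pair: 4}]
        cooc = [{pair}] * 3
        r1 = consensus_interactions(per, cooc)
        r2 = consensus_interactions(list(reversed(per)), cooc)
        assert r1[0].category == r2[0].category
        assert r1[0].fraction == r2[0].fraction


class TestLiterature:
    def records(self, mapping):
        per = [dict(mapping)]
        cooc = [set(mapping)]
        return consensus_interactions(per, cooc)

    def test_worked_toy(self):
        recs = self.records({frozenset(("A", "B")): 3})
        lit = [("A", "B"), ("A", "C")]
        summary, _ = compare_to_literature(recs, lit, taxa_in_data=("A", "B", "C"))
        assert summary.confirmed == 1
        assert summary.missing == 1
        assert summary.accuracy == pytest.approx(0.5)
        assert summary.confirmed + summary.missing == 2

    def test_empty_literature(self):
        recs = self.records({frozenset(("A", "B")): 3})
        summary, _ = compare_to_literature(recs, [])
        assert np.isnan(summary.accuracy)
        assert summary.proposed == 1

    def test_out_of_data_pair_logged(self):
        recs = self.records({frozenset(("A", "B")): 3})
        with pytest.warns(UserWarning, match="absent"):
            summary, _ = compare_to_literature(
                recs, [("A", "Zeno")], taxa_in_data=("A", "B")
            )
        assert summary.out_of_data == 1

    def test_competitive_counted_separately(self):
        recs = self.records(
            {frozenset(("A", "B")): 1, frozenset(("C", "D")): 4}
        )
        summary, ann = compare_to_literature(
            recs, [], taxa_in_data=("A", "B", "C", "D")
        )
        assert summary.competitive == 1
        statuses = {tuple(sorted(r.pair)): r.literature_status for r in ann}
        assert statuses[("A", "B")] == "competitive"
        assert statuses[("C", "D")] == "proposed"

    def test_rare_excluded(self):
        recs = self.records({frozenset(("A", "B")): 3})
        summary, _ = compare_to_literature(
            recs, [("C", "D")], taxa_in_data=("A", "B", "C", "D"), rare_taxa={"C"}
        )
        assert summary.rare_excluded == 1


class TestSBM:
    def two_block_graph(self):
        g = nx.Graph()
        blockA = [f"a{i}" for i in range(8)]
        blockB = [f"b{i}" for i in range(8)]
        for blk in (blockA, blockB):
            for i in range(8):
                for j in range(i + 1, 8):
                    g.add_edge(blk[i], blk[j])
        return g, blockA, blockB

    def test_fit_recovers_two_blocks(self):
        g, blockA, blockB = self.two_block_graph()
        blocks = fit_sbm(g, n_blocks_range=(1, 2, 3, 4))
        assert len(blocks) == 2
        assert {frozenset(b) for b in blocks} == {frozenset(blockA), frozenset(blockB)}

    def test_uniform_labels_give_one(self):
        g, blockA, blockB = self.two_block_graph()
        labels = {}
        for blk in (blockA, blockB):
            for i, n in enumerate(blk):
                labels[n] = "x" if i % 2 == 0 else "y"
        assert sbm_equitability(g, labels) == pytest.approx(1.0)

    def test_single_label_blocks_give_zero(self):
        g, blockA, blockB = self.two_block_graph()
        labels = {n: ("x" if n in blockA else "y") for n in g.nodes}
        assert sbm_equitability(g, labels) == pytest.approx(0.0)

    def test_three_quarter_mix_closed_form(self):
        g, blockA, blockB = self.two_block_graph()
        labels = {}
        for blk in (blockA, blockB):
            for i, n in enumerate(blk):
                labels[n] = "x" if i < 6 else "y"
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25)) / np.log(2)
        assert sbm_equitability(g, labels) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.8113, abs=1e-4)

    def test_label_renaming_invariance(self):
        g, blockA, blockB = self.two_block_graph()
        labels = {n: ("x" if n in blockA else "y") for n in g.nodes}
        renamed = {n: ("endo" if v == "x" else "nekto") for n, v in labels.items()}
        assert sbm_equitability(g, labels) == pytest.approx(
            sbm_equitability(g, renamed)
        )

    def test_single_label_network_warns_zero(self):
        g, *_ = self.two_block_graph()
        labels = {n: "x" for n in g.nodes}
        with pytest.warns(UserWarning):
            assert sbm_equitability(g, labels) == 0.0


class TestHabitatChisq:
    def cs_with_edges(self, rows):
        return make_cs(
            [(a, b, r, 1e-4, 1e-3, 50, 40) for a, b, r in rows]
        )

    def test_no_association_chi2_zero(self):
        # balanced 2x2: 10 in each cell
        rows = []
        habs = {}
        k = 0
        for sel, same in ((True, True), (True, False), (False, True), (False, False)):
            for _ in range(10):
                a, b = f"t{k}", f"u{k}"
                k += 1
                habs[a] = "nektobenthic"
                habs[b] = "nektobenthic" if same else "endo/epibenthic"
                rows.append((a, b, -0.5 if sel else 0.5))
        chi2, p = habitat_chisq(self.cs_with_edges(rows), habs, sign="negative")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_yates_oracle_value(self):
        # table [[20,5],[5,20]] -> chi2 = n(|ad-bc|-n/2)^2 / row/col products
        rows, habs = [], {}
        k = 0
        for sel, same, count in (
            (True, True, 20), (True, False, 5), (False, True, 5), (False, False, 20),
        ):
            for _ in range(count):
                a, b = f"t{k}", f"u{k}"
                k += 1
                habs[a] = "nektobenthic"
                habs[b] = "nektobenthic" if same else "endo/epibenthic"
                rows.append((a, b, -0.5 if sel else 0.5))
        chi2, p = habitat_chisq(self.cs_with_edges(rows), habs, sign="negative")
        n = 50
        oracle = n * (abs(20 * 20 - 5 * 5) - n / 2) ** 2 / (25 * 25 * 25 * 25)
        assert chi2 == pytest.approx(oracle, abs=1e-9)
        assert chi2 == pytest.approx(15.68, abs=0.01)
        assert p == pytest.approx(7.5e-5, rel=0.05)

    def test_no_selected_sign_rejected(self):
        cs = self.cs_with_edges([("a", "b", 0.5)])
        with pytest.raises(ValueError):
            habitat_chisq(cs, {"a": "nektobenthic", "b": "nektobenthic"}, sign="negative")
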