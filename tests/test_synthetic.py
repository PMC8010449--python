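"""Synthetic assemblage generator: copula correlations, thinning, traits."""

import numpy as np
import pytest

from cambronet.biofacies import anosim
from cambronet.synthetic import (
    PlantedEdge,
    apply_preservation,
    community_edge_spec,
    default_edge_spec,
    generate_assemblage,
    trait_preservation_map,
)


class TestGenerate:
    def test_no_edges_sample_correlations_near_zero(self):
        asm = generate_assemblage(n_taxa=10, n_levels=800, edge_spec=[], seed=2)
        x = np.log1p(asm.abundance.counts.astype(float))
        corr = np.corrcoef(x, rowvar=False)
        off = corr[np.triu_indices(10, 1)]
        assert np.abs(off).max() < 0.15

    def test_planted_rho_09_recovered_within_01(self):
        asm = generate_assemblage(
            n_taxa=10, n_levels=500,
            edge_spec=[PlantedEdge(0, 1, "specialist", 0.9)], seed=1,
        )
        x = np.log1p(asm.abundance.counts.astype(float))
        r = np.corrcoef(x[:, 0], x[:, 1])[0, 1]
        assert abs(r - 0.9) < 0.1

    def test_two_facies_disjoint_taxa_anosim_near_one(self):
        # two facies with strong turnover approximate disjoint dominant taxa
        asm = generate_assemblage(
            n_taxa=16, n_levels=40, boundaries=(20,), edge_spec=[],
            facies_turnover=0.6, seed=3,
        )
        labels = np.array([0] * 20 + [1] * 20)
        R, p = anosim(asm.abundance, labels, n_perm=99, seed=0)
        assert R > 0.8
        assert p <= 0.01

    def test_non_psd_edge_spec_rejected(self):
        edges = [
            PlantedEdge(0, 1, "specialist", 0.9),
            PlantedEdge(1, 2, "specialist", 0.9),
            PlantedEdge(0, 2, "competitive", -0.9),
        ]
        with pytest.raises(ValueError, match="positive semi-definite"):
            generate_assemblage(n_taxa=5, n_levels=50, edge_spec=edges, seed=0)

    def test_deterministic_under_seed(self):
        a = generate_assemblage(n_taxa=12, n_levels=30, seed=9)
        b = generate_assemblage(n_taxa=12, n_levels=30, seed=9)
        assert np.array_equal(a.abundance.counts, b.abundance.counts)

    def test_edge_class_ordering_in_sample_correlations(self):
        # specialist > generalist > 0 > competitive on the log-count scale
        rs = {"specialist": [], "generalist": [], "competitive": []}
        for seed in range(10):
            asm = generate_assemblage(n_taxa=30, n_levels=200, seed=seed)
            x = np.log1p(asm.abundance.counts.astype(float))
            corr = np.corrcoef(x, rowvar=False)
            for e in asm.planted_edges:
                rs[e.kind].append(corr[e.i, e.j])
        assert np.mean(rs["specialist"]) > np.mean(rs["generalist"]) > 0
        assert np.mean(rs["competitive"]) < 0


class TestPreservation:
    def test_perfect_preservation_identity(self, small_assemblage):
        m = small_assemblage.abundance
        thinned = apply_preservation(m, {t: 1.0 for t in m.taxon_names}, seed=0)
        assert np.array_equal(thinned.counts, m.counts)

    def test_binomial_moments(self):
        from cambronet.io import AbundanceMatrix

        m = AbundanceMatrix(("0",), np.array([[1000]]), ("a",))
        thinned = apply_preservation(m, {"a": 0.5}, seed=4)
        sigma = np.sqrt(1000 * 0.25)
        assert abs(int(thinned.counts[0, 0]) - 500) < 3 * sigma

    def test_near_zero_probability_empties_column(self):
        from cambronet.io import AbundanceMatrix

        counts = np.full((20, 1), 100)
        m = AbundanceMatrix(tuple(map(str, range(20))), counts, ("a",))
        thinned = apply_preservation(m, {"a": 1e-6}, seed=0)
        assert thinned.counts.sum() == 0

    def test_thinning_never_increases_cells(self, small_assemblage):
        m = small_assemblage.abundance
        probs = {t: 0.3 for t in m.taxon_names}
        thinned = apply_preservation(m, probs, seed=11)
        assert np.all(thinned.counts <= m.counts)

    def test_expected_thinned_matrix(self):
        from cambronet.io import AbundanceMatrix

        counts = np.array([[40, 80], [120, 10]])
        m = AbundanceMatrix(("0", "1"), counts, ("a", "b"))
        p = np.array([0.25, 0.8])
        acc = np.zeros_like(counts, dtype=float)
        for seed in range(250):
            acc += apply_preservation(m, p, seed=seed).counts
        np.testing.assert_allclose(acc / 250, counts * p, rtol=0.12)

    def test_invalid_probability_rejected(self, small_assemblage):
        m = small_assemblage.abundance
        with pytest.raises(ValueError):
            apply_preservation(m, {t: 0.0 for t in m.taxon_names}, seed=0)


class TestTraitMap:
    def test_body_type_map(self, small_assemblage):
        probs = trait_preservation_map(
            small_assemblage.traits, "body_type",
            {"hard": 1.0, "intermediate": 0.5, "soft": 0.1},
        )
        table = small_assemblage.traits.table
        for taxon, p in probs.items():
            expected = {"hard": 1.0, "intermediate": 0.5, "soft": 0.1}[
                table.at[taxon, "body_type"]
            ]
            assert p == expected

    def test_uniform_map_all_ones(self, small_assemblage):
        cats = set(small_assemblage.traits.table["habitat"])
        probs = trait_preservation_map(
            small_assemblage.traits, "habitat", {c: 1.0 for c in cats}
        )
        assert set(probs.values()) == {1.0}

    def test_missing_category_rejected(self, small_assemblage):
        with pytest.raises(KeyError):
            trait_preservation_map(small_assemblage.traits, "body_type", {"hard": 1.0})


def test_edge_specs_are_valid_and_disjoint():
    edges = default_edge_spec(30, seed=1)
    taxa = [t for e in edges for t in (e.i, e.j)]
    assert len(taxa) == len(set(taxa))  # disjoint pairs
    guild = community_edge_spec(30, seed=1)
    kinds = {e.kind for e in guild}
    assert kinds == {"specialist", "generalist", "competitive"}
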