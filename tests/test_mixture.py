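"""1-D Gaussian mixtures, Bhattacharyya similarity, spectral categorization."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from cambronet.mixture import (
    CategoryScheme,
    GaussianComponent,
    category_composition,
    cluster_components,
    fit_gmm_1d,
    gaussian_similarity,
)


class TestGMM:
    def test_single_component_recovery(self):
        rng = np.random.default_rng(0)
        fit = fit_gmm_1d(rng.normal(0, 0.1, 500), seed=0)
        assert fit.k == 1
        assert abs(fit.means()[0]) < 0.02

    def test_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-0.5, 0.05, 250), rng.normal(0.6, 0.05, 250)])
        fit = fit_gmm_1d(x, seed=0)
        assert fit.k == 2
        np.testing.assert_allclose(sorted(fit.means()), [-0.5, 0.6], atol=0.05)

    def test_selected_k_minimizes_bic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.2, 0.1, 300)
        fit = fit_gmm_1d(x, seed=0)
        assert fit.bic_by_k[fit.k] == min(fit.bic_by_k.values())

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(-0.4, 0.1, 100), rng.normal(0.5, 0.1, 100)])
        fit = fit_gmm_1d(x, seed=0)
        assert sum(c.weight for c in fit.components) == pytest.approx(1.0)

    def test_k_range_truncated_for_few_values(self):
        rng = np.random.default_rng(4)
        with pytest.warns(UserWarning, match="truncated"):
            fit = fit_gmm_1d(rng.normal(0, 1, 10), k_candidates=(1, 6), seed=0)
        assert fit.k <= 5

    def test_em_monotone_log_likelihood(self):
        # stepping EM one iteration at a time never decreases the bound
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        x = np.concatenate(
            [rng.normal(-0.5, 0.1, 200), rng.normal(0.4, 0.1, 200)]
        ).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=2, max_iter=1, warm_start=True, init_params="k-means++",
            reg_covar=1e-6, random_state=0, tol=0.0,
        )
        lls = []
        for _ in range(25):
            gm.fit(x)
            lls.append(gm.score(x))
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestSimilarity:
    def test_identical_components_similarity_one(self):
        a = GaussianComponent(0.2, 0.1, 1.0)
        assert gaussian_similarity(a, a) == pytest.approx(1.0)

    def test_closed_form_against_numerical_integration(self):
        a = GaussianComponent(0.0, 1.0, 1.0)
        b = GaussianComponent(2.0, 1.0, 1.0)
        bc_int, _ = quad(
            lambda x: np.sqrt(norm.pdf(x, 0, 1) * norm.pdf(x, 2, 1)), -15, 15
        )
        assert abs(gaussian_similarity(a, b) - bc_int) < 1e-6
        c = GaussianComponent(-0.3, 0.4, 1.0)
        d = GaussianComponent(0.5, 0.15, 1.0)
        bc_int2, _ = quad(
            lambda x: np.sqrt(norm.pdf(x, -0.3, 0.4) * norm.pdf(x, 0.5, 0.15)), -15, 15
        )
        assert abs(gaussian_similarity(c, d) - bc_int2) < 1e-6

    def test_vanishes_for_distant_means(self):
        a = GaussianComponent(0.0, 0.1, 1.0)
        b = GaussianComponent(50.0, 0.1, 1.0)
        assert gaussian_similarity(a, b) < 1e-12

    def test_symmetry(self):
        a = GaussianComponent(0.1, 0.2, 1.0)
        b = GaussianComponent(-0.4, 0.05, 1.0)
        assert gaussian_similarity(a, b) == pytest.approx(gaussian_similarity(b, a))


class TestClustering:
    def test_two_well_separated_clusters(self):
        comps = [GaussianComponent(m, 0.03, 0.25) for m in (-0.3, -0.31, 0.5, 0.52)]
        scheme = cluster_components(comps, seed=0)
        assert scheme.n_categories == 2
        assert scheme.intervals[0] == pytest.approx((-0.31, -0.3))
        assert scheme.intervals[1] == pytest.approx((0.5, 0.52))

    def test_identical_components_one_cluster(self):
        comps = [GaussianComponent(0.1, 0.05, 0.25)] * 4
        assert cluster_components(comps, seed=0).n_categories == 1

    def test_four_mode_recovery(self):
        rng = np.random.default_rng(1)
        comps = [
            GaussianComponent(m + rng.normal(0, 0.02), 0.08 + rng.uniform(0, 0.04), 0.25)
            for _ in range(4)
            for m in (-0.45, 0.0, 0.35, 0.7)
        ]
        scheme = cluster_components(comps, seed=0)
        assert scheme.n_categories == 4

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        comps = [
            GaussianComponent(m + rng.normal(0, 0.02), 0.05, 0.25)
            for _ in range(3)
            for m in (-0.4, 0.3)
        ]
        s1 = cluster_components(comps, seed=0)
        s2 = cluster_components(list(reversed(comps)), seed=0)
        assert s1.intervals == s2.intervals

    def test_translation_shifts_intervals(self):
        comps = [GaussianComponent(m, 0.05, 0.25) for m in (-0.3, -0.28, 0.4, 0.42)]
        s1 = cluster_components(comps, seed=0)
        shifted = [GaussianComponent(c.mean + 0.1, c.sd, c.weight) for c in comps]
        s2 = cluster_components(shifted, seed=0)
        for (a1, b1), (a2, b2) in zip(s1.intervals, s2.intervals):
            assert a2 == pytest.approx(a1 + 0.1)
            assert b2 == pytest.approx(b1 + 0.1)

    def test_categories_ordered_by_mean(self):
        comps = [GaussianComponent(m, 0.05, 0.25) for m in (0.5, -0.3, 0.52, -0.31)]
        scheme = cluster_components(comps, seed=0)
        lows = [iv[0] for iv in scheme.intervals]
        assert lows == sorted(lows)


class TestComposition:
    def make_df(self, rows):
        import pandas as pd

        return pd.DataFrame(rows, columns=["species_a", "species_b", "label", "r"])

    def test_all_inside_one_interval(self):
        scheme = CategoryScheme(
            clusters=((GaussianComponent(0.0, 0.1, 1.0),),),
            intervals=((-0.5, 0.5),),
            assignment_intervals=((-0.5, 0.5),),
        )
        df = self.make_df(
            [("a", "b", "specialist", 0.1), ("c", "d", "competition", -0.2)]
        )
        res = category_composition(df, scheme)
        assert res.in_interval_fraction == 1.0
        assert sum(res.per_category[1].values()) == pytest.approx(1.0)

    def test_gap_values_uncategorized(self):
        scheme = CategoryScheme(
            clusters=((GaussianComponent(-0.4, 0.02, 0.5),),
                      (GaussianComponent(0.4, 0.02, 0.5),)),
            intervals=((-0.45, -0.35), (0.35, 0.45)),
            assignment_intervals=((-0.45, -0.35), (0.35, 0.45)),
        )
        df = self.make_df([("a", "b", "generalist", 0.0)])
        res = category_composition(df, scheme)
        assert res.in_interval_fraction == 0.0

    def test_none_label_ignored(self):
        scheme = CategoryScheme(
            clusters=((GaussianComponent(0.0, 0.1, 1.0),),),
            intervals=((-1, 1),),
            assignment_intervals=((-1, 1),),
        )
        df = self.make_df(
            [("a", "b", "none", 0.1), ("c", "d", "specialist", 0.2)]
        )
        res = category_composition(df, scheme)
        assert res.per_category[1] == {"specialist": 1.0}
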