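"""Reproducible validation studies for the full inference pipeline.

Each study generates its own synthetic inputs (assemblages with planted
structure, agent-based-model communities with known interactions), runs the
corresponding pipeline stage, and measures how well the known truth is
recovered.  The studies dimension every experiment at desk scale: a few
tens of replicate assemblages or a few hundred simulations, sized so the
whole battery runs on one CPU in minutes.  All randomness is controlled by
the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import replace
from functools import partial

import numpy as np
import pandas as pd

from .abm import ABMConfig, abm_correlations, run_abm, run_abm_corpus
from .bias import (
    BiasCalibration,
    bias_coefficient,
    calibrate_bias,
    default_net_builder,
)
from .biofacies import detect_subassemblages
from .corrnet import build_network, corrected_correlations
from .interactions import (
    categorize_pairs,
    compare_to_literature,
    consensus_interactions,
    habitat_chisq,
    sbm_equitability,
)
from .io import AbundanceMatrix, make_windows
from .mixture import (
    category_composition,
    cluster_components,
    fit_gmm_1d,
    gaussian_similarity,
)
from .synthetic import (
    PlantedEdge,
    apply_preservation,
    community_edge_spec,
    default_edge_spec,
    generate_assemblage,
)

__all__ = [
    "edge_detection_power",
    "null_edge_calibration",
    "boundary_recovery",
    "gmm_recovery",
    "abm_class_correlations",
    "preference_study",
    "bias_calibration_study",
    "bias_null_and_clique",
    "bias_region_flagging",
    "abm_category_study",
    "consensus_accuracy_study",
    "habitat_control_study",
]

# the trophically dominated configuration used for the prey-preference
# experiment: smaller environmental forcing so predation, not shared
# environment, carries the correlation signal
PREFERENCE_CONFIG = dict(
    grid_side=20, initial_prey=25, initial_predators=12,
    env_sigma=0.08, env_theta=0.01, steps=600, burn_in=150,
)

# guild structure used by the categorization / consensus studies; the class
# correlations sit on the scale of the ABM's emergent correlations
GUILD_RHO = {"specialist": 0.65, "generalist": 0.35, "competitive": -0.4}


def edge_detection_power(n_seeds: int = 60, seed: int = 0, alpha: float = 0.05):
    """Power to detect a planted rho=0.9 pair at n_levels=200.

    Returns ``(power, false_edge_rate)``: the fraction of replicates where
    the planted edge is recovered at the given FDR level, and the mean
    fraction of null pairs spuriously connected.
    """
    hits = 0
    false_rates = []
    for k in range(n_seeds):
        asm = generate_assemblage(
            n_taxa=15, n_levels=200,
            edge_spec=[PlantedEdge(0, 1, "specialist", 0.9)], seed=seed + k,
        )
        cs = corrected_correlations(asm.abundance)
        g = build_network(cs, alpha=alpha)
        hits += g.has_edge("taxon_00", "taxon_01")
        n_null = len(cs.pairs) - 1
        false_edges = g.number_of_edges() - g.has_edge("taxon_00", "taxon_01")
        false_rates.append(false_edges / n_null)
    return hits / n_seeds, float(np.mean(false_rates))


def null_edge_calibration(n_seeds: int = 20, seed: int = 0):
    """Type-I calibration: fraction of independent pairs with p < 0.05."""
    rates = []
    for k in range(n_seeds):
        asm = generate_assemblage(n_taxa=15, n_levels=500, edge_spec=[], seed=seed + k)
        cs = corrected_correlations(asm.abundance)
        rates.append((cs.pairs.p < 0.05).mean())
    return float(np.mean(rates))


def boundary_recovery(n_seeds: int = 50, seed: int = 0, n_perm: int = 199):
    """SHE + ANOSIM consensus recovery of one planted facies boundary.

    Returns the fraction of replicates with a boundary within +/-3 levels
    of the planted one (level 30 of 60).
    """
    hits = 0
    for k in range(n_seeds):
        asm = generate_assemblage(
            n_taxa=20, n_levels=60, boundaries=(30,), seed=seed + k
        )
        part = detect_subassemblages(asm.abundance, n_perm=n_perm, seed=seed + k)
        hits += any(abs(b - 30) <= 3 for b in part.boundaries)
    return hits / n_seeds


def gmm_recovery(seed: int = 0):
    """K and mean recovery for a two-component mixture of 500 draws."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.normal(-0.5, 0.05, 250), rng.normal(0.6, 0.05, 250)])
    fit = fit_gmm_1d(x, seed=seed)
    means = np.sort(fit.means())
    err = float(np.max(np.abs(means - np.array([-0.5, 0.6])))) if fit.k == 2 else float("inf")
    return fit.k, err


def abm_class_correlations(n_runs: int = 60, seed: int = 0) -> pd.DataFrame:
    """Pooled labelled abundance correlations from default ABM communities."""
    dfs = []
    for k in range(n_runs):
        df = abm_correlations(run_abm(ABMConfig(seed=seed + k)))
        df["run"] = k
        dfs.append(df)
    return pd.concat(dfs, ignore_index=True)


def preference_study(n_seeds: int = 100, seed: int = 0):
    """Variant-2 contrast: one generalist with preferences (0.9, 0.1).

    Returns mean correlations ``(hi_weighted, lo_weighted, lo_unweighted)``
    between the predator and its high/low-preference prey under the
    weighted diet and the low-preference prey under the unweighted diet.
    """
    diet = {k: (k % 17,) for k in range(4)}
    diet[4] = (10, 11)
    diet[5] = (12, 13, 14, 15, 16)
    diet[6] = (5, 6, 7)
    diet[7] = (8, 9)
    prefs = {4: {10: 0.9, 11: 0.1}}
    hw, lw, lu = [], [], []

    def corr(df, prey, pred):
        m = df[(df.species_a == prey) & (df.species_b == pred)]
        return float(m.r.iloc[0]) if len(m) else np.nan

    for k in range(n_seeds):
        rw = abm_correlations(
            run_abm(ABMConfig(seed=seed + k, diet=diet, preferences=prefs,
                              **PREFERENCE_CONFIG))
        )
        ru = abm_correlations(
            run_abm(ABMConfig(seed=seed + k, diet=diet, **PREFERENCE_CONFIG))
        )
        hw.append(corr(rw, "prey_10", "pred_04"))
        lw.append(corr(rw, "prey_11", "pred_04"))
        lu.append(corr(ru, "prey_11", "pred_04"))
    return float(np.nanmean(hw)), float(np.nanmean(lw)), float(np.nanmean(lu))


def bias_calibration_study(
    seed: int = 0, n_runs: int = 35, n_degradations: int = 3, n_perm: int = 40
) -> BiasCalibration:
    """Calibrate the bias coefficient on a desk-scale ABM corpus."""
    corpus = run_abm_corpus(
        n_runs=n_runs, n_degradations_per_run=n_degradations, seed=seed
    )
    return calibrate_bias(
        corpus,
        net_builder=partial(default_net_builder, alpha=0.2, min_occupancy=0.25),
        n_perm=n_perm,
        seed=seed,
    )


def bias_null_and_clique(cal: BiasCalibration, seed: int = 0, n_null: int = 40):
    """Coefficient under a shuffled-label null and a category-clique graph.

    Returns ``(null_median, clique_coefficient)``.
    """
    import networkx as nx

    asm = generate_assemblage(
        n_taxa=30, n_levels=60,
        edge_spec=default_edge_spec(
            30, n_specialist=15, n_generalist=0, n_competitive=0,
            rho={"specialist": 0.9}, seed=seed,
        ),
        seed=seed,
    )
    g = build_network(corrected_correlations(asm.abundance, min_occupancy=0.25), alpha=0.2)
    g.add_nodes_from(asm.abundance.taxon_names)
    labels = asm.traits.labels("body_type", asm.abundance.taxon_names)
    rng = np.random.default_rng(seed)
    vals = list(labels.values())
    nulls = []
    for k in range(n_null):
        rng.shuffle(vals)
        nulls.append(
            bias_coefficient(g, dict(zip(labels, vals)), cal, n_perm=40, seed=seed + k)
        )
    clique = nx.Graph()
    nodes = [f"n{i}" for i in range(15)]
    clique.add_nodes_from(nodes)
    clabels = {
        n: ("hard" if i < 7 else "soft" if i < 12 else "intermediate")
        for i, n in enumerate(nodes)
    }
    for i in range(7):
        for j in range(i + 1, 7):
            clique.add_edge(f"n{i}", f"n{j}")
    clique_coef = bias_coefficient(clique, clabels, cal, n_perm=40, seed=seed)
    return float(np.median(nulls)), float(clique_coef)


def bias_region_flagging(
    cal: BiasCalibration, n_seeds: int = 25, seed: int = 0, threshold: float = 0.5
):
    """Planted-bias recovery: a basal trait-thinned region must be trimmed.

    Each replicate plants a strongly structured assemblage of 240 levels,
    applies severe soft-taxon thinning to the lower half (the analogue of a
    poorly preserving basal interval), and splits the section into four
    60-level windows.  Sensitivity is the fraction of replicates whose
    thinned region (either of its two windows) is flagged at the
    coefficient threshold; specificity is the fraction of clean windows not
    flagged.
    """
    region_hits = 0
    clean_flags = 0
    n_clean = 0
    pm = {"soft": 0.005, "intermediate": 0.6, "hard": 1.0}
    for k in range(n_seeds):
        es = default_edge_spec(
            30, n_specialist=15, n_generalist=0, n_competitive=0,
            rho={"specialist": 0.9}, seed=seed + k,
        )
        asm = generate_assemblage(n_taxa=30, n_levels=240, edge_spec=es, seed=seed + k)
        m = asm.abundance
        labels = asm.traits.labels("body_type", m.taxon_names)
        thinned = apply_preservation(
            m, {t: pm[labels[t]] for t in m.taxon_names}, seed=seed + k + 1000
        )
        counts = m.counts.copy()
        counts[:120] = thinned.counts[:120]
        m2 = AbundanceMatrix(m.level_ids, counts, m.taxon_names)
        flags = []
        for w in make_windows(m2, width=60, step=60):
            sub = m2.select_levels(w.level_indices)
            g = build_network(
                corrected_correlations(sub, min_occupancy=0.25), alpha=0.2
            )
            g.add_nodes_from(m.taxon_names)
            coef = bias_coefficient(g, labels, cal, n_perm=40, seed=seed + k)
            flags.append(coef > threshold)
        region_hits += any(flags[:2])
        clean_flags += sum(flags[2:])
        n_clean += 2
    return region_hits / n_seeds, 1.0 - clean_flags / n_clean


def abm_category_study(abm_df: pd.DataFrame, seed: int = 0, n_batches: int = 4):
    """Interaction categories from the ABM correlation distribution.

    Runs are split into batches (the analogue of strata); the pooled
    correlation distribution of each batch is decomposed into Gaussians and
    the components are clustered into categories.  Returns
    ``(scheme, CompositionResult)``.
    """
    comps = []
    runs = sorted(abm_df["run"].unique())
    for b in range(n_batches):
        batch_runs = [r for i, r in enumerate(runs) if i % n_batches == b]
        sub = abm_df[abm_df.run.isin(batch_runs) & (abm_df.label != "none")]
        fit = fit_gmm_1d(sub.r.to_numpy(), seed=seed + b, stratum=str(b))
        comps.extend(fit.components)
    scheme = cluster_components(comps, seed=seed)
    return scheme, category_composition(abm_df, scheme)


def consensus_accuracy_study(seed: int = 0):
    """End-to-end consensus interactions vs the planted positive pairs.

    A guild-structured assemblage (four facies) is analysed per stratum:
    the category scheme is built from Gaussian decompositions of the
    stratum and aligned running-frame correlation distributions (marginal
    scale), significant pairs are categorized per stratum, and
    majority-rule consensus interactions are compared against the planted
    positive (trophic-like) pairs as the literature stand-in.
    """
    es = community_edge_spec(
        30, specialist_block=8, generalist_block=8, competitive_block=8,
        rho=GUILD_RHO, seed=seed,
    )
    asm = generate_assemblage(
        n_taxa=30, n_levels=640, boundaries=(160, 320, 480), edge_spec=es,
        seed=seed, facies_turnover=0.2,
    )
    names = asm.abundance.taxon_names
    strata = [(0, 160), (160, 320), (320, 480), (480, 640)]
    css, comps = [], []
    fit_id = 0
    for a, b in strata:
        cs = corrected_correlations(
            asm.abundance.select_levels(range(a, b)),
            min_occupancy=0.25, estimator="pearson",
        )
        css.append(cs)
        for w0, w1 in [(a, b), (a, a + 80), (a + 40, a + 120), (a + 80, b)]:
            cw = cs if (w0, w1) == (a, b) else corrected_correlations(
                asm.abundance.select_levels(range(w0, w1)),
                min_occupancy=0.25, estimator="pearson",
            )
            fit = fit_gmm_1d(cw.pairs.r.to_numpy(), seed=fit_id, stratum=f"{w0}-{w1}")
            fit_id += 1
            # broad components describe the unresolved null background, not
            # an interaction class
            comps.extend(c for c in fit.components if c.sd <= 0.2)
    scheme = cluster_components(comps, seed=seed)
    per_stratum, cooc = [], []
    for cs in css:
        per_stratum.append(categorize_pairs(cs, scheme, alpha=0.05))
        cooc.append(
            {
                frozenset((r.taxon_a, r.taxon_b))
                for r in cs.pairs.itertuples()
                if r.co_occurrence >= 4
            }
        )
    records = consensus_interactions(per_stratum, cooc)
    rare = set(names) - set().union(*[set(cs.taxa) for cs in css])
    literature = {
        frozenset((names[e.i], names[e.j])) for e in asm.planted_edges if e.rho > 0
    }
    summary, annotated = compare_to_literature(
        records, literature, taxa_in_data=names, rare_taxa=rare
    )
    return summary, scheme, annotated


def habitat_control_study(n_seeds: int = 10, seed: int = 0):
    """Habitat null controls on assemblages with habitat-independent edges.

    Returns ``(mean_negative_p, equitability, null_band)`` where the chi
    squared p-values are pooled over windows and the equitability null band
    is the 5-95% range under habitat-label shuffling.
    """
    ps = []
    for k in range(n_seeds):
        asm = generate_assemblage(n_taxa=24, n_levels=120, seed=seed + k)
        habs = asm.traits.labels("habitat", asm.abundance.taxon_names)
        for w0 in range(0, 61, 30):
            cs = corrected_correlations(
                asm.abundance.select_levels(range(w0, w0 + 60)), min_occupancy=0.25
            )
            try:
                _, p = habitat_chisq(cs, habs, sign="negative")
                ps.append(p)
            except ValueError:
                continue
    asm = generate_assemblage(n_taxa=24, n_levels=200, seed=seed + 1)
    cs = corrected_correlations(asm.abundance, min_occupancy=0.25)
    g = build_network(cs, alpha=0.2)
    habs = asm.traits.labels("habitat", g.nodes)
    eq = sbm_equitability(g, habs)
    rng = np.random.default_rng(seed)
    vals = list(habs.values())
    nulls = []
    for _ in range(30):
        rng.shuffle(vals)
        nulls.append(sbm_equitability(g, dict(zip(habs, vals))))
    band = (float(np.quantile(nulls, 0.05)), float(np.quantile(nulls, 0.95)))
    return float(np.mean(ps)), float(eq), band
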