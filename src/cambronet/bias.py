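"""Preservation-bias quantification via ERGM attribute effects.

Differential fossil preservation (soft vs hard bodies, small vs large
taxa, different habitats) distorts correlation networks in ways that align
with the trait categories.  This module measures that alignment with an
exponential random graph model (ERGM) fitted by maximum pseudo-likelihood
(a logistic regression over dyads with category-homophily and
category-activity terms) and converts it into a bias coefficient on [0, 1]
by calibration against the agent-based-model corpus, where each degraded
network can be compared with its perfect-preservation base case through
the normalized Hamming distance.

The calibration fits an isotonic (monotone non-decreasing) regression of
the edge-normalized Hamming alteration between each degraded network and
its perfect-preservation base case on the permutation-standardized ERGM
attribute effect of the degraded network.  The bias coefficient of a
fossil window is its calibrated expected alteration, rescaled to the
calibration's dynamic range (0 = the alteration expected with no
differential bias, 1 = the most severe differential bias in the corpus).
A coefficient above 0.5 indicates alteration beyond half that range, the
threshold used to exclude strata from downstream interaction inference.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .corrnet import build_network, corrected_correlations
from .io import AbundanceMatrix, StratWindow, TaxonTraits

__all__ = [
    "ERGMFit",
    "BiasCalibration",
    "BiasSeries",
    "hamming_distance",
    "edge_normalized_alteration",
    "attribute_effect",
    "fit_ergm",
    "calibrate_bias",
    "bias_coefficient",
    "bias_series_and_trim",
    "default_net_builder",
]

FACTORS = ("body_type", "size_class", "habitat")


def hamming_distance(g1: nx.Graph, g2: nx.Graph) -> float:
    """Fraction of unordered node pairs whose edge status differs."""
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    n = g1.number_of_nodes()
    if n < 2:
        return 0.0
    e1 = {frozenset(e) for e in g1.edges}
    e2 = {frozenset(e) for e in g2.edges}
    return len(e1 ^ e2) / (n * (n - 1) / 2)


@dataclass(frozen=True)
class ERGMFit:
    coefficients: dict  # term name -> theta
    std_errors: dict
    null_deviance: float
    deviance: float
    n_dyads: int
    degenerate: bool = False

    @property
    def delta(self) -> float:
        """Attribute-block deviance improvement per dyad."""
        if self.degenerate or self.n_dyads == 0:
            return 0.0
        return max(self.null_deviance - self.deviance, 0.0) / self.n_dyads


def _logistic_irls(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6, max_iter: int = 100):
    """Ridge-stabilized IRLS for logistic regression; returns (beta, cov, deviance)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        xtw = X.T * w
        h = xtw @ X + ridge * np.eye(p)
        beta_new = np.linalg.solve(h, xtw @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-8:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-12
    dev = -2.0 * np.sum(y * np.log(mu + eps) + (1 - y) * np.log(1 - mu + eps))
    w = np.maximum(mu * (1 - mu), 1e-10)
    cov = np.linalg.inv((X.T * w) @ X + ridge * np.eye(p))
    return beta, cov, float(dev)


def fit_ergm(g: nx.Graph, labels: dict) -> ERGMFit:
    """Maximum pseudo-likelihood ERGM with category attribute terms.

    Dyad predictors: an edges (intercept) term; per category c a homophily
    indicator (both endpoints in c) and an activity count (number of
    endpoints in c, with the last category dropped for identifiability).
    ``labels`` maps every node to its category.  Complete and empty graphs
    are degenerate: the fit is flagged and Delta is 0.
    """
    nodes = sorted(g.nodes)
    if len(nodes) < 5:
        raise ValueError("ERGM fit needs at least 5 nodes")
    missing = [v for v in nodes if v not in labels]
    if missing:
        raise KeyError(f"nodes without category labels: {missing}")
    cats = sorted({labels[v] for v in nodes})
    dyads = list(itertools.combinations(nodes, 2))
    y = np.array([1.0 if g.has_edge(a, b) else 0.0 for a, b in dyads])
    n_dyads = len(dyads)
    if y.sum() == 0 or y.sum() == n_dyads:
        return ERGMFit(
            coefficients={"edges": float("nan")},
            std_errors={},
            null_deviance=0.0,
            deviance=0.0,
            n_dyads=n_dyads,
            degenerate=True,
        )
    terms = ["edges"]
    cols = [np.ones(n_dyads)]
    for c in cats:
        cols.append(np.array([float(labels[a] == c and labels[b] == c) for a, b in dyads]))
        terms.append(f"match.{c}")
    for c in cats[:-1]:
        cols.append(
            np.array([float(labels[a] == c) + float(labels[b] == c) for a, b in dyads])
        )
        terms.append(f"activity.{c}")
    X = np.column_stack(cols)
    beta, cov, dev = _logistic_irls(X, y)
    _, _, dev0 = _logistic_irls(np.ones((n_dyads, 1)), y)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return ERGMFit(
        coefficients=dict(zip(terms, beta.tolist())),
        std_errors=dict(zip(terms, se.tolist())),
        null_deviance=dev0,
        deviance=dev,
        n_dyads=n_dyads,
    )


def attribute_effect(g: nx.Graph, labels: dict, n_perm: int = 20, seed: int = 0) -> float:
    """Permutation-standardized ERGM attribute effect of a network.

    The raw deviance improvement Delta depends strongly on network size and
    density (more dyads and more edges inflate it), so it does not transfer
    between the calibration corpus and fossil windows.  Standardizing
    against the label-permutation null of the *same* network conditions
    that out: the returned statistic is
    (Delta_obs - median(Delta_perm)) / IQR(Delta_perm), floored at 0.
    """
    fit = fit_ergm(g, labels)
    if fit.degenerate:
        return 0.0
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    values = [labels[v] for v in nodes]
    null = []
    for _ in range(n_perm):
        perm = list(values)
        rng.shuffle(perm)
        null.append(fit_ergm(g, dict(zip(nodes, perm))).delta)
    null = np.asarray(null)
    spread = np.quantile(null, 0.75) - np.quantile(null, 0.25)
    # guard against degenerate nulls on very sparse networks: fall back to
    # the null's own scale, then to the dyad-count resolution of Delta
    spread = max(spread, np.std(null), np.median(null) * 0.1, 1.0 / fit.n_dyads)
    return float(max((fit.delta - np.median(null)) / spread, 0.0))


def edge_normalized_alteration(g1: nx.Graph, g2: nx.Graph) -> float:
    """Structural alteration |E1 xor E2| / (|E1| + |E2|) in [0, 1].

    The dyad-normalized Hamming distance of sparse networks is compressed
    toward 0 (two completely unrelated sparse networks differ on only a few
    percent of dyads), so the calibration uses this edge-normalized variant:
    0 for identical edge sets, 1 for disjoint ones.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same node set")
    e1 = {frozenset(e) for e in g1.edges}
    e2 = {frozenset(e) for e in g2.edges}
    denom = len(e1) + len(e2)
    return len(e1 ^ e2) / denom if denom else 0.0


@dataclass(frozen=True)
class BiasCalibration:
    """Monotone map from the standardized ERGM attribute effect to expected
    network alteration (edge-normalized Hamming distance to the perfectly
    preserved case)."""

    effect_grid: np.ndarray  # sorted observed standardized effects
    alt_fitted: np.ndarray  # isotonic fit of alteration at effect_grid
    floor: float  # fitted alteration at zero effect (label-independent churn)
    ceil: float  # fitted alteration at the largest observed effect
    flat: bool = False

    def expected_alteration(self, effect: float) -> float:
        """Isotonic lookup with linear extrapolation beyond the fitted range."""
        d = float(effect)
        x, yv = self.effect_grid, self.alt_fitted
        if self.flat or len(x) == 0:
            return float(yv[0]) if len(yv) else 0.0
        if d <= x[0]:
            return float(yv[0])
        if d > x[-1]:
            span = x[-1] - x[0]
            slope = (yv[-1] - yv[0]) / span if span > 0 else 0.0
            return float(min(yv[-1] + slope * (d - x[-1]), 1.0))
        return float(np.interp(d, x, yv))

    def coefficient(self, effect: float) -> float:
        """Attribute-aligned alteration as a fraction of the calibration's
        dynamic range (floor = no differential bias, ceil = the most severe
        differential bias in the corpus), clipped to [0, 1]."""
        denom = self.ceil - self.floor
        if denom <= 0:
            return 0.0
        return float(np.clip((self.expected_alteration(effect) - self.floor) / denom, 0.0, 1.0))


def default_net_builder(census: np.ndarray, alpha: float = 0.05,
                        min_occupancy: float = 0.1, bin_steps: int = 10) -> nx.Graph:
    """Correlation network from an abundance time series (steps x species).

    The census is summed into blocks of ``bin_steps`` consecutive steps
    before correlation, mirroring the temporal averaging of stratigraphic
    levels (each fossil level accumulates many generations); this also
    keeps the sample size in the regime of the fossil analysis, where only
    strong correlations are significant.  All species are retained as nodes
    even when the occupancy filter drops them from the correlation
    estimate, so degraded and base networks stay on a common node set.
    """
    n_species = census.shape[1]
    names = tuple(f"s{i:03d}" for i in range(n_species))
    if bin_steps > 1:
        n_blocks = census.shape[0] // bin_steps
        census = census[: n_blocks * bin_steps]
        census = census.reshape(n_blocks, bin_steps, n_species).sum(axis=1)
    m = AbundanceMatrix(
        level_ids=tuple(str(t) for t in range(census.shape[0])),
        counts=census,
        taxon_names=names,
    )
    cs = corrected_correlations(m, min_occupancy=min_occupancy)
    g = build_network(cs, alpha=alpha)
    g.add_nodes_from(names)
    return g


def calibrate_bias(corpus, net_builder=default_net_builder, n_perm: int = 20,
                   seed: int = 0) -> BiasCalibration:
    """Fit the attribute-effect -> alteration calibration on an ABM corpus.

    For every (base, degraded) census pair the two networks are built with
    the same builder; the edge-normalized Hamming alteration between them
    and the permutation-standardized ERGM attribute effect of the degraded
    network (labelled by each species' preservation category) enter an
    isotonic regression.
    """
    effects, alts = [], []
    for k, (base_census, degraded_census, categories, cfg) in enumerate(corpus.pairs()):
        g_base = net_builder(base_census)
        g_deg = net_builder(degraded_census)
        alts.append(edge_normalized_alteration(g_base, g_deg))
        labels = {node: f"cat{c}" for node, c in zip(sorted(g_deg.nodes), categories)}
        effects.append(attribute_effect(g_deg, labels, n_perm=n_perm, seed=seed + k))
    if len(effects) < 100:
        raise ValueError("calibration needs at least 100 (base, degraded) pairs")
    effects = np.asarray(effects)
    alts = np.asarray(alts)
    if np.all(alts == 0):
        warnings.warn("no degradation effect observed; calibration is flat at 0")
        return BiasCalibration(
            effect_grid=np.array([0.0]), alt_fitted=np.array([0.0]),
            floor=0.0, ceil=0.0, flat=True,
        )
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(effects, alts)
    order = np.argsort(effects)
    grid = effects[order]
    fitted = np.clip(iso.predict(grid), 0.0, 1.0)
    return BiasCalibration(
        effect_grid=grid,
        alt_fitted=fitted,
        floor=float(fitted[0]),
        ceil=float(fitted[-1]),
    )


def bias_coefficient(g: nx.Graph, labels: dict, cal: BiasCalibration,
                     n_perm: int = 20, seed: int = 0) -> float:
    """Calibrated preservation-bias coefficient of one network in [0, 1]."""
    eff = attribute_effect(g, labels, n_perm=n_perm, seed=seed)
    return cal.coefficient(eff)


@dataclass(frozen=True)
class BiasSeries:
    table: pd.DataFrame  # window_id, factor, coefficient, excluded
    threshold: float

    def excluded_windows(self) -> tuple:
        t = self.table
        flagged = sorted(set(t.loc[t["excluded"], "window_id"]))
        return tuple(flagged)

    def per_factor(self, factor: str) -> pd.Series:
        t = self.table
        return t.loc[t["factor"] == factor].set_index("window_id")["coefficient"]


def bias_series_and_trim(
    windows,
    networks,
    traits: TaxonTraits,
    cal: BiasCalibration,
    threshold: float = 0.5,
    factors=FACTORS,
):
    """Per-window bias coefficients and the trimmed (retained) stratum set.

    A window is excluded when the coefficient of any factor exceeds
    ``threshold``.  Contiguous excluded runs touching the bottom or top of
    the section are reported as end trims (the analogue of excluding
    basal/top intervals whose preservation regime differs from the
    interior).

    Returns ``(BiasSeries, retained_window_ids, trims)`` where ``trims`` is
    a dict with ``"bottom"`` and ``"top"`` lists of window ids.
    """
    if len(windows) != len(networks):
        raise ValueError("one network per window is required")
    rows = []
    excluded = []
    for win, g in zip(windows, networks):
        flags = []
        for factor in factors:
            labels = traits.labels(factor, g.nodes)
            coef = bias_coefficient(g, labels, cal)
            flags.append(coef > threshold)
            rows.append(
                {
                    "window_id": win.window_id,
                    "factor": factor,
                    "coefficient": coef,
                    "excluded": False,
                }
            )
        if any(flags):
            excluded.append(win.window_id)
    table = pd.DataFrame(rows, columns=["window_id", "factor", "coefficient", "excluded"])
    table["excluded"] = table["window_id"].isin(excluded)
    ids = [w.window_id for w in windows]
    excluded_set = set(excluded)
    bottom, top = [], []
    for wid in ids:
        if wid in excluded_set:
            bottom.append(wid)
        else:
            break
    for wid in reversed(ids):
        if wid in excluded_set and wid not in bottom:
            top.append(wid)
        else:
            break
    top.reverse()
    retained = tuple(w for w in ids if w not in excluded_set)
    return (
        BiasSeries(table=table, threshold=threshold),
        retained,
        {"bottom": bottom, "top": top},
    )
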