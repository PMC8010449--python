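"""Statistically corrected pairwise abundance correlations and networks.

The default estimator is a shrinkage-regularized partial correlation:
counts are log(1+x) transformed, the sample correlation matrix is shrunk
toward the identity with an analytically chosen intensity (the
Schafer-Strimmer estimator), and partial correlations are read off the
inverse of the shrunk matrix.  Two-sided p-values come from the Fisher
z-transform and are corrected for multiple testing by Benjamini-Hochberg;
edges of the network are the pairs whose adjusted q-value passes the
significance level.  Plain Pearson and Spearman estimators are available
for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import AbundanceMatrix

__all__ = ["CorrelationSet", "corrected_correlations", "build_network"]


@dataclass(frozen=True)
class CorrelationSet:
    """Pairwise corrected correlations within one stratum set.

    ``pairs`` has one row per unordered taxon pair that passed the occupancy
    filter, with columns taxon_a, taxon_b, r, p, q, n_levels, co_occurrence.
    ``rare_taxa`` lists taxa excluded as numerically rare.
    """

    taxa: tuple
    pairs: pd.DataFrame
    rare_taxa: tuple = ()
    estimator: str = "pcor-shrink"
    shrinkage_lambda: float = float("nan")

    def lookup(self, a, b):
        """Row for the unordered pair (a, b) or None if filtered out."""
        key = frozenset((a, b))
        for row in self.pairs.itertuples(index=False):
            if frozenset((row.taxon_a, row.taxon_b)) == key:
                return row
        return None


def _shrinkage_lambda(x: np.ndarray) -> float:
    """Schafer-Strimmer optimal intensity shrinking correlations toward 0.

    lambda* = sum_ij Var(r_ij) / sum_ij r_ij^2 over off-diagonal entries,
    clipped to [0, 1]; Var(r_ij) is the empirical variance of the centred
    cross-product terms.
    """
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xs.T @ xs) / (n - 1)
    # w_kij = xs_ki * xs_kj ; Var(r_ij) = n/((n-1)^3) * sum_k (w_kij - wbar_ij)^2
    var_sum = 0.0
    r2_sum = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            w = xs[:, i] * xs[:, j]
            var_sum += n / (n - 1.0) ** 3 * np.sum((w - w.mean()) ** 2)
            r2_sum += r[i, j] ** 2
    if r2_sum <= 0:
        return 1.0
    return float(np.clip(var_sum / r2_sum, 0.0, 1.0))


def _partial_from_shrunk(r_shrunk: np.ndarray) -> np.ndarray:
    omega = np.linalg.inv(r_shrunk)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return np.clip(pcor, -1.0, 1.0)


def corrected_correlations(
    m: AbundanceMatrix,
    min_occupancy: float = 0.25,
    shrinkage="auto",
    estimator: str = "pcor-shrink",
) -> CorrelationSet:
    """Corrected pairwise correlations among sufficiently recorded taxa.

    Taxa present in fewer than ``min_occupancy`` of the levels are excluded
    as numerically rare (no statistically robust estimate is possible for
    them) but reported in ``rare_taxa``.

    ``shrinkage`` is ``'auto'`` (analytic intensity) or a float in [0, 1];
    it applies only to the default ``'pcor-shrink'`` estimator.
    """
    if m.n_levels < 4:
        raise ValueError("need at least 4 levels for correlation analysis")
    occupancy = (m.counts > 0).mean(axis=0)
    keep = occupancy >= min_occupancy
    taxa = tuple(t for t, k in zip(m.taxon_names, keep) if k)
    rare = tuple(t for t, k in zip(m.taxon_names, keep) if not k)
    cols = ["taxon_a", "taxon_b", "r", "p", "q", "n_levels", "co_occurrence"]
    if len(taxa) < 2:
        warnings.warn("fewer than 2 taxa pass the occupancy filter; empty set")
        return CorrelationSet(
            taxa=taxa, pairs=pd.DataFrame(columns=cols), rare_taxa=rare,
            estimator=estimator,
        )

    counts = m.counts[:, keep]
    x = np.log1p(counts.astype(float))
    n, p = x.shape
    lam = float("nan")
    if estimator == "pcor-shrink":
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            # constant columns carry no correlation information: jitter-free
            # handling by treating their correlations as exactly zero
            sd = np.where(sd == 0, 1.0, sd)
        xs = (x - x.mean(axis=0)) / sd
        r_sample = (xs.T @ xs) / (n - 1)
        np.fill_diagonal(r_sample, 1.0)
        well_conditioned = n >= p + 13 and np.linalg.matrix_rank(r_sample) == p
        if shrinkage == "auto":
            if well_conditioned:
                # enough levels to invert the sample matrix directly; the
                # unshrunk partial correlation keeps the Fisher z test at
                # its nominal size
                lam = 0.0
            else:
                lam = _shrinkage_lambda(x) if np.all(x.std(axis=0, ddof=1) > 0) else 1.0
        else:
            lam = float(shrinkage)
            if not 0.0 <= lam <= 1.0:
                raise ValueError("shrinkage must lie in [0, 1]")
        r_shrunk = (1.0 - lam) * r_sample
        np.fill_diagonal(r_shrunk, 1.0)
        if lam == 0.0 and np.linalg.matrix_rank(r_shrunk) < p:
            raise np.linalg.LinAlgError(
                "sample correlation matrix is singular at shrinkage 0; "
                "use shrinkage='auto' or a positive intensity"
            )
        rmat = _partial_from_shrunk(r_shrunk)
        # shrinkage deflates off-diagonal magnitudes by ~(1 - lambda);
        # de-attenuate so r stays on the usual correlation scale, comparable
        # across strata and with plain Pearson values
        if 0.0 < lam < 1.0:
            rmat = np.clip(rmat / (1.0 - lam), -1.0, 1.0)
        elif lam >= 1.0:
            rmat = np.zeros_like(rmat)
            np.fill_diagonal(rmat, 1.0)
    elif estimator == "pearson":
        rmat = np.corrcoef(x, rowvar=False)
    elif estimator == "spearman":
        rmat, _ = stats.spearmanr(x)
        rmat = np.atleast_2d(rmat)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    rows = []
    present = counts > 0
    # Fisher z degrees of freedom: the unshrunk partial correlation
    # conditions on the remaining p-2 taxa; under heavy shrinkage the
    # de-attenuated statistic behaves like a marginal correlation, so the
    # effective n is simply the number of levels
    k_cond = p - 2 if (estimator == "pcor-shrink" and lam == 0.0) else 0
    dof = max(n - k_cond - 3, 1)
    for i in range(p):
        for j in range(i + 1, p):
            r = float(np.clip(rmat[i, j], -0.999999, 0.999999))
            z = np.arctanh(r) * np.sqrt(dof)
            pval = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "taxon_a": taxa[i],
                    "taxon_b": taxa[j],
                    "r": r,
                    "p": pval,
                    "q": np.nan,
                    "n_levels": n,
                    "co_occurrence": int(np.sum(present[:, i] & present[:, j])),
                }
            )
    pairs = pd.DataFrame(rows, columns=cols)
    if len(pairs):
        pairs["q"] = multipletests(pairs["p"].to_numpy(), method="fdr_bh")[1]
        pairs["q"] = np.maximum(pairs["q"], pairs["p"])
    return CorrelationSet(
        taxa=taxa, pairs=pairs, rare_taxa=rare, estimator=estimator,
        shrinkage_lambda=lam,
    )


def build_network(cs: CorrelationSet, alpha: float = 0.05) -> nx.Graph:
    """Network whose edges are the pairs with BH-adjusted q <= alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    g = nx.Graph()
    g.add_nodes_from(cs.taxa)
    for row in cs.pairs.itertuples(index=False):
        if row.q <= alpha:
            g.add_edge(row.taxon_a, row.taxon_b, weight=row.r, q_value=row.q)
    return g
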