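"""Synthetic stratigraphic assemblages with planted ground truth.

Every downstream stage of the pipeline (biofacies detection, correlation
networks, interaction categorization, preservation-bias quantification) is
validated against assemblages generated here, where the true pairwise
dependencies, facies boundaries and preservation probabilities are known.

Counts are generated by a Gaussian-copula / Poisson-emission construction:
a latent multivariate normal field with a planted correlation matrix is
drawn independently per level, added to a per-facies baseline log-abundance
vector, and exponentiated into the Poisson rate.  Planted pairwise latent
correlations therefore translate directly into abundance correlations on
the log scale, which is the scale on which the downstream categories
(competitive < generalist < specialist) are defined.

Preservation is modelled as independent binomial thinning of each cell with
a per-taxon retention probability, optionally derived from a trait category
(soft-bodied taxa preserving worse than hard-bodied ones, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    BODY_TYPES,
    HABITATS,
    SIZE_CLASSES,
    AbundanceMatrix,
    TaxonTraits,
)

__all__ = [
    "PlantedEdge",
    "SyntheticAssemblage",
    "generate_assemblage",
    "apply_preservation",
    "trait_preservation_map",
    "default_edge_spec",
]

EDGE_CLASSES = ("specialist", "generalist", "competitive")

# default latent correlations per interaction class: specialists are strongly
# positively coupled, generalists weakly positively, competitors negatively
DEFAULT_RHO = {"specialist": 0.8, "generalist": 0.35, "competitive": -0.5}


@dataclass(frozen=True)
class PlantedEdge:
    """A planted pairwise dependency between two taxa (by column index)."""

    i: int
    j: int
    kind: str  # specialist | generalist | competitive
    rho: float

    def __post_init__(self):
        if self.kind not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {self.kind!r}")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [-1, 1]")
        if self.i == self.j:
            raise ValueError("planted edge must join two distinct taxa")


@dataclass(frozen=True)
class SyntheticAssemblage:
    abundance: AbundanceMatrix
    traits: TaxonTraits
    planted_edges: tuple
    planted_boundaries: tuple  # interior level indices, strictly increasing
    preservation_probs: dict  # taxon -> retention probability in (0, 1]

    def edge_pairs(self) -> set:
        """Planted pairs as frozensets of taxon names."""
        names = self.abundance.taxon_names
        return {frozenset((names[e.i], names[e.j])) for e in self.planted_edges}


def default_edge_spec(
    n_taxa: int,
    n_specialist: int = 4,
    n_generalist: int = 4,
    n_competitive: int = 4,
    rho: dict | None = None,
    seed: int = 0,
) -> list:
    """Assign disjoint taxon pairs to the three interaction classes.

    Pairs are disjoint (each taxon participates in at most one planted edge)
    so that the requested latent correlation matrix is trivially positive
    definite.
    """
    rho = {**DEFAULT_RHO, **(rho or {})}
    n_pairs = n_specialist + n_generalist + n_competitive
    if 2 * n_pairs > n_taxa:
        raise ValueError(f"{n_pairs} disjoint pairs need at least {2 * n_pairs} taxa")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_taxa)
    edges, k = [], 0
    for kind, count in (
        ("specialist", n_specialist),
        ("generalist", n_generalist),
        ("competitive", n_competitive),
    ):
        for _ in range(count):
            i, j = int(order[k]), int(order[k + 1])
            edges.append(PlantedEdge(i=min(i, j), j=max(i, j), kind=kind, rho=rho[kind]))
            k += 2
    return edges


def community_edge_spec(
    n_taxa: int = 30,
    specialist_block: int = 6,
    generalist_block: int = 8,
    competitive_block: int = 8,
    rho: dict | None = None,
    seed: int = 0,
) -> list:
    """Guild-structured dependencies: whole blocks of co-varying taxa.

    Disjoint planted pairs cap the number of dependent pairs at n/2, which
    leaves the pairwise-correlation distribution dominated by its null
    bulk.  Real assemblages have trophic guilds: here a specialist-like
    guild is equicorrelated at the specialist rho, a generalist-like guild
    at the generalist rho, and a competitive block is split into two halves
    with opposite latent loadings (positive within a half, negative across
    halves).  All blocks are positive semi-definite by construction and the
    resulting correlation distribution carries a visible mode per class.
    """
    rho = {**DEFAULT_RHO, **(rho or {})}
    need = specialist_block + generalist_block + competitive_block
    if need > n_taxa:
        raise ValueError(f"blocks need {need} taxa, only {n_taxa} available")
    if competitive_block % 2:
        raise ValueError("competitive_block must be even (two opposing halves)")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n_taxa))
    spec = [order.pop() for _ in range(specialist_block)]
    gen = [order.pop() for _ in range(generalist_block)]
    comp = [order.pop() for _ in range(competitive_block)]
    half = competitive_block // 2
    edges = []
    for block, kind in ((spec, "specialist"), (gen, "generalist")):
        r = rho[kind]
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                i, j = sorted((block[a], block[b]))
                edges.append(PlantedEdge(i=i, j=j, kind=kind, rho=r))
    rc = abs(rho["competitive"])
    for a in range(competitive_block):
        for b in range(a + 1, competitive_block):
            i, j = sorted((comp[a], comp[b]))
            same_half = (a < half) == (b < half)
            edges.append(
                PlantedEdge(
                    i=i, j=j,
                    kind="generalist" if same_half else "competitive",
                    rho=rc if same_half else -rc,
                )
            )
    return edges


def _latent_correlation(n_taxa: int, edges) -> np.ndarray:
    corr = np.eye(n_taxa)
    for e in edges:
        corr[e.i, e.j] = corr[e.j, e.i] = e.rho
    eigmin = np.linalg.eigvalsh(corr)[0]
    if eigmin < -1e-10:
        raise ValueError(
            f"planted correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigmin:.3g}); thin the edge specification"
        )
    return corr


def _random_traits(taxon_names, rng) -> TaxonTraits:
    motilities = ("motile", "sessile", "facultatively motile")
    table = pd.DataFrame(
        {
            "body_type": rng.choice(sorted(BODY_TYPES), size=len(taxon_names)),
            "size_class": rng.choice(sorted(SIZE_CLASSES), size=len(taxon_names)),
            "habitat": rng.choice(sorted(HABITATS), size=len(taxon_names)),
            "motility": rng.choice(motilities, size=len(taxon_names)),
        },
        index=list(taxon_names),
    )
    return TaxonTraits(table=table)


def generate_assemblage(
    n_taxa: int = 30,
    n_levels: int = 93,
    boundaries=(),
    edge_spec=None,
    noise_sd: float = 1.0,
    base_log_mean: float = 3.0,
    facies_sd: float = 1.2,
    facies_turnover: float = 0.3,
    level_thickness_cm: float = 10.0,
    seed: int = 0,
) -> SyntheticAssemblage:
    """Generate a multi-facies count section with planted dependencies.

    Parameters
    ----------
    boundaries
        Interior level indices at which the facies baseline changes; a
        boundary at ``b`` means level ``b`` starts a new facies.
    edge_spec
        Iterable of :class:`PlantedEdge`; default plants 4 specialist,
        4 generalist and 4 competitive disjoint pairs.
    noise_sd
        Standard deviation of the latent log-abundance field; controls how
        strongly the planted latent correlations express in the counts.
    base_log_mean, facies_sd
        Per-facies baseline log-rates are drawn once per (facies, taxon)
        from Normal(base_log_mean, facies_sd), i.e. a log-normal prior on
        the Poisson rate.
    facies_turnover
        Fraction of taxa suppressed to near-absence in any given facies,
        emulating the compositional turnover that distinguishes biofacies
        (each sub-assemblage has its own set of dominant taxa).
    """
    rng = np.random.default_rng(seed)
    boundaries = tuple(int(b) for b in boundaries)
    if any(b <= 0 or b >= n_levels for b in boundaries):
        raise ValueError("boundaries must be interior level indices")
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("boundaries must be strictly increasing")
    if edge_spec is None:
        per_class = min(4, n_taxa // 6)  # scale the default down for small communities
        edge_spec = default_edge_spec(
            n_taxa, n_specialist=per_class, n_generalist=per_class,
            n_competitive=per_class, seed=seed,
        )
    edge_spec = tuple(edge_spec)
    for e in edge_spec:
        if not (0 <= e.i < n_taxa and 0 <= e.j < n_taxa):
            raise ValueError(f"edge ({e.i},{e.j}) outside taxon range")
    corr = _latent_correlation(n_taxa, edge_spec)

    taxon_names = tuple(f"taxon_{k:02d}" for k in range(n_taxa))
    cuts = (0, *boundaries, n_levels)
    # per-facies baseline log-rate vectors (the planted compositional shifts);
    # suppressed taxa are pushed to near-absence to create the taxon turnover
    # that distinguishes biofacies
    n_facies = len(cuts) - 1
    baselines = rng.normal(base_log_mean, facies_sd, size=(n_facies, n_taxa))
    if not 0.0 <= facies_turnover < 1.0:
        raise ValueError("facies_turnover must lie in [0, 1)")
    if n_facies > 1 and facies_turnover > 0:
        suppressed = rng.random(size=(n_facies, n_taxa)) < facies_turnover
        baselines[suppressed] -= 8.0

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(n_taxa))
    z = rng.standard_normal(size=(n_levels, n_taxa)) @ chol.T
    log_rate = np.empty((n_levels, n_taxa))
    for s in range(len(cuts) - 1):
        log_rate[cuts[s] : cuts[s + 1]] = baselines[s]
    log_rate += noise_sd * z
    counts = rng.poisson(np.exp(log_rate))

    abundance = AbundanceMatrix(
        level_ids=tuple(str(i) for i in range(n_levels)),
        counts=counts,
        taxon_names=taxon_names,
        level_thickness_cm=level_thickness_cm,
    )
    traits = _random_traits(taxon_names, rng)
    return SyntheticAssemblage(
        abundance=abundance,
        traits=traits,
        planted_edges=edge_spec,
        planted_boundaries=boundaries,
        preservation_probs={t: 1.0 for t in taxon_names},
    )


def apply_preservation(m: AbundanceMatrix, probs, seed: int = 0) -> AbundanceMatrix:
    """Binomially thin each cell with its taxon's retention probability.

    ``probs`` maps taxon name -> probability in (0, 1]; alternatively an
    array aligned with ``m.taxon_names``.  A probability of 1 leaves a taxon
    untouched (exactly, not just in expectation).
    """
    if isinstance(probs, dict):
        missing = [t for t in m.taxon_names if t not in probs]
        if missing:
            raise KeyError(f"no preservation probability for taxa: {missing}")
        p = np.array([probs[t] for t in m.taxon_names], dtype=float)
    else:
        p = np.asarray(probs, dtype=float)
        if p.shape != (m.n_taxa,):
            raise ValueError("probs must have one entry per taxon")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("preservation probabilities must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(m.counts, p[np.newaxis, :])
    keep = p >= 1.0
    thinned[:, keep] = m.counts[:, keep]
    return AbundanceMatrix(
        level_ids=m.level_ids,
        counts=thinned,
        taxon_names=m.taxon_names,
        level_thickness_cm=m.level_thickness_cm,
    )


def trait_preservation_map(traits: TaxonTraits, factor: str, probs_by_category: dict) -> dict:
    """Map each taxon to a preservation probability via one trait factor."""
    if factor not in TaxonTraits.REQUIRED:
        raise ValueError(f"unknown trait factor {factor!r}")
    categories = set(traits.table[factor])
    missing = categories - set(probs_by_category)
    if missing:
        raise KeyError(
            f"probs_by_category lacks categories {sorted(missing)} of factor {factor!r}"
        )
    return {
        taxon: float(probs_by_category[cat])
        for taxon, cat in traits.table[factor].items()
    }
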