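"""Consensus interaction extraction and control analyses.

Significant pair correlations are mapped onto the interaction categories
(1 = competitive/negative through the top category = specialist-like
strongly positive).  A pair obtains a consensus interaction when the same
category is assigned in a strict majority (>50%) of the strata where the
two taxa co-occur.  Consensus interactions are compared against a
literature list of proposed trophic pairs, and two control analyses test
whether habitat (or motility) structure could explain the correlations
instead: Shannon equitability of trait labels across stochastic-block-model
blocks, and Yates-corrected chi-squared association between edge sign and
habitat sharing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .corrnet import CorrelationSet
from .mixture import CategoryScheme

__all__ = [
    "InteractionRecord",
    "ComparisonSummary",
    "categorize_pairs",
    "consensus_interactions",
    "compare_to_literature",
    "sbm_equitability",
    "habitat_chisq",
]


@dataclass(frozen=True)
class InteractionRecord:
    pair: frozenset
    category: int | None  # consensus category, None if no majority
    fraction: float  # modal-category fraction over co-occurring strata
    n_strata: int  # strata where the pair co-occurred with a category call
    literature_status: str = "unassessed"


@dataclass(frozen=True)
class ComparisonSummary:
    confirmed: int
    missing: int
    proposed_partial: int  # new pairs among taxa with some known interactions
    proposed_new: int  # new pairs among taxa absent from the literature list
    competitive: int
    rare_excluded: int
    out_of_data: int

    @property
    def proposed(self) -> int:
        return self.proposed_partial + self.proposed_new

    @property
    def accuracy(self) -> float:
        denom = self.confirmed + self.missing
        return self.confirmed / denom if denom else float("nan")


def categorize_pairs(cs: CorrelationSet, scheme: CategoryScheme, alpha: float = 0.05) -> dict:
    """Map each significant pair to the category interval containing its r.

    Pairs whose r falls between category intervals are uncategorized and
    omitted from the result.
    """
    if scheme.n_categories == 0:
        raise ValueError("empty category scheme")
    out = {}
    for row in cs.pairs.itertuples(index=False):
        if row.q > alpha:
            continue
        cat = scheme.assign(row.r)
        if cat is not None:
            out[frozenset((row.taxon_a, row.taxon_b))] = cat
    return out


def consensus_interactions(per_stratum_categories, co_occurrence) -> list:
    """Majority-rule consensus categories across strata.

    ``per_stratum_categories`` is a sequence of pair->category dicts (one
    per stratum); ``co_occurrence`` is a sequence of sets of pairs that
    co-occurred in each stratum (the denominator of the consensus
    fraction).  A consensus requires the modal category in strictly more
    than half of the co-occurring strata; exact 50% ties yield none.
    """
    if len(per_stratum_categories) != len(co_occurrence):
        raise ValueError("need one co-occurrence set per stratum")
    if len(per_stratum_categories) == 0:
        raise ValueError("need at least one stratum")
    votes: dict = {}
    n_cooc: dict = {}
    for cats, cooc in zip(per_stratum_categories, co_occurrence):
        for pair in cooc:
            n_cooc[pair] = n_cooc.get(pair, 0) + 1
        for pair, cat in cats.items():
            votes.setdefault(pair, []).append(cat)
    records = []
    for pair, n in sorted(n_cooc.items(), key=lambda kv: sorted(kv[0])):
        vs = votes.get(pair, [])
        if not vs:
            continue
        uniq, counts = np.unique(vs, return_counts=True)
        top = counts.max()
        modal = int(uniq[np.argmax(counts)])
        fraction = top / n
        category = modal if fraction > 0.5 else None
        records.append(
            InteractionRecord(pair=pair, category=category, fraction=fraction, n_strata=n)
        )
    return records


def compare_to_literature(
    records,
    literature_pairs,
    taxa_in_data=None,
    rare_taxa=(),
    competitive_categories=(1,),
) -> tuple:
    """Book-keeping of consensus interactions against a literature list.

    Trophic consensus = any consensus category outside
    ``competitive_categories``; category-1 consensus pairs are counted as
    competitive and kept out of the trophic comparison (competitive
    interactions have no literature reference set).  Literature pairs whose
    taxa were numerically rare (``rare_taxa``) are excluded from accuracy;
    pairs naming taxa absent from the data are logged as out-of-data.

    Returns ``(ComparisonSummary, annotated_records)``.
    """
    literature = {frozenset(p) for p in literature_pairs}
    lit_taxa = set().union(*literature) if literature else set()
    rare = set(rare_taxa)
    consensus_trophic = {
        r.pair for r in records if r.category is not None
        and r.category not in competitive_categories
    }
    competitive = {
        r.pair for r in records if r.category in competitive_categories
    }
    confirmed = missing = rare_excluded = out_of_data = 0
    for pair in literature:
        if taxa_in_data is not None and not pair <= set(taxa_in_data):
            warnings.warn(f"literature pair {sorted(pair)} names taxa absent from data")
            out_of_data += 1
            continue
        if pair & rare:
            rare_excluded += 1
            continue
        if pair in consensus_trophic:
            confirmed += 1
        else:
            missing += 1
    proposed_partial = proposed_new = 0
    for pair in consensus_trophic - literature:
        if pair & lit_taxa:
            proposed_partial += 1
        else:
            proposed_new += 1
    status = {}
    for pair in literature:
        status[pair] = "confirmed" if pair in consensus_trophic else "missing"
        if pair & rare:
            status[pair] = "rare-excluded"
    annotated = []
    for r in records:
        if r.category is None:
            st = "no-consensus"
        elif r.category in competitive_categories:
            st = "competitive"
        else:
            st = status.get(r.pair, "proposed")
        annotated.append(
            InteractionRecord(
                pair=r.pair, category=r.category, fraction=r.fraction,
                n_strata=r.n_strata, literature_status=st,
            )
        )
    summary = ComparisonSummary(
        confirmed=confirmed,
        missing=missing,
        proposed_partial=proposed_partial,
        proposed_new=proposed_new,
        competitive=len(competitive),
        rare_excluded=rare_excluded,
        out_of_data=out_of_data,
    )
    return summary, annotated


def _bernoulli_term(e: float, poss: float) -> float:
    if poss <= 0 or e <= 0 or e >= poss:
        return 0.0
    p = e / poss
    return poss * (p * np.log(p) + (1 - p) * np.log(1 - p))


def fit_sbm(g: nx.Graph, n_blocks_range=(1, 2, 3, 4, 5, 6), seed: int = 0) -> list:
    """Agglomerative likelihood SBM: greedy merging from singleton blocks.

    Repeatedly merges the block pair that least decreases the Bernoulli
    profile log-likelihood, scoring each partition along the way with an
    ICL-style penalty (log-likelihood minus 0.5 * B(B+1)/2 * log(n_dyads));
    the best-scoring block count within ``n_blocks_range`` is returned as a
    list of node lists.
    """
    nodes = sorted(g.nodes)
    n = len(nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    # block state: member lists, sizes, E[a, b] = edges between blocks a, b
    # (E[a, a] = internal edge count)
    blocks = [[i] for i in range(n)]
    sizes = [1] * n
    E = adj.copy()
    E[np.diag_indices(n)] = 0.0
    n_dyads = max(n * (n - 1) / 2, 1)

    def pair_term(a, b):
        if a == b:
            return _bernoulli_term(E[a, a], sizes[a] * (sizes[a] - 1) / 2)
        return _bernoulli_term(E[a, b], sizes[a] * sizes[b])

    partitions = {n: [list(b) for b in blocks]}
    while len(blocks) > 1:
        B = len(blocks)
        best_pair, best_delta = None, -np.inf
        for i in range(B):
            for j in range(i + 1, B):
                old = pair_term(i, i) + pair_term(j, j) + pair_term(i, j)
                s_new = sizes[i] + sizes[j]
                new = _bernoulli_term(
                    E[i, i] + E[j, j] + E[i, j], s_new * (s_new - 1) / 2
                )
                for k in range(B):
                    if k in (i, j):
                        continue
                    old += pair_term(i, k) + pair_term(j, k)
                    new += _bernoulli_term(E[i, k] + E[j, k], s_new * sizes[k])
                delta = new - old
                if delta > best_delta:
                    best_delta, best_pair = delta, (i, j)
        i, j = best_pair
        merged = blocks[i] + blocks[j]
        keep = [k for k in range(B) if k not in (i, j)]
        newE = np.zeros((B - 1, B - 1))
        newE[: len(keep), : len(keep)] = E[np.ix_(keep, keep)]
        for a, k in enumerate(keep):
            newE[a, -1] = newE[-1, a] = E[i, k] + E[j, k]
        newE[-1, -1] = E[i, i] + E[j, j] + E[i, j]
        E = newE
        sizes = [sizes[k] for k in keep] + [sizes[i] + sizes[j]]
        blocks = [blocks[k] for k in keep] + [merged]
        partitions[len(blocks)] = [list(b) for b in blocks]

    def partition_ll(partition):
        ll = 0.0
        for ai, a in enumerate(partition):
            for b in partition[ai:]:
                if a is b:
                    ll += _bernoulli_term(
                        adj[np.ix_(a, a)].sum() / 2, len(a) * (len(a) - 1) / 2
                    )
                else:
                    ll += _bernoulli_term(adj[np.ix_(a, b)].sum(), len(a) * len(b))
        return ll

    scores = {}
    for b_count, partition in partitions.items():
        if b_count not in n_blocks_range:
            continue
        penalty = 0.5 * (b_count * (b_count + 1) / 2) * np.log(n_dyads)
        scores[b_count] = partition_ll(partition) - penalty
    if not scores:
        raise ValueError("no block count in n_blocks_range is feasible")
    b_best = max(scores, key=scores.get)
    return [[nodes[i] for i in blk] for blk in partitions[b_best]]


def sbm_equitability(
    g: nx.Graph, labels: dict, n_blocks_range=(1, 2, 3, 4, 5, 6), seed: int = 0
) -> float:
    """Size-weighted Shannon equitability of trait labels across SBM blocks.

    1 means every block mixes the label types evenly (no block structure
    along the trait); 0 means each block is dominated by a single type.
    Blocks with a single node contribute 0.
    """
    nodes = list(g.nodes)
    if len(nodes) < 4:
        raise ValueError("need at least 4 nodes")
    missing = [v for v in nodes if v not in labels]
    if missing:
        raise KeyError(f"nodes without labels: {missing}")
    k_types = len({labels[v] for v in nodes})
    if k_types < 2:
        warnings.warn("single-label network; equitability is 0 by definition")
        return 0.0
    blocks = fit_sbm(g, n_blocks_range=n_blocks_range, seed=seed)
    total = 0.0
    weight = 0
    for blk in blocks:
        if len(blk) < 2:
            eq = 0.0
        else:
            labs = [labels[v] for v in blk]
            _, counts = np.unique(labs, return_counts=True)
            p = counts / counts.sum()
            h = -(p * np.log(p)).sum()
            eq = h / np.log(k_types)
        total += eq * len(blk)
        weight += len(blk)
    return float(total / weight)


def habitat_chisq(
    cs: CorrelationSet, habitats: dict, sign: str = "negative", alpha: float = 0.05
):
    """Yates-corrected chi-squared: edge sign vs habitat sharing.

    Builds the 2x2 table (edge has the selected sign vs the other sign) x
    (endpoints share a habitat vs not) over significant pairs, and returns
    ``(chi2, p)``.  A degenerate table (a zero margin) yields p = 1.
    """
    if sign not in ("negative", "positive"):
        raise ValueError("sign must be 'negative' or 'positive'")
    table = np.zeros((2, 2), dtype=int)
    n_selected = 0
    for row in cs.pairs.itertuples(index=False):
        if row.q > alpha:
            continue
        selected = (row.r < 0) if sign == "negative" else (row.r > 0)
        same = habitats[row.taxon_a] == habitats[row.taxon_b]
        table[0 if selected else 1, 0 if same else 1] += 1
        n_selected += selected
    if n_selected == 0:
        raise ValueError(f"no significant {sign} pairs")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); p reported as 1")
        return 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(table, correction=True)
    return float(chi2), float(p)
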