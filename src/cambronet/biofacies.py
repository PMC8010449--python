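"""Sub-assemblage (biofacies) boundary detection.

Two classical community-boundary methods are combined:

* SHE analysis for biozone identification: accumulating specimens upward
  through the section, richness S, Shannon information H and evenness
  E = exp(H)/S obey the identity ln S = H + ln E at every step.  Within a
  homogeneous biozone, ln E declines roughly linearly in ln N; a structural
  break in that trend marks a candidate biozone boundary.
* ANOSIM: a permutation test on Bray-Curtis rank dissimilarities comparing
  between-segment with within-segment similarity.

A boundary enters the consensus partition when the SHE breakpoint is
confirmed by a significant ANOSIM contrast between the adjacent segments.
Segments are labelled A, B, C, ... from oldest (lowest) upward.
"""

from __future__ import annotations

import itertools
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import AbundanceMatrix

__all__ = [
    "SHESeries",
    "FaciesPartition",
    "she_analysis",
    "anosim",
    "detect_subassemblages",
]


@dataclass(frozen=True)
class SHESeries:
    """Accumulated S, H, E decomposition along the section."""

    table: pd.DataFrame  # columns: level_index, N, S, H, lnE, segment
    boundaries: tuple  # candidate boundary level indices (start of new segment)


@dataclass(frozen=True)
class FaciesPartition:
    boundaries: tuple  # interior level indices, strictly increasing
    labels: tuple  # one segment label per level, e.g. A, A, B, ...
    support: dict  # boundary -> {"she": bool, "anosim": bool, "anosim_p": float}

    @property
    def n_segments(self) -> int:
        return len(self.boundaries) + 1

    def segment_slices(self):
        cuts = (0, *self.boundaries, len(self.labels))
        return [slice(a, b) for a, b in zip(cuts, cuts[1:])]


def _shannon(counts: np.ndarray) -> float:
    tot = counts.sum()
    p = counts[counts > 0] / tot
    return float(-(p * np.log(p)).sum())


def _she_curves(counts: np.ndarray):
    """Accumulation curves ln N, ln E and richness S for one segment."""
    acc = np.cumsum(counts, axis=0)
    N = np.maximum(acc.sum(axis=1), 1)
    S = np.maximum((acc > 0).sum(axis=1), 1)
    H = np.array([_shannon(a) if a.sum() else 0.0 for a in acc])
    return np.log(N), H - np.log(S), S


def she_analysis(
    m: AbundanceMatrix,
    break_tolerance: float = 6.0,
    s_jump: int = 3,
    s_span: int = 3,
    min_segment: int = 8,
    window: int = 10,
) -> SHESeries:
    """SHE biozone identification on the specimen accumulation curve.

    Within a biozone, accumulating further levels changes the evenness
    decomposition ln S = H + ln E only gradually.  A biofacies boundary
    announces itself in two ways on the accumulation curve: an abrupt
    innovation in ln E (new dominance structure), detected as a robust z
    score above ``break_tolerance`` relative to the trailing ``window`` of
    innovations; or a burst of richness, ``s_jump`` or more first
    occurrences within ``s_span`` consecutive levels (taxon turnover).
    After a trigger the breakpoint is localized by the best two-piece
    linear fit of ln E vs ln N around the trigger, accumulation restarts
    there, and scanning continues.  ``min_segment`` levels must accumulate
    before breaks are tested.

    Returns the accumulated series (with segment assignments) and the
    candidate boundaries; candidates are refined and confirmed by ANOSIM
    in :func:`detect_subassemblages`.
    """
    if m.n_levels < 6:
        raise ValueError("SHE analysis needs at least 6 levels")
    totals = m.counts.sum(axis=1)
    if (totals == 0).any():
        empty = [m.level_ids[i] for i in np.flatnonzero(totals == 0)]
        warnings.warn(f"level(s) with zero specimens: {empty}")

    def rss(xi, yi):
        if len(xi) < 3:
            return 0.0
        b, a = np.polyfit(xi, yi, 1)
        return float(((yi - a - b * xi) ** 2).sum())

    boundaries = []
    seg_start = 0
    while m.n_levels - seg_start >= min_segment + 3:
        x, y, S = _she_curves(m.counts[seg_start:])
        d = np.diff(y)
        dS = np.diff(S)
        trigger = None
        jump_trigger = False
        for i in range(min_segment, len(d)):
            tail = d[max(0, i - window):i]
            med = np.median(tail)
            scale = 1.4826 * np.median(np.abs(tail - med)) + 1e-12
            jump = dS[max(0, i - s_span + 1):i + 1].sum()
            if abs(d[i] - med) / scale > break_tolerance or jump >= s_jump:
                jump_trigger = jump >= s_jump
                trigger = max(i - (s_span - 1) if jump_trigger else i + 1, 1)
                break
        if trigger is None:
            break
        if not jump_trigger:
            # localize the ln E kink by the best two-piece linear fit
            lo = max(0, trigger - 12)
            hi = min(len(y), trigger + 5)
            best_t, best_r = trigger, np.inf
            for t in range(lo + 3, hi - 2):
                r = rss(x[lo:t], y[lo:t]) + rss(x[t:hi], y[t:hi])
                if r < best_r:
                    best_t, best_r = t, r
            trigger = max(best_t, 1)
        boundaries.append(seg_start + trigger)
        seg_start += trigger

    rows = []
    cuts = [0, *boundaries, m.n_levels]
    for si, (a, b) in enumerate(zip(cuts, cuts[1:])):
        acc = np.cumsum(m.counts[a:b], axis=0)
        for k, accrow in enumerate(acc):
            N = int(accrow.sum())
            S = int((accrow > 0).sum())
            H = _shannon(accrow) if N else 0.0
            rows.append(
                {"level_index": a + k, "N": N, "S": S, "H": H,
                 "lnE": (H - np.log(S)) if S else 0.0, "segment": si}
            )
    return SHESeries(table=pd.DataFrame(rows), boundaries=tuple(boundaries))


def anosim(
    m: AbundanceMatrix,
    partition,
    n_perm: int = 999,
    seed: int = 0,
    metric: str = "braycurtis",
):
    """ANOSIM R statistic and permutation p-value for a level partition.

    ``partition`` assigns a group label to every level.  R compares mean
    between-group and within-group ranks of the Bray-Curtis dissimilarities:
    R = (rb - rw) / (M/2) with M = C(n, 2).  The p-value is the fraction of
    ``n_perm`` label permutations (plus the observed one) attaining R at
    least as large.
    """
    labels = np.asarray(partition)
    if labels.shape != (m.n_levels,):
        raise ValueError("partition must label every level")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 levels")
    d = pdist(m.counts.astype(float), metric=metric)
    ranks = rankdata(d)
    iu = np.triu_indices(m.n_levels, k=1)

    def r_stat(lab):
        within = lab[iu[0]] == lab[iu[1]]
        rw = ranks[within].mean()
        rb = ranks[~within].mean()
        return (rb - rw) / (len(ranks) / 2.0)

    observed = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 1  # the observed labelling counts as one permutation
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if r_stat(perm) >= observed - 1e-12:
            hits += 1
    return float(observed), hits / (n_perm + 1.0)


def anosim_exhaustive(m: AbundanceMatrix, partition, metric: str = "braycurtis"):
    """Exact ANOSIM p-value by enumerating all distinct label permutations.

    Feasible only for small sections; used as an oracle for the sampled
    permutation test.
    """
    labels = np.asarray(partition)
    d = pdist(m.counts.astype(float), metric=metric)
    ranks = rankdata(d)
    iu = np.triu_indices(m.n_levels, k=1)

    def r_stat(lab):
        lab = np.asarray(lab)
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2.0)

    observed = r_stat(labels)
    perms = set(itertools.permutations(labels))
    hits = sum(1 for p in perms if r_stat(p) >= observed - 1e-12)
    return float(observed), hits / len(perms)


def detect_subassemblages(
    m: AbundanceMatrix,
    break_tolerance: float = 6.0,
    alpha: float = 0.05,
    n_perm: int = 999,
    merge_radius: int = 6,
    seed: int = 0,
    _depth: int = 0,
) -> FaciesPartition:
    """Consensus sub-assemblage partition from SHE breakpoints and ANOSIM.

    SHE proposes candidate boundaries; each is refined by maximizing the
    ANOSIM R statistic over splits of the surrounding stretch and then
    confirmed by the ANOSIM permutation test (p <= alpha).  Confirmed
    segments are recursively re-screened (with a slightly more sensitive
    SHE tolerance, ANOSIM still gating) for boundaries the first pass
    missed, and boundaries closer than ``merge_radius`` levels are merged,
    keeping the better-separating one.  Segments are labelled oldest-first
    A, B, C, ...
    """
    she = she_analysis(m, break_tolerance=break_tolerance)
    candidates = sorted(she.boundaries)
    retained = []  # (boundary, R, p)
    for k, b in enumerate(candidates):
        lo = candidates[k - 1] if k else 0
        hi = candidates[k + 1] if k + 1 < len(candidates) else m.n_levels
        if hi - lo < 5:
            continue
        sub = m.select_levels(np.arange(lo, hi))
        best_b, best_r = None, -np.inf
        for t in range(lo + 3, hi - 2):
            lab = (np.arange(lo, hi) >= t).astype(int)
            r, _ = anosim(sub, lab, n_perm=0, seed=seed)
            if r > best_r:
                best_b, best_r = t, r
        lab = (np.arange(lo, hi) >= best_b).astype(int)
        _, p = anosim(sub, lab, n_perm=n_perm, seed=seed + k)
        # Bonferroni over the candidates tested in this pass
        if p <= alpha / max(len(candidates), 1):
            retained.append((best_b, best_r, p))
    if retained and _depth < 3:
        cuts = [0, *sorted(b for b, _, _ in retained), m.n_levels]
        for a, b in zip(cuts, cuts[1:]):
            if b - a >= 16:
                # stricter alpha inside the recursion: the re-screen multiplies
                # the number of ANOSIM tests, so spurious splits must be held back
                inner = detect_subassemblages(
                    m.select_levels(np.arange(a, b)),
                    break_tolerance=min(break_tolerance, 5.0),
                    alpha=alpha / 5.0, n_perm=n_perm, merge_radius=merge_radius,
                    seed=seed + 31 * (_depth + 1), _depth=_depth + 1,
                )
                for ib in inner.boundaries:
                    info = inner.support.get(ib, {})
                    retained.append((a + ib, info.get("R", 0.0), info.get("anosim_p", np.nan)))
    merged = []  # (boundary, R, p)
    for b, r, p in sorted(retained):
        if merged and b - merged[-1][0] < merge_radius:
            if r > merged[-1][1]:
                merged[-1] = (b, r, p)
        else:
            merged.append((b, r, p))
    support = {
        int(b): {"she": True, "anosim": True, "anosim_p": float(p), "R": float(r)}
        for b, r, p in merged
    }
    boundaries = [b for b, _, _ in merged]
    labels = []
    seg = 0
    names = string.ascii_uppercase
    for i in range(m.n_levels):
        if seg < len(boundaries) and i >= boundaries[seg]:
            seg += 1
        labels.append(names[seg % len(names)])
    return FaciesPartition(boundaries=tuple(boundaries), labels=tuple(labels), support=support)
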