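"""Gaussian decomposition of correlation distributions and categorization.

The distribution of pairwise abundance correlations within a stratum is
decomposed into a mixture of 1-D Gaussians by maximum likelihood (EM with
multiple seeded restarts; component count chosen by BIC).  Components
pooled across strata are then clustered into interaction categories:
pairwise Bhattacharyya similarity -> symmetric normalized Laplacian ->
spectral embedding -> k-means, with the number of clusters chosen by the
Tibshirani gap statistic against uniform reference draws in the embedding.
Each category's interval is the range of its member component means;
correlations falling between intervals remain uncategorized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "GaussianComponent",
    "CompositionResult",
    "GaussianMixtureFit",
    "CategoryScheme",
    "fit_gmm_1d",
    "gaussian_similarity",
    "cluster_components",
    "category_composition",
]

SIGMA_FLOOR = 1e-3


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    weight: float
    stratum: str = ""

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("component sd must be positive")
        if not 0 < self.weight <= 1:
            raise ValueError("component weight must lie in (0, 1]")


@dataclass(frozen=True)
class GaussianMixtureFit:
    components: tuple
    k: int
    log_likelihood: float
    bic_by_k: dict

    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered interaction categories with mean-range intervals.

    ``clusters[c]`` holds the member components of category ``c+1``;
    ``intervals[c]`` is (lo, hi), the range of member component means, the
    quantity reported for each category.  Because a category's members are
    Gaussians with finite width, membership of an individual correlation is
    decided by the wider ``assignment_intervals`` (member means +/- one
    member standard deviation, truncated at the midpoint between adjacent
    categories so they never overlap); values outside every assignment
    interval are uncategorized.  Categories are ordered by ascending
    cluster mean, so category 1 holds the most negative correlations and
    the top category the most positive.
    """

    clusters: tuple
    intervals: tuple
    assignment_intervals: tuple = ()

    def __post_init__(self):
        if not self.assignment_intervals:
            object.__setattr__(self, "assignment_intervals", self.intervals)

    @property
    def n_categories(self) -> int:
        return len(self.clusters)

    def assign(self, r: float):
        """1-based category whose assignment interval contains ``r``."""
        for c, (lo, hi) in enumerate(self.assignment_intervals):
            if lo <= r <= hi:
                return c + 1
        return None


def _scheme_from_clusters(clusters) -> CategoryScheme:
    """Order clusters by mean and derive reported + assignment intervals."""
    clusters = sorted(clusters, key=lambda ms: np.mean([c.mean for c in ms]))
    intervals, wide = [], []
    for members in clusters:
        mu = [c.mean for c in members]
        intervals.append((float(min(mu)), float(max(mu))))
        wide.append(
            (float(min(c.mean - c.sd for c in members)),
             float(max(c.mean + c.sd for c in members)))
        )
    # truncate overlapping assignment intervals at the midpoint between
    # neighbouring categories
    assign = [list(iv) for iv in wide]
    for a, b in zip(assign, assign[1:]):
        if a[1] > b[0]:
            mid = 0.5 * (a[1] + b[0])
            a[1] = b[0] = mid
    return CategoryScheme(
        clusters=tuple(tuple(m) for m in clusters),
        intervals=tuple(intervals),
        assignment_intervals=tuple((lo, hi) for lo, hi in assign),
    )


def fit_gmm_1d(
    values,
    k_candidates=(1, 2, 3, 4, 5, 6),
    n_restarts: int = 5,
    seed: int = 0,
    stratum: str = "",
) -> GaussianMixtureFit:
    """Maximum-likelihood 1-D Gaussian mixture with BIC model selection."""
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("need at least 10 values to fit a mixture")
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if any(k < 1 or k > 8 for k in k_candidates):
        raise ValueError("k candidates must lie in 1..8")
    feasible = [k for k in k_candidates if 2 * k <= len(x)]
    if feasible != k_candidates:
        warnings.warn("k candidate range truncated: too few values")
        k_candidates = feasible
    bic_by_k, fits = {}, {}
    for k in k_candidates:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_restarts,
            init_params="k-means++",
            reg_covar=SIGMA_FLOOR**2,
            random_state=seed,
            max_iter=500,
        ).fit(x)
        bic_by_k[k] = float(gm.bic(x))
        fits[k] = gm
    best_k = min(bic_by_k, key=bic_by_k.get)
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    comps = tuple(
        GaussianComponent(
            mean=float(gm.means_.ravel()[i]),
            sd=float(max(np.sqrt(gm.covariances_.ravel()[i]), SIGMA_FLOOR)),
            weight=float(gm.weights_[i]),
            stratum=stratum,
        )
        for i in order
    )
    return GaussianMixtureFit(
        components=comps,
        k=best_k,
        log_likelihood=float(gm.score(x) * len(x)),
        bic_by_k=bic_by_k,
    )


def gaussian_similarity(a: GaussianComponent, b: GaussianComponent) -> float:
    """Bhattacharyya coefficient between two univariate Gaussians.

    BC = exp(-D_B) with
    D_B = (mu_a - mu_b)^2 / (4 (s_a^2 + s_b^2)) + 1/2 ln((s_a^2 + s_b^2) / (2 s_a s_b)).
    """
    va, vb = a.sd**2, b.sd**2
    if va <= 0 or vb <= 0:
        raise ValueError("component variances must be positive")
    db = (a.mean - b.mean) ** 2 / (4.0 * (va + vb)) + 0.5 * np.log(
        (va + vb) / (2.0 * a.sd * b.sd)
    )
    return float(np.exp(-db))


def _spectral_embedding(sim: np.ndarray, dim: int) -> np.ndarray:
    deg = sim.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(len(sim)) - d_inv_sqrt[:, None] * sim * d_inv_sqrt[None, :]
    _, vecs = eigh(lap, subset_by_index=(0, dim - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    return vecs / np.where(norms > 0, norms, 1.0)


def cluster_components(
    components,
    c_candidates=(1, 2, 3, 4, 5, 6),
    n_ref: int = 50,
    seed: int = 0,
    similarity_floor: float = 1e-12,
) -> CategoryScheme:
    """Spectral clustering of Gaussian components into ordered categories.

    For each candidate cluster count c the components are embedded with the
    first max(c, 2) eigenvectors of the symmetric normalized Laplacian of
    the Bhattacharyya similarity matrix (rows normalized) and partitioned
    by k-means; c is chosen by the Tibshirani gap statistic, with ``n_ref``
    uniform reference draws over the embedding's bounding box, stopping at
    the first c with Gap(c) >= Gap(c+1) - s(c+1).
    """
    components = tuple(components)
    if len(components) < 4:
        raise ValueError("need at least 4 components to cluster")
    c_candidates = sorted(set(int(c) for c in c_candidates))
    c_candidates = [c for c in c_candidates if 1 <= c < len(components)]
    n = len(components)
    sim = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = gaussian_similarity(components[i], components[j])

    def one_cluster():
        return _scheme_from_clusters([list(components)])

    off = sim[np.triu_indices(n, 1)]
    if off.max() - off.min() < 1e-9 and off.min() > similarity_floor:
        return one_cluster()  # indistinguishable components

    # a similarity graph split into connected components is already
    # clustered: the zero eigenvalues of the Laplacian make the k-means
    # embedding degenerate, so resolve components first
    adj = sim > max(similarity_floor, 1e-4)
    comp_label = np.full(n, -1)
    n_comp = 0
    for s0 in range(n):
        if comp_label[s0] >= 0:
            continue
        stack = [s0]
        comp_label[s0] = n_comp
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u]):
                if comp_label[v] < 0:
                    comp_label[v] = n_comp
                    stack.append(v)
        n_comp += 1
    if n_comp > 1:
        if n_comp == n:
            warnings.warn(
                "similarity graph effectively disconnected; one cluster per component"
            )
        return _scheme_from_clusters(
            [
                [components[i] for i in np.flatnonzero(comp_label == lab)]
                for lab in sorted(set(comp_label))
            ]
        )

    rng = np.random.default_rng(seed)

    def within_dispersion(x, c):
        km = KMeans(n_clusters=c, n_init=10, random_state=seed).fit(x)
        w = 0.0
        for lab in range(c):
            pts = x[km.labels_ == lab]
            if len(pts) > 1:
                w += ((pts - pts.mean(axis=0)) ** 2).sum()
        return max(w, 1e-12), km

    gaps, sks, kms, embeds = {}, {}, {}, {}
    for c in c_candidates:
        dim = min(max(c, 2), n - 1)
        emb = _spectral_embedding(sim, dim)
        embeds[c] = emb
        w_obs, km = within_dispersion(emb, c)
        kms[c] = km
        lo, hi = emb.min(axis=0), emb.max(axis=0)
        ref_logw = []
        for _ in range(n_ref):
            ref = rng.uniform(lo, hi, size=emb.shape)
            w_ref, _ = within_dispersion(ref, c)
            ref_logw.append(np.log(w_ref))
        ref_logw = np.array(ref_logw)
        gaps[c] = float(ref_logw.mean() - np.log(w_obs))
        sks[c] = float(ref_logw.std(ddof=0) * np.sqrt(1.0 + 1.0 / n_ref))
    # choose the cluster count with the largest gap; when tight component
    # groups drive the observed dispersion to ~0 the gap peaks at the true
    # count, whereas the first-local-optimum rule tends to stop too early
    # on overlapping 1-D modes
    chosen = max(c_candidates, key=lambda c: gaps[c])
    if chosen == 1:
        return one_cluster()
    labels = kms[chosen].labels_
    return _scheme_from_clusters(
        [
            [components[i] for i in np.flatnonzero(labels == lab)]
            for lab in sorted(set(labels))
        ]
    )


@dataclass(frozen=True)
class CompositionResult:
    """Label composition of ABM correlations within category intervals.

    ``per_category`` maps category id -> {label: share of the category's
    correlations}; because interaction classes have very different base
    rates (in a 17-prey community the competition/apparent-competition
    pairs outnumber specialist pairs by two orders of magnitude),
    ``per_label`` additionally reports the base-rate-normalized view: for
    each category, P(category | label) renormalized across labels, i.e.
    which feeding type is most concentrated in that band relative to its
    own abundance.  ``in_interval_fraction`` is the share of all labelled
    correlations falling inside any category interval.
    """

    per_category: dict
    per_label: dict
    in_interval_fraction: float

    def plurality(self, category: int, normalized: bool = True):
        d = (self.per_label if normalized else self.per_category).get(category, {})
        return max(d, key=d.get) if d else None


def category_composition(labeled_correlations, scheme: CategoryScheme) -> CompositionResult:
    """Compose ABM interaction labels within each category's interval.

    ``labeled_correlations`` is a DataFrame with columns ``label`` and ``r``
    (as produced by :func:`cambronet.abm.abm_correlations`); pairs labelled
    ``none`` (no interaction) are ignored.  Correlations falling in the
    gaps between category intervals are counted as outside.
    """
    if scheme.n_categories == 0:
        raise ValueError("empty category scheme")
    df = labeled_correlations[labeled_correlations["label"] != "none"]
    labels = sorted(df["label"].unique())
    label_totals = df["label"].value_counts().to_dict()
    counts = {c + 1: {} for c in range(scheme.n_categories)}
    total = len(df)
    inside = 0
    for row in df.itertuples(index=False):
        cat = scheme.assign(row.r)
        if cat is not None:
            inside += 1
            counts[cat][row.label] = counts[cat].get(row.label, 0) + 1
    per_category, per_label = {}, {}
    for cat, d in counts.items():
        n_cat = sum(d.values())
        per_category[cat] = {lab: k / n_cat for lab, k in d.items()} if n_cat else {}
        cond = {lab: d.get(lab, 0) / label_totals[lab] for lab in labels if label_totals.get(lab)}
        z = sum(cond.values())
        per_label[cat] = {lab: v / z for lab, v in cond.items()} if z > 0 else {}
    frac = inside / total if total else float("nan")
    return CompositionResult(
        per_category=per_category, per_label=per_label, in_interval_fraction=frac
    )
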