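# Methods

`cambronet` infers trophic and competitive interactions among fossil taxa
from stratigraphic abundance data. The chain is: biofacies detection →
corrected pairwise correlations → preservation-bias screening → Gaussian
decomposition and categorization of the correlation distribution →
majority-rule consensus interactions, with an agent-based model (ABM)
supplying the ecological interpretation of correlation magnitudes and the
calibration target for the bias coefficient. This note documents each
model, its assumptions, the tunable parameters, and the design choices
made where the construction was genuinely open.

## Synthetic assemblages

Real quarry data are a single, fixed observation; every stage here is
instead validated on synthetic assemblages with planted truth
(`cambronet.synthetic`). Counts follow a Gaussian-copula/Poisson
construction: a latent normal field `z_t ~ N(0, R)` is drawn independently
per 10 cm level, and taxon `j`'s count at level `t` is
`Poisson(exp(b_{f(t),j} + sigma * z_tj))`, where `b` is a per-facies
baseline (`Normal(3.0, 1.2)` per facies and taxon — median rate ~20
specimens per level) and `sigma = 1.0`. The planted latent correlation
matrix `R` carries the pairwise dependencies: strongly positive
specialist-like pairs (default rho 0.8), weakly positive generalist-like
pairs (0.35) and negative competitive-like pairs (−0.5), either as
disjoint pairs (`default_edge_spec`) or as guild blocks
(`community_edge_spec`: an equicorrelated block per positive class and a
two-half block with opposite latent loadings for competition; both are
positive semi-definite by construction). Poisson emission attenuates the
latent correlation on the log-count scale; the defaults were chosen so a
planted rho = 0.9 pair shows a sample log-count Pearson correlation within
±0.1 of 0.9 at 500 levels.

Facies boundaries shift the baseline vectors, and a fraction
(`facies_turnover`, default 0.3) of taxa is suppressed to near-absence in
any given facies — the compositional turnover that distinguishes real
biofacies. Preservation is binomial thinning of each cell with a
per-taxon retention probability, optionally derived from a trait category.

What the generator does not emulate: sediment transport, spatial patchiness
within a bedding plane, time-averaging across levels, collection effort, or
taxonomic misassignment. Passing tests therefore demonstrate statistical
correctness of the inference chain under the stated generative model, not
robustness to every taphonomic process.

## Biofacies detection

`she_analysis` accumulates specimens upward and tracks the SHE
decomposition `H = ln S + ln E` (Shannon information = log richness + log
evenness, so `E = exp(H)/S <= 1`). Within a biozone the accumulation curve
changes smoothly; a boundary announces itself either as an outlier
innovation of `ln E` (robust z against the trailing window of innovations,
threshold `break_tolerance = 6`) or as a burst of richness (>= 3 first
occurrences within 3 levels). Detected breaks are localized by the best
two-piece linear fit of `ln E` vs `ln N` near the trigger, and accumulation
restarts at the boundary. The classical single-residual break rule proved
both insensitive and uncalibrated on cumulative curves (their residuals are
smooth and autocorrelated), hence this innovation-scale construction.

`detect_subassemblages` forms the consensus with ANOSIM: each SHE
candidate's position is refined by maximizing the ANOSIM R statistic over
splits of the surrounding stretch (Bray-Curtis on raw counts), confirmed by
a seeded permutation test with a Bonferroni correction over the candidates
of the pass, recursively re-screened inside confirmed segments (slightly
more sensitive SHE threshold, ANOSIM still gating), and merged within 6
levels. Measured on the generator's defaults: ~5% false-boundary rate on
homogeneous sections, ~90% recovery of a planted boundary within ±3
levels, ~88% exact segment-count recovery with three strong planted
boundaries.

## Corrected correlations and networks

Counts are `log(1+x)` transformed. When the stratum is long enough to
invert the sample correlation matrix stably (`n >= p + 13`), the estimator
is the plain partial correlation with Fisher-z p-values at
`dof = n - (p-2) - 3`. Shorter strata — the regime of real 20 cm-bin
sub-assemblages, where taxa outnumber levels — use a shrinkage estimator:
off-diagonals scaled by `(1 - lambda)` with the Schafer–Strimmer analytic
intensity, partial correlations from the inverse, then de-attenuated by
`1/(1 - lambda)` so the reported `r` stays on the usual correlation scale;
under heavy shrinkage the statistic behaves like a marginal correlation and
the Fisher z uses `dof = n - 3`. Plain Pearson and Spearman are available
as `estimator=` for sensitivity analysis; the decomposition/categorization
stage uses `estimator="pearson"` because its categories are transferred to
plain-Pearson ABM correlations and the two must share a scale. Multiple
testing is Benjamini–Hochberg; edges are pairs with `q <= alpha` (default
0.05). Taxa present in fewer than 25% of levels are excluded as
numerically rare but reported. Measured calibration: null `p < 0.05` rate
0.052; power for a planted rho = 0.9 pair at 200 levels ~1.0.

## Agent-based model

A toroidal grid (default 30×30) carries a regrowing resource; 17 prey
species graze it and 8 predators (4 specialists with one-prey diets, 4
generalists with five-prey diets) consume co-located prey. Agents random
walk, pay a metabolic cost (prey 0.5, predators 1.5 per step), die at zero
energy and reproduce by fission above an energy threshold (12). Two
stabilizing mechanisms are part of the model: a small immigration stream
(0.1 expected individuals per species per step — the rescue effect of a
regional pool; without it predators boom-bust to extinction) and a slow
Ornstein–Uhlenbeck fluctuation of each prey's grazing efficiency
(`sigma = 0.12`, mean-reversion 0.008, i.e. fluctuation timescale ~125
steps). The slow waves matter: abundance correlation expresses trophic
coupling only on long timescales, and without environmental variation the
census is demographic noise. Variant 2 weights a predator's prey choice by
preference × local availability.

With the defaults (1200 steps, burn-in 300), the mean post-burn-in Pearson
correlations order as specialist (~0.29) > generalist (~0.09) > competition
(~0.00), and pairs with `r > 0.5` are dominated by specialist interactions
once the classes' very different base rates are accounted for. The
preference experiment uses a smaller, trophically dominated configuration
(20×20 grid, `env_sigma = 0.08`, 600 steps): with large environmental
waves the shared-environment covariance swamps the ~0.01–0.03 preference
contrast. Ground-truth pair labels come from the diet matrix; all
competition flavours (shared resource, shared predator, intra-guild) are
pooled into one class.

## Preservation-bias coefficient

The coefficient asks: does the network's structure align with a trait
factor (body type, size class, habitat) in the way differential
preservation would cause? Three ingredients:

1. **ERGM attribute effect.** A maximum pseudo-likelihood ERGM (logistic
   regression over dyads; terms: edges, per-category homophily, per-category
   activity) gives the attribute-block deviance improvement per dyad,
   `Delta`. Because `Delta` scales with network size and density, it is
   standardized against a label-permutation null of the same network
   (median/IQR), which makes the statistic transferable between the
   calibration corpus and fossil windows.
2. **Calibration corpus.** ABM communities (the moderate-population
   calibration configuration, 1200 steps) are binomially thinned per species
   with preservation categories (1.0, 0.05, 0.005) — severities chosen to
   reach the counting-noise floor of the binned census, where thinning
   actually destroys correlation signal. Each case draws a differential
   severity `f ~ U(0, 0.5)` (the fraction of species degraded), and every
   run also contributes its perfect-preservation case with a hypothetical
   category assignment, anchoring the chance-alignment end of the curve.
3. **Isotonic map.** The edge-normalized alteration
   `|E1 xor E2| / (|E1| + |E2|)` between each degraded network and its
   perfect base case is regressed isotonically on the standardized effect.
   (The dyad-normalized Hamming distance of sparse networks is compressed
   toward zero, which would make the 0.5 threshold unreachable;
   `hamming_distance` itself remains dyad-normalized.) The coefficient of a
   fossil window is its fitted alteration rescaled to the calibration's
   dynamic range — 0 at the no-differential-bias floor, 1 at the corpus's
   most severe differential bias — clipped to [0, 1]. Windows are excluded
   when any factor's coefficient exceeds 0.5, and contiguous flagged runs at
   the section's ends are reported as basal/top trims.

Desk-scale calibration uses 35 runs × 3 degradations (plus 35 perfect
cases); measured behaviour: shuffled-label null median ~0.0, a constructed
category-clique network scores 1.0, and a severely soft-thinned basal
region of a planted assemblage is flagged with ~84% sensitivity at ~90%
per-window specificity. Known caveat: the corpus-level monotone relation
between attribute effect and alteration is noisy (Spearman ~0.2–0.4), so
the coefficient is a screening instrument, not a precise alteration
estimate.

## Mixture decomposition and interaction categories

Per-stratum correlation distributions are decomposed by 1-D maximum
likelihood Gaussian mixtures (EM with k-means++ restarts, `sigma` floored
at 1e-3, component count by BIC over K = 1..6). Components pooled across
strata are compared by the Bhattacharyya coefficient and clustered
spectrally: symmetric normalized Laplacian, per-candidate embedding with
max(c, 2) eigenvectors (row-normalized), k-means, and the Tibshirani gap
statistic against uniform reference draws in the embedding, choosing the
cluster count with the largest gap (the first-local-optimum rule stops too
early on overlapping 1-D modes). Similarity graphs that fall apart into
connected components are clustered as their components. Categories are
ordered by mean; each reports the range of its member means. Membership of
an individual correlation is decided by wider assignment intervals (member
means ± one member standard deviation, truncated at midpoints between
neighbours): with desk-scale component counts the bare means-range covers
almost none of the r-axis and every pair would be uncategorized.

Composition of ABM correlations within the categories is reported two
ways: raw shares per category, and base-rate-normalized shares
(`P(category | label)` renormalized across labels). The normalized view is
the meaningful one — in a 17-prey community, competition/apparent
competition pairs outnumber specialist pairs by two orders of magnitude, so
raw shares are competition-dominated everywhere. In the benchmark study
(categories fitted on the ABM's own correlation distribution in four
run-batches), the lowest category's normalized plurality is competition and
the highest category's is specialist.

## Consensus interactions and controls

Per stratum, significant pairs are assigned to categories; a pair obtains a
consensus interaction when one category holds in a strict majority (>50%)
of the strata where the two taxa co-occur (ties yield none). Consensus
categories above the competitive category count as trophic and are compared
with a literature list (in the validation study, the planted positive pairs
play the literature's role): confirmed, missing, proposed (split by whether
the taxa appear in the literature at all), with category-1 consensus pairs
counted separately as competitive. Measured end-to-end accuracy on
guild-structured assemblages (four facies, scheme from stratum plus
aligned running-frame decompositions, background components with
sd > 0.2 excluded): ~0.85–0.9.

Two control analyses check that habitat structure does not explain the
correlations: a Yates-corrected chi-squared association between edge sign
and habitat sharing (null mean p ~0.9 on habitat-independent synthetics),
and the size-weighted Shannon equitability of habitat labels across blocks
of a hand-rolled agglomerative Bernoulli stochastic block model (ICL-style
penalty; no installed package provides SBM fitting). Equitability on
habitat-independent synthetics sits inside its label-shuffled null band.

## Problem sizes and determinism

Default study sizes: 60–100 replicate assemblages for power/recovery
rates, 40 ABM runs for the correlation benchmark, 100 paired runs for the
preference contrast, 35 × 3 corpus cases for the bias calibration, 25
replicates for planted-bias flagging, and 3 replicate assemblages for the
end-to-end consensus study. Every stochastic step takes an explicit seed;
identical seeds reproduce results bit-for-bit. The full validation battery
(`scripts/acceptance.py`) runs in a few minutes on one CPU.

## Known limitations

- The bias coefficient is a reconstruction: the exact published formula is
  not available, and the weak effect–alteration correlation at calibration
  scale means the 0.5 threshold separates severe from mild bias rather
  than measuring alteration precisely. No sample-size correction beyond
  the permutation standardization is applied.
- Undirected correlations cannot assign predator and prey roles, cannot
  separate mutualism or shared environmental response from trophic
  coupling, and the categories inherit any estimator-scale mismatch
  between fossil and benchmark correlations.
- SHE-based boundary detection needs compositional turnover; facies that
  differ only in relative abundances of a shared species pool are found by
  the ANOSIM refinement only if SHE proposes a candidate nearby.
- The ABM is a minimal grid-energy realization; its rates were chosen for
  stable coexistence and expressed trophic coupling, not fitted to any
  empirical system.
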