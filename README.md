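# cambronet

Inference of trophic and competitive interactions among fossil taxa from
stratigraphic abundance data.

Exceptionally preserved fossil sites record specimen counts of dozens of
taxa through metres of section at decimetre resolution. If two taxa
interacted — a specialist predator tracking its prey, competitors
displacing one another — their abundances should co-vary through time:
strongly and positively for specialized trophic links, weakly positively
for generalized ones, negatively for competition. `cambronet` turns that
premise into a tested pipeline:

1. **Biofacies detection** — sub-assemblage boundaries from the consensus
   of SHE biozone analysis (breaks in the accumulation-curve evenness
   decomposition `H = ln S + ln E`) and ANOSIM (permutation test on
   Bray–Curtis rank dissimilarities, `R = (r_between − r_within)/(M/2)`).
2. **Corrected correlation networks** — shrinkage-regularized partial
   correlations of `log(1+x)` counts per sub-assemblage and per running
   window; Fisher-z p-values with Benjamini–Hochberg FDR; edges are
   significantly correlated taxon pairs.
3. **Preservation-bias screening** — a coefficient on [0, 1] measuring how
   much a window's network structure aligns with a preservation-relevant
   trait factor (body type, size, habitat). The maximum-pseudo-likelihood
   ERGM attribute effect, standardized against a label-permutation null,
   is mapped through an isotonic calibration fitted on an agent-based-model
   corpus where degraded networks can be compared with their
   perfect-preservation base cases. Windows exceeding 0.5 on any factor
   are excluded.
4. **Interaction categorization** — the distribution of corrected
   correlations per stratum is decomposed into Gaussians by maximum
   likelihood (BIC-selected K); components pooled across strata are
   clustered by spectral analysis of their Bhattacharyya similarity with
   the gap statistic, yielding ordered interaction categories from
   competitive (negative r) to specialist-like (strongly positive r).
   An agent-based resource–prey–predator model with known diets supplies
   the ecological reading of each category.
5. **Consensus interactions** — a taxon pair obtains a consensus
   interaction when the same category holds in a strict majority (>50%) of
   the strata where the pair co-occurs; consensus pairs are compared with
   a literature list (confirmed / missing / proposed) and category-1 pairs
   are reported separately as putative competition.

Because real quarry data are a single fixed observation, every stage is
validated on synthetic assemblages with planted ground truth (Gaussian
copula + Poisson counts, planted facies boundaries, planted pairwise
dependencies, binomial preservation thinning) and on the agent-based
model, where the true interactions are known by construction.

## Worked example

Generate a synthetic section with a planted facies boundary at level 30,
then run ingest, network construction and biofacies detection:

```
$ cambronet synth --n-taxa 20 --n-levels 60 --boundaries 30 --seed 3 --out d1
wrote abundance.csv, traits.csv, truth.json to d1

$ cambronet ingest --abundance d1/abundance.csv --traits d1/traits.csv --bin-cm 20
levels: 30  taxa: 20  specimens: 107654
traits: 20 taxa, all four factors present

$ cambronet networks --abundance d1/abundance.csv --alpha 0.05 --out net.csv
18 taxa, 3 significant edges (lambda=0.000; 2 rare taxa excluded)

$ cambronet biofacies --abundance d1/abundance.csv --out part.json
2 sub-assemblage(s); boundaries [30]
```

The ingest step rebins the 60 raw 10 cm levels into 30 complete 20 cm bins
and reports the grand specimen total. Network construction excludes two
numerically rare taxa (present in fewer than a quarter of levels), selects
no shrinkage (the 60-level section is long enough to invert the sample
correlation matrix directly) and finds 3 edges at FDR 0.05 — planted
dependencies strong enough to survive multiple-testing control at this
section length. Biofacies detection recovers the planted boundary exactly:
two sub-assemblages, A below level 30 and B above.

The same machinery is available as a library; see `cambronet.studies` for
complete, seeded experiments (power and error-rate measurement, planted
boundary recovery, bias calibration and flagging, the ABM interaction
benchmark, end-to-end consensus accuracy).

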