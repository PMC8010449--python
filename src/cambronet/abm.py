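"""Agent-based resource-prey-predator simulation on a toroidal grid.

The model realizes a three-trophic-level community: a regrowing base
resource distributed over grid cells, a set of prey species that graze it,
and a set of predator species that consume co-located prey according to a
diet matrix.  Specialist predators have a one-prey diet; generalists eat
several prey species.  Agents random-walk on the torus, pay a metabolic
cost each step, die at zero energy and reproduce by fission above an energy
threshold.  A second variant weights each predator's prey choice by a
preference vector, so low-preference prey are consumed (and hence coupled
to the predator's abundance) more weakly.

Because the diet matrix is known, every species pair carries a ground-truth
interaction label (specialist, generalist, competition/apparent competition
or none), which downstream modules use to interpret the abundance
correlations that emerge from the simulated dynamics.  The simulator also
feeds the preservation-bias calibration: census series are binomially
thinned per species to emulate differential fossil preservation, and the
resulting network distortion is measured against the perfect-preservation
base case.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ABMConfig",
    "ABMResult",
    "ABMCorpus",
    "CorpusRecord",
    "SimulationExplosion",
    "default_diet",
    "run_abm",
    "pair_labels",
    "abm_correlations",
    "run_abm_corpus",
]


class SimulationExplosion(RuntimeError):
    """Population exceeded the configured cap; parameters are divergent."""


def default_diet(
    n_prey: int = 17,
    n_predators: int = 8,
    n_specialists: int = 4,
    generalist_diet_size: int = 5,
    seed: int = 0,
) -> dict:
    """Deterministic diet map: specialists get one prey each, generalists
    a random draw of ``generalist_diet_size`` prey."""
    n_specialists = min(n_specialists, n_predators)
    rng = np.random.default_rng(seed)
    diet = {}
    for k in range(n_specialists):
        diet[k] = (k % n_prey,)
    for k in range(n_specialists, n_predators):
        diet[k] = tuple(
            sorted(rng.choice(n_prey, size=min(generalist_diet_size, n_prey), replace=False))
        )
    return diet


@dataclass(frozen=True)
class ABMConfig:
    n_prey: int = 17
    n_predators: int = 8
    grid_side: int = 30
    resource_regrowth: float = 0.15
    resource_cap: float = 1.5
    initial_prey: int = 50  # individuals per prey species
    initial_predators: int = 25  # individuals per predator species
    initial_energy: float = 6.0
    prey_gain: float = 2.0  # energy per unit resource grazed
    predator_gain: float = 12.0  # energy per prey consumed
    bite_size: float = 1.0
    reproduction_threshold: float = 12.0
    metabolic_cost: float = 0.5
    predator_metabolic_cost: float | None = 1.5  # predators turn over faster
    diet: dict | None = None  # predator index -> tuple of prey indices
    preferences: dict | None = None  # predator -> {prey: weight}; variant 2
    immigration_rate: float = 0.1  # expected immigrants per species per step
    # slow Ornstein-Uhlenbeck fluctuation of each prey species' grazing
    # efficiency; produces long-timescale abundance waves through which
    # trophic coupling expresses as abundance correlation
    env_sigma: float = 0.12
    env_theta: float = 0.008
    steps: int = 1200
    burn_in: int = 300
    pop_cap: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.diet is None:
            object.__setattr__(
                self, "diet", default_diet(self.n_prey, self.n_predators, seed=self.seed)
            )
        for k in range(self.n_predators):
            if k not in self.diet or len(self.diet[k]) == 0:
                raise ValueError(f"predator {k} has an empty diet")
            if any(p < 0 or p >= self.n_prey for p in self.diet[k]):
                raise ValueError(f"predator {k} diet references unknown prey")
        if self.preferences is not None:
            for k in range(self.n_predators):
                w = self.preferences.get(k)
                if w is None:
                    continue
                if set(w) != set(self.diet[k]):
                    raise ValueError(f"preferences for predator {k} must cover its diet")
                vals = np.array([w[p] for p in self.diet[k]], dtype=float)
                if np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
                    raise ValueError(
                        f"preference weights for predator {k} must be non-negative "
                        "and sum to 1"
                    )
        if not self.burn_in < self.steps:
            raise ValueError("burn_in must be smaller than steps")

    @property
    def n_species(self) -> int:
        return self.n_prey + self.n_predators

    def species_names(self) -> tuple:
        return tuple(
            [f"prey_{i:02d}" for i in range(self.n_prey)]
            + [f"pred_{i:02d}" for i in range(self.n_predators)]
        )


@dataclass(frozen=True)
class ABMResult:
    config: ABMConfig
    census: np.ndarray  # (steps, n_species) integer abundances
    births: np.ndarray  # (steps, n_species)
    deaths: np.ndarray  # (steps, n_species)

    def species_names(self):
        return self.config.species_names()


def pair_labels(cfg: ABMConfig) -> dict:
    """Ground-truth interaction label for every unordered species pair.

    Predator-prey pairs in the diet are ``specialist`` (singleton diet) or
    ``generalist``; all prey-prey pairs compete for the common base resource
    (and possibly apparently through a shared predator); predator-predator
    pairs sharing at least one prey are intra-guild competitors.  All
    competitive flavours are pooled as ``competition``; everything else is
    ``none``.
    """
    labels = {}
    n_prey, n_pred = cfg.n_prey, cfg.n_predators
    diet_sets = {k: set(v) for k, v in cfg.diet.items()}
    for a in range(cfg.n_species):
        for b in range(a + 1, cfg.n_species):
            a_prey, b_prey = a < n_prey, b < n_prey
            if a_prey and b_prey:
                labels[(a, b)] = "competition"
            elif not a_prey and not b_prey:
                da, db = diet_sets[a - n_prey], diet_sets[b - n_prey]
                labels[(a, b)] = "competition" if da & db else "none"
            else:
                prey, pred = (a, b) if a_prey else (b, a)
                d = diet_sets[pred - n_prey]
                if prey in d:
                    labels[(a, b)] = "specialist" if len(d) == 1 else "generalist"
                else:
                    labels[(a, b)] = "none"
    return labels


def _grouped_accept(keys: np.ndarray, capacity: np.ndarray, rng) -> np.ndarray:
    """Accept at most ``capacity[key]`` entries per key, in random order.

    Returns a boolean mask over entries.
    """
    n = len(keys)
    if n == 0:
        return np.zeros(0, dtype=bool)
    priority = rng.permutation(n)
    order = np.lexsort((priority, keys))
    ks = keys[order]
    first = np.ones(n, dtype=bool)
    first[1:] = ks[1:] != ks[:-1]
    group_start = np.where(first, np.arange(n), 0)
    np.maximum.accumulate(group_start, out=group_start)
    rank = np.arange(n) - group_start
    accept_sorted = rank < capacity[ks]
    accept = np.zeros(n, dtype=bool)
    accept[order] = accept_sorted
    return accept


def run_abm(cfg: ABMConfig) -> ABMResult:
    """Run one simulation; bit-reproducible for a fixed (config, seed)."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.grid_side * cfg.grid_side
    n_prey, n_pred, S = cfg.n_prey, cfg.n_predators, cfg.n_species

    counts0 = [cfg.initial_prey] * n_prey + [cfg.initial_predators] * n_pred
    species = np.repeat(np.arange(S), counts0)
    n0 = len(species)
    pos = rng.integers(0, G, size=n0)
    energy = np.full(n0, float(cfg.initial_energy))
    resource = np.full(G, cfg.resource_cap, dtype=float)

    # diet as a (n_pred, n_prey) weight matrix; preferences fold in here
    diet_w = np.zeros((n_pred, n_prey))
    for k, prey_list in cfg.diet.items():
        for p in prey_list:
            if cfg.preferences is not None and k in cfg.preferences:
                diet_w[k, p] = cfg.preferences[k][p]
            else:
                diet_w[k, p] = 1.0 / len(prey_list)

    census = np.zeros((cfg.steps, S), dtype=np.int64)
    births = np.zeros((cfg.steps, S), dtype=np.int64)
    deaths = np.zeros((cfg.steps, S), dtype=np.int64)

    side = cfg.grid_side
    moves = np.array([-1, 1, -side, side])
    env = np.zeros(n_prey)  # log grazing-efficiency anomalies

    for t in range(cfg.steps):
        env += -cfg.env_theta * env + cfg.env_sigma * rng.standard_normal(n_prey)
        n = len(species)
        if n == 0:
            break
        # random walk on the torus (4-neighbourhood)
        step = moves[rng.integers(0, 4, size=n)]
        x = pos % side
        # wrap horizontal moves within the row, vertical moves within the grid
        horiz = np.abs(step) == 1
        newx = (x + step) % side
        pos = np.where(horiz, pos - x + newx, (pos + step) % G)

        is_prey = species < n_prey
        # prey graze the local resource, sharing the cell's stock equally
        prey_pos = pos[is_prey]
        if len(prey_pos):
            per_cell = np.bincount(prey_pos, minlength=G)
            with np.errstate(divide="ignore", invalid="ignore"):
                share = np.where(
                    per_cell > 0,
                    np.minimum(cfg.bite_size, resource / np.maximum(per_cell, 1)),
                    0.0,
                )
            energy[is_prey] += (
                cfg.prey_gain * share[prey_pos] * np.exp(env[species[is_prey]])
            )
            resource -= share * per_cell

        # per-cell prey availability by species
        prey_key = pos[is_prey] * n_prey + species[is_prey]
        P = np.bincount(prey_key, minlength=G * n_prey)

        killed = np.zeros(n, dtype=bool)
        pred_mask = ~is_prey
        pred_idx = np.flatnonzero(pred_mask)
        if len(pred_idx):
            pcells = pos[pred_idx]
            pspecies = species[pred_idx] - n_prey
            avail = P.reshape(G, n_prey)[pcells]  # (n_predators_alive, n_prey)
            w = avail * diet_w[pspecies]
            tot = w.sum(axis=1)
            hungry = tot > 0
            if hungry.any():
                wh = w[hungry]
                cum = np.cumsum(wh, axis=1)
                r = rng.random(hungry.sum()) * tot[hungry]
                target = (cum > r[:, None]).argmax(axis=1)
                att_pred = pred_idx[hungry]
                att_key = pos[att_pred] * n_prey + target
                accept = _grouped_accept(att_key, P, rng)
                # successful predators gain energy
                energy[att_pred[accept]] += cfg.predator_gain
                # remove exactly the accepted number of prey per (cell, species)
                kills = np.bincount(att_key[accept], minlength=G * n_prey)
                prey_agents = np.flatnonzero(is_prey)
                eaten = _grouped_accept(prey_key, kills, rng)
                killed[prey_agents[eaten]] = True

        pred_cost = (
            cfg.predator_metabolic_cost
            if cfg.predator_metabolic_cost is not None
            else cfg.metabolic_cost
        )
        energy -= np.where(is_prey, cfg.metabolic_cost, pred_cost)
        dead = killed | (energy <= 0)
        deaths[t] = np.bincount(species[dead], minlength=S)
        alive = ~dead
        species, pos, energy = species[alive], pos[alive], energy[alive]

        # fission reproduction above the energy threshold
        # immigration from an implicit regional pool keeps rare species from
        # absorbing extinction (rescue effect)
        if cfg.immigration_rate > 0:
            n_imm = rng.poisson(cfg.immigration_rate, size=S)
            tot_imm = int(n_imm.sum())
            if tot_imm:
                imm_species = np.repeat(np.arange(S), n_imm)
                species = np.concatenate([species, imm_species])
                pos = np.concatenate([pos, rng.integers(0, G, size=tot_imm)])
                energy = np.concatenate(
                    [energy, np.full(tot_imm, float(cfg.initial_energy))]
                )
                births[t] += n_imm

        rep = energy >= cfg.reproduction_threshold
        if rep.any():
            energy[rep] *= 0.5
            offspring = species[rep]
            species = np.concatenate([species, offspring])
            pos = np.concatenate([pos, pos[rep]])
            energy = np.concatenate([energy, energy[rep]])
            births[t] += np.bincount(offspring, minlength=S)

        resource = np.minimum(resource + cfg.resource_regrowth, cfg.resource_cap)
        census[t] = np.bincount(species, minlength=S)
        if len(species) > cfg.pop_cap:
            raise SimulationExplosion(
                f"population {len(species)} exceeded cap {cfg.pop_cap} at step {t}"
            )

    return ABMResult(config=cfg, census=census, births=births, deaths=deaths)


def abm_correlations(res: ABMResult, burn_in: int | None = None) -> pd.DataFrame:
    """Pearson correlations of post-burn-in abundance series, with labels.

    Pairs in which either series is constant after burn-in (e.g. extinct
    species) have undefined correlation and are dropped with a warning.
    """
    cfg = res.config
    if burn_in is None:
        burn_in = cfg.burn_in
    if burn_in >= cfg.steps:
        raise ValueError("burn_in must be smaller than steps")
    x = res.census[burn_in:].astype(float)
    sd = x.std(axis=0)
    labels = pair_labels(cfg)
    names = cfg.species_names()
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    rows, dropped = [], 0
    for (a, b), lab in labels.items():
        if sd[a] == 0 or sd[b] == 0:
            dropped += 1
            continue
        rows.append(
            {"species_a": names[a], "species_b": names[b], "label": lab,
             "r": float(corr[a, b])}
        )
    if dropped:
        warnings.warn(f"{dropped} pairs dropped (constant post-burn-in series)")
    return pd.DataFrame(rows, columns=["species_a", "species_b", "label", "r"])


@dataclass(frozen=True)
class CorpusRecord:
    """One base simulation plus its preservation-degraded copies.

    ``perfect_categories`` is a hypothetical category assignment attached to
    the retained perfect-preservation base case: it lets the calibration see
    how large the attribute effect can get by chance alone when the
    categories cause no differential preservation at all.
    """

    run_id: int
    base_census: np.ndarray  # (steps_kept, n_species)
    degraded_census: tuple  # tuple of arrays, same shape
    categories: tuple  # tuple of per-species preservation-category index arrays
    category_probs: tuple  # retention probability per category
    config: ABMConfig
    perfect_categories: tuple = ()


@dataclass(frozen=True)
class ABMCorpus:
    records: tuple

    def pairs(self, include_perfect: bool = True):
        """Yield (base_census, degraded_census, category_labels, config).

        With ``include_perfect`` the retained perfect-preservation case is
        yielded too (degraded = base), labelled by its hypothetical
        category assignment.
        """
        for rec in self.records:
            if include_perfect and rec.perfect_categories:
                yield rec.base_census, rec.base_census, rec.perfect_categories, rec.config
            for deg, cats in zip(rec.degraded_census, rec.categories):
                yield rec.base_census, deg, cats, rec.config


def _thin_census(census: np.ndarray, probs: np.ndarray, rng) -> np.ndarray:
    thinned = rng.binomial(census, probs[np.newaxis, :])
    keep = probs >= 1.0
    thinned[:, keep] = census[:, keep]
    return thinned


def run_abm_corpus(
    n_runs: int = 100,
    n_degradations_per_run: int = 5,
    base_config: ABMConfig | None = None,
    cfg_sampler=None,
    degradation_probs=(1.0, 0.05, 0.005),
    degraded_fraction_range=(0.0, 0.5),
    seed: int = 0,
    out_dir=None,
) -> ABMCorpus:
    """Simulate a corpus of (perfect, degraded) census pairs.

    Each run draws a configuration (via ``cfg_sampler(rng)`` if given,
    else jittered initial conditions around ``base_config``), simulates it,
    and produces ``n_degradations_per_run`` binomially thinned copies.  For
    each degraded copy every species is assigned independently to one of
    the preservation categories in ``degradation_probs``: with probability
    ``1 - f`` the perfectly preserved first category, else one of the two
    degraded categories, where the case's differential-bias severity ``f``
    is drawn uniformly from ``degraded_fraction_range``.  The corpus thus
    sweeps mild through severe *differential* preservation, the axis the
    bias coefficient is calibrated on.  If ``out_dir`` is given, census
    CSVs and a labels JSON are streamed there per run.
    """
    if n_runs < 1 or n_degradations_per_run < 1:
        raise ValueError("n_runs and n_degradations_per_run must be >= 1")
    rng = np.random.default_rng(seed)
    # the calibration regime: moderate populations so that the degradation
    # probabilities actually push thinned species toward the counting-noise
    # floor of the binned census (larger communities would need rescaled
    # probabilities)
    base = base_config or ABMConfig(
        grid_side=20, initial_prey=25, initial_predators=12,
        env_sigma=0.08, env_theta=0.01, steps=1200, burn_in=200,
    )
    probs = np.asarray(degradation_probs, dtype=float)
    if np.any(probs <= 0) or np.any(probs > 1):
        raise ValueError("degradation probabilities must lie in (0, 1]")
    f_lo, f_hi = degraded_fraction_range
    if not 0.0 <= f_lo <= f_hi <= 1.0:
        raise ValueError("degraded_fraction_range must be within [0, 1]")
    records = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for run in range(n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        if cfg_sampler is not None:
            cfg = cfg_sampler(np.random.default_rng(run_seed))
            cfg = replace(cfg, seed=run_seed)
        else:
            cfg = replace(
                base,
                initial_prey=int(rng.integers(max(5, base.initial_prey // 2),
                                              base.initial_prey * 2)),
                initial_predators=int(rng.integers(max(3, base.initial_predators // 2),
                                                   base.initial_predators * 2)),
                resource_cap=float(rng.uniform(0.7, 1.3) * base.resource_cap),
                seed=run_seed,
            )
        res = run_abm(cfg)
        kept = res.census[cfg.burn_in :]
        k = len(probs)

        def draw_categories():
            f = rng.uniform(f_lo, f_hi)
            weights = np.concatenate([[1.0 - f], np.full(k - 1, f / (k - 1))])
            return rng.choice(k, size=cfg.n_species, p=weights)

        degraded, categories = [], []
        for _ in range(n_degradations_per_run):
            cats = draw_categories()
            degraded.append(_thin_census(kept, probs[cats], rng))
            categories.append(tuple(int(c) for c in cats))
        rec = CorpusRecord(
            run_id=run,
            base_census=kept,
            degraded_census=tuple(degraded),
            categories=tuple(categories),
            category_probs=tuple(float(p) for p in probs),
            config=cfg,
            perfect_categories=tuple(int(c) for c in draw_categories()),
        )
        records.append(rec)
        if out_dir is not None:
            run_dir = out_dir / f"run_{run:04d}"
            run_dir.mkdir(exist_ok=True)
            names = cfg.species_names()
            pd.DataFrame(kept, columns=names).to_csv(run_dir / "census_base.csv", index=False)
            for d, (deg, cats) in enumerate(zip(degraded, rec.categories)):
                pd.DataFrame(deg, columns=names).to_csv(
                    run_dir / f"census_degraded_{d:03d}.csv", index=False
                )
            meta = {
                "labels": {f"{a},{b}": lab for (a, b), lab in pair_labels(cfg).items()},
                "categories": [list(c) for c in rec.categories],
                "category_probs": list(rec.category_probs),
                "seed": run_seed,
            }
            (run_dir / "labels.json").write_text(json.dumps(meta))
    return ABMCorpus(records=tuple(records))
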