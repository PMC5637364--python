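"""Forward-time, site-occupancy, individual-based genetic simulator.

The model is generation-stepped over a fixed set of habitat sites, each
holding at most one diploid individual with ``n_loci`` biallelic SNP
loci.  Movement (mating and natal dispersal) is driven by a site x site
least-cost matrix and a linear dispersal kernel: the probability of
moving to a candidate at cost ``c`` is proportional to
``max(0, 1 - c / budget)`` with a sex-specific cost budget.

One generation comprises, in order:

1. **Mating and reproduction** — every currently living female draws a
   Poisson(lambda) egg clutch; each egg survives birth independently with
   probability ``1 - birth_mortality``; each surviving offspring draws
   its sire independently (multiple paternity) from the males within the
   mating budget (by default the female threshold — pair formation is
   limited by the mobile sex), with linear-kernel weights.  No selfing;
   females without a reachable male produce nothing.  Inheritance is Mendelian: one
   uniformly chosen allele per locus from each parent; sex is uniform;
   the natal site is the mother's.
2. **Adult mortality** — each adult survives independently with
   probability ``1 - adult_mortality`` (default 5% carry over, keeping
   their site; survivors are sedentary).
3. **Juvenile dispersal** — juveniles are processed in uniformly random
   order; each samples one vacant site from the linear kernel over its
   sex-specific budget (the natal site is excluded unless it is the only
   reachable vacancy).  At most one settler per site; juveniles with no
   reachable vacancy die.

There is no mutation, selection, or age structure beyond the adult
carry-over, so heterozygosity decays by drift alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .analysis import ReplicateSeries
from .connectivity import CostMatrix
from .genetics import zone_summary
from .landscape import SiteSet, Zone

__all__ = [
    "SimulationParams",
    "Individual",
    "Population",
    "init_population",
    "dispersal_weights",
    "choose_mates",
    "reproduce",
    "apply_adult_mortality",
    "disperse_juveniles",
    "step",
    "run_replicates",
]

FEMALE = 0
MALE = 1


@dataclass(frozen=True)
class SimulationParams:
    """Demographic and genetic parameters of one simulation scenario.

    Defaults are the normal-dispersal parameterisation for the cabbage
    white: 500 SNP loci, female/male cost budgets of 4000/1350
    cost-metres, Poisson(300) egg clutches with 99% birth mortality, 95%
    adult mortality, 100 generations and 5 replicate runs.
    """

    n_loci: int = 500
    female_budget: float = 4000.0
    male_budget: float = 1350.0
    fecundity_lambda: float = 300.0
    birth_mortality: float = 0.99
    adult_mortality: float = 0.95
    n_generations: int = 100
    n_runs: int = 5
    dispersal_kernel: str = "linear"
    allow_philopatry_fallback: bool = True
    mate_budget: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.birth_mortality <= 1 and 0 <= self.adult_mortality <= 1):
            raise ValueError("mortalities must lie in [0, 1]")
        if self.female_budget <= 0 or self.male_budget <= 0:
            raise ValueError("budgets must be > 0")
        if self.fecundity_lambda <= 0:
            raise ValueError("fecundity lambda must be > 0")
        if self.dispersal_kernel != "linear":
            raise ValueError("only the linear kernel is implemented")

    @property
    def mating_budget(self) -> float:
        """Cost budget governing pair formation.

        Defaults to the female budget: pair formation is limited by the
        reach of the mobile sex (females roam up to their dispersal
        threshold; the separate, smaller male budget only limits where
        male offspring settle).
        """
        return self.female_budget if self.mate_budget is None else self.mate_budget

    def reduced(self) -> "SimulationParams":
        """Scenario with both dispersal budgets halved (2000/675)."""
        return replace(
            self,
            female_budget=self.female_budget / 2,
            male_budget=self.male_budget / 2,
            mate_budget=None if self.mate_budget is None else self.mate_budget / 2,
        )


@dataclass(frozen=True)
class Individual:
    """One butterfly: id, sex, home site, diploid biallelic genotype."""

    id: int
    sex: int
    site: int
    genotype: np.ndarray  # (n_loci, 2) allele indicators in {0, 1}


@dataclass
class Population:
    """Living individuals keyed by site; at most one individual per site.

    ``occupied`` marks inhabited sites; ``sex`` and ``genotypes`` are only
    meaningful where occupied.  Occupied and vacant sites partition the
    site set.
    """

    sites: SiteSet
    occupied: np.ndarray  # bool (n_sites,)
    sex: np.ndarray  # int8 (n_sites,), FEMALE/MALE
    genotypes: np.ndarray  # int8 (n_sites, n_loci, 2)
    generation: int = 0

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def size(self) -> int:
        return int(self.occupied.sum())

    @property
    def vacant(self) -> np.ndarray:
        return ~self.occupied

    def individuals(self) -> Iterator[Individual]:
        for i in np.nonzero(self.occupied)[0]:
            yield Individual(int(i), int(self.sex[i]), int(i), self.genotypes[i])

    def copy(self) -> "Population":
        return Population(
            self.sites,
            self.occupied.copy(),
            self.sex.copy(),
            self.genotypes.copy(),
            self.generation,
        )


def init_population(
    sites: SiteSet, params: SimulationParams, seed: int | np.random.Generator
) -> Population:
    """One individual per site; alleles and sexes uniform at random.

    Each allele copy is drawn independently with both alleles
    equiprobable, so the per-locus expected heterozygosity starts at its
    Hardy–Weinberg maximum of 0.5.
    """
    if len(sites) == 0:
        raise ValueError("site set must be non-empty")
    rng = np.random.default_rng(seed)
    n = len(sites)
    genotypes = rng.integers(0, 2, size=(n, params.n_loci, 2), dtype=np.int8)
    sex = rng.integers(0, 2, size=n, dtype=np.int8)
    return Population(sites, np.ones(n, dtype=bool), sex, genotypes, generation=0)


def dispersal_weights(cost_row: np.ndarray, budget: float) -> np.ndarray:
    """Linear-kernel probabilities over candidates from one origin.

    Weight ``max(0, 1 - c / budget)`` per candidate, normalised to sum 1.
    Candidates beyond the budget (including unreachable, +inf) get zero;
    if no candidate is reachable the all-zero vector is returned (empty
    distribution).  Negative costs are rejected.
    """
    if budget <= 0:
        raise ValueError("budget must be > 0")
    c = np.asarray(cost_row, dtype=float)
    if (c < 0).any():
        raise ValueError("costs must be non-negative")
    with np.errstate(invalid="ignore"):
        w = 1.0 - c / budget
    w[~np.isfinite(w)] = 0.0
    np.clip(w, 0.0, None, out=w)
    total = w.sum()
    if total > 0:
        w /= total
    return w


def _sample(p: np.ndarray, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Categorical sampling from a normalised weight vector (cumsum inversion)."""
    cdf = np.cumsum(p)
    r = rng.random(size) * cdf[-1]
    return np.searchsorted(cdf, r, side="right")


def choose_mates(
    cost_to_males: np.ndarray,
    budget: float,
    n_offspring: int,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Sire index per offspring, drawn independently (multiple paternity).

    ``cost_to_males`` are least costs from the female's site to each
    candidate male (the female herself is never a candidate); ``budget``
    is the mating-movement cost threshold.  Returns ``None`` when no
    male is reachable within it — the female then produces no offspring.
    """
    p = dispersal_weights(cost_to_males, budget)
    if p.sum() == 0:
        return None
    return _sample(p, rng, n_offspring)


def _mendel(
    mother: np.ndarray, fathers: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian inheritance: one uniform allele per locus from each parent.

    ``mother``: (L, 2); ``fathers``: (k, L, 2) one per offspring.
    Returns (k, L, 2) int8 genotypes.
    """
    k, n_loci = fathers.shape[0], fathers.shape[1]
    loci = np.arange(n_loci)
    maternal = mother[loci, rng.integers(0, 2, size=(k, n_loci))]
    paternal = fathers[
        np.arange(k)[:, None], loci[None, :], rng.integers(0, 2, size=(k, n_loci))
    ]
    return np.stack([maternal, paternal], axis=2).astype(np.int8)


@dataclass
class Juvenile:
    natal_site: int
    sex: int
    genotype: np.ndarray


def reproduce(
    mother_genotype: np.ndarray,
    sire_genotypes: np.ndarray,
    natal_site: int,
    rng: np.random.Generator,
) -> list[Juvenile]:
    """Build juveniles from a mother and the per-offspring sire genotypes."""
    k = sire_genotypes.shape[0]
    if k == 0:
        return []
    genos = _mendel(mother_genotype, sire_genotypes, rng)
    sexes = rng.integers(0, 2, size=k)
    return [Juvenile(natal_site, int(sexes[i]), genos[i]) for i in range(k)]


def apply_adult_mortality(
    population: Population, rate: float, rng: np.random.Generator
) -> Population:
    """Each adult survives independently with probability ``1 - rate``."""
    if not 0 <= rate <= 1:
        raise ValueError("mortality rate must lie in [0, 1]")
    survivors = population.copy()
    occ = np.nonzero(population.occupied)[0]
    dead = occ[rng.random(occ.size) < rate]
    survivors.occupied[dead] = False
    return survivors


def disperse_juveniles(
    juveniles: Sequence[Juvenile],
    population: Population,
    cost_matrix: CostMatrix,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Population:
    """Settle juveniles into vacant sites (in place on ``population``).

    Juveniles are processed in uniformly random order; each samples one
    currently vacant site from the linear kernel over its sex-specific
    budget.  The natal site is excluded unless it is the juvenile's only
    reachable vacancy (strict exclusion would doom isolated lineages).
    Unplaceable juveniles die.
    """
    order = rng.permutation(len(juveniles))
    costs = cost_matrix.costs
    budgets = (params.female_budget, params.male_budget)
    for j in order:
        juv = juveniles[j]
        vacant_idx = np.nonzero(~population.occupied)[0]
        if vacant_idx.size == 0:
            break
        c = costs[juv.natal_site, vacant_idx]
        budget = budgets[juv.sex]
        with np.errstate(invalid="ignore"):
            w = 1.0 - c / budget
        w[~np.isfinite(w)] = 0.0
        np.clip(w, 0.0, None, out=w)
        natal_pos = np.nonzero(vacant_idx == juv.natal_site)[0]
        if natal_pos.size:
            natal_weight = w[natal_pos[0]]
            w[natal_pos[0]] = 0.0
            if w.sum() == 0 and params.allow_philopatry_fallback:
                w[natal_pos[0]] = natal_weight
        total = w.sum()
        if total == 0:
            continue
        pick = vacant_idx[_sample(w / total, rng)[0]]
        population.occupied[pick] = True
        population.sex[pick] = juv.sex
        population.genotypes[pick] = juv.genotype
    return population


def step(
    population: Population,
    cost_matrix: CostMatrix,
    params: SimulationParams,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one generation.

    Order: mating + reproduction over all current adults, then birth
    mortality (folded into the clutch thinning), then adult mortality,
    then juvenile dispersal into the resulting vacancies.  An extinct
    population stays extinct.
    """
    costs = cost_matrix.costs
    occ = np.nonzero(population.occupied)[0]
    females = occ[population.sex[occ] == FEMALE]
    males = occ[population.sex[occ] == MALE]

    juveniles: list[Juvenile] = []
    if females.size and males.size:
        survive_birth = 1.0 - params.birth_mortality
        for f in females:
            eggs = rng.poisson(params.fecundity_lambda)
            k = rng.binomial(eggs, survive_birth) if eggs else 0
            if k == 0:
                continue
            sires = choose_mates(costs[f, males], params.mating_budget, k, rng)
            if sires is None:
                continue
            sire_sites = males[sires]
            juveniles.extend(
                reproduce(
                    population.genotypes[f],
                    population.genotypes[sire_sites],
                    int(f),
                    rng,
                )
            )

    survivors = apply_adult_mortality(population, params.adult_mortality, rng)
    survivors = disperse_juveniles(juveniles, survivors, cost_matrix, params, rng)
    survivors.generation = population.generation + 1
    return survivors


def run_replicates(
    sites: SiteSet,
    zones: Sequence[Zone],
    cost_matrix: CostMatrix,
    params: SimulationParams,
) -> ReplicateSeries:
    """Run ``params.n_runs`` independent replicates of the full simulation.

    Per-run seeds are spawned deterministically from ``params.seed``, so
    the same master seed reproduces the identical series.  Returns a
    :class:`~fraglands.analysis.ReplicateSeries` with one row per
    (zone, generation, run) — including generation 0.
    """
    rows: list[dict] = []
    children = np.random.SeedSequence(params.seed).spawn(params.n_runs)
    for run, child in enumerate(children):
        rng = np.random.default_rng(child)
        pop = init_population(sites, params, rng)
        for record in zone_summary(pop, zones, run=run):
            rows.append(_record_row(record))
        for _ in range(params.n_generations):
            pop = step(pop, cost_matrix, params, rng)
            for record in zone_summary(pop, zones, run=run):
                rows.append(_record_row(record))
    return ReplicateSeries(pd.DataFrame(rows))


def _record_row(record) -> dict:
    return {
        "zone": record.zone,
        "transect": record.transect,
        "level": record.level,
        "generation": record.generation,
        "run": record.run,
        "H_obs": record.h_obs,
        "H_exp": record.h_exp,
        "N": record.n,
    }
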