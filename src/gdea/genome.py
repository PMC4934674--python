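"""Three-gene genotype and real-coded genetic operators.

A chromosome carries three genes controlling a mirror-symmetric dot pattern:

* ``ds`` — deviation from symmetry, the distance (degrees of visual angle)
  each dot is displaced from a perfectly symmetric template; 0 is perfect
  mirror symmetry, 4.25 obliterates it.
* ``ori`` — orientation of the symmetry axis, 0 (vertical) to 90 (horizontal).
* ``bina`` — a ±1 sign; ``ori * bina`` is the actual axis angle, so the 0–90
  encoding stays perceptually monotone while still allowing left/right tilts.

Selection is tournament-based (sample 3, breed the 2 fittest), reproduction
is per-gene arithmetic blending with Gaussian mutation reflected at the gene
bounds, and each generation the offspring replace the least-fit members so
the population size stays constant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DS_BOUNDS",
    "ORI_BOUNDS",
    "Chromosome",
    "Individual",
    "Population",
    "GeneticParams",
    "InvalidConfigError",
    "UnscoredPopulationError",
    "random_chromosome",
    "init_population",
    "tournament_select",
    "crossover",
    "mutate",
    "next_generation",
    "axis_angle",
]

DS_BOUNDS = (0.0, 4.25)
ORI_BOUNDS = (0.0, 90.0)

#: provenance labels for an individual's fitness
PRESENTED = "presented"
ESTIMATED = "estimated"
UNSCORED = "offspring-unscored"


class InvalidConfigError(ValueError):
    """A structural parameter (population size, offspring count, ...) is unusable."""


class UnscoredPopulationError(RuntimeError):
    """An operation requiring fitness was applied to unscored members."""


@dataclass(frozen=True)
class Chromosome:
    """Immutable genotype: ``ds`` in [0, 4.25] deg, ``ori`` in [0, 90] deg, ``bina`` ±1."""

    ds: float
    ori: float
    bina: int

    def __post_init__(self) -> None:
        if not (DS_BOUNDS[0] <= self.ds <= DS_BOUNDS[1]):
            raise ValueError(f"ds={self.ds} outside {DS_BOUNDS}")
        if not (ORI_BOUNDS[0] <= self.ori <= ORI_BOUNDS[1]):
            raise ValueError(f"ori={self.ori} outside {ORI_BOUNDS}")
        if self.bina not in (-1, 1):
            raise ValueError(f"bina={self.bina} must be -1 or +1")


@dataclass
class Individual:
    """A population member: genotype plus (possibly unset) fitness in [0, 1]."""

    chromosome: Chromosome
    fitness: float | None = None
    provenance: str = UNSCORED

    def __post_init__(self) -> None:
        if self.fitness is not None and not (0.0 <= self.fitness <= 1.0):
            raise ValueError(f"fitness={self.fitness} outside [0, 1]")


@dataclass
class Population:
    members: list[Individual]
    generation_index: int = 1

    def __len__(self) -> int:
        return len(self.members)

    @property
    def scored(self) -> bool:
        return all(m.fitness is not None for m in self.members)


@dataclass
class GeneticParams:
    """Knobs of the reproduction step.

    Mutation adds per-gene Gaussian noise with sd equal to
    ``mutation_sigma_fraction`` of the gene range, independently with
    probability ``mutation_prob_per_gene``; out-of-range values are reflected
    back into the interval. The binary gene flips with ``bina_flip_prob``.
    """

    tournament_size: int = 3
    n_offspring: int = 32
    mutation_prob_per_gene: float = 0.1
    mutation_sigma_fraction: float = 0.05
    bina_flip_prob: float = 0.05

    def validate(self, population_size: int) -> None:
        if self.tournament_size < 2:
            raise InvalidConfigError("tournament_size must be >= 2")
        if self.n_offspring >= population_size:
            raise InvalidConfigError("n_offspring must be < population size")
        if self.n_offspring % 2 != 0 or self.n_offspring < 2:
            raise InvalidConfigError("n_offspring must be a positive even number")
        for name in ("mutation_prob_per_gene", "bina_flip_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InvalidConfigError(f"{name}={p} outside [0, 1]")
        if self.mutation_sigma_fraction < 0:
            raise InvalidConfigError("mutation_sigma_fraction must be >= 0")


def random_chromosome(rng: np.random.Generator) -> Chromosome:
    """Draw each gene uniformly over its full range; ``bina`` uniform over {-1, +1}."""
    return Chromosome(
        ds=float(rng.uniform(*DS_BOUNDS)),
        ori=float(rng.uniform(*ORI_BOUNDS)),
        bina=int(rng.choice((-1, 1))),
    )


def init_population(rng: np.random.Generator, size: int = 48) -> Population:
    """A fresh unscored population of ``size`` random genotypes (generation 1)."""
    if size < 4:
        raise InvalidConfigError(f"population size {size} < 4 (one trial's worth)")
    return Population(
        members=[Individual(random_chromosome(rng)) for _ in range(size)],
        generation_index=1,
    )


def _require_scored(pop: Population) -> None:
    if not pop.scored:
        n = sum(m.fitness is None for m in pop.members)
        raise UnscoredPopulationError(f"{n} members have unset fitness")


def tournament_select(
    pop: Population, params: GeneticParams, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Sample ``tournament_size`` members without replacement; return the two fittest.

    Fitness ties are broken in favour of the earlier population index, so the
    outcome is deterministic given the sampled indices.
    """
    _require_scored(pop)
    idx = rng.choice(len(pop.members), size=params.tournament_size, replace=False)
    ranked = sorted(idx, key=lambda i: (-pop.members[i].fitness, i))
    return pop.members[ranked[0]], pop.members[ranked[1]]


def crossover(p1: Chromosome, p2: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Per-gene arithmetic blend ``w*p1 + (1-w)*p2`` with independent w ~ U(0,1).

    ``bina`` is binary and excluded from blending: it is copied from one
    parent chosen uniformly.
    """
    w_ds, w_ori = rng.uniform(size=2)
    bina = p1.bina if rng.uniform() < 0.5 else p2.bina
    return Chromosome(
        ds=float(w_ds * p1.ds + (1.0 - w_ds) * p2.ds),
        ori=float(w_ori * p1.ori + (1.0 - w_ori) * p2.ori),
        bina=bina,
    )


def _reflect(value: float, lo: float, hi: float) -> float:
    # fold back into [lo, hi] with mirror reflection at both bounds
    width = hi - lo
    u = (value - lo) % (2.0 * width)
    return lo + (width - abs(u - width))


def mutate(c: Chromosome, params: GeneticParams, rng: np.random.Generator) -> Chromosome:
    """Gaussian perturbation per continuous gene, reflection at bounds, ±1 flip."""
    ds, ori, bina = c.ds, c.ori, c.bina
    for name, bounds in (("ds", DS_BOUNDS), ("ori", ORI_BOUNDS)):
        if rng.uniform() < params.mutation_prob_per_gene:
            sigma = params.mutation_sigma_fraction * (bounds[1] - bounds[0])
            noise = rng.normal(0.0, sigma)
            if name == "ds":
                ds = _reflect(ds + noise, *bounds)
            else:
                ori = _reflect(ori + noise, *bounds)
    if rng.uniform() < params.bina_flip_prob:
        bina = -bina
    return Chromosome(ds=ds, ori=ori, bina=bina)


def next_generation(
    pop: Population, params: GeneticParams, rng: np.random.Generator
) -> Population:
    """One generational replacement step.

    ``n_offspring/2`` tournaments each yield a parent pair; every pair
    produces two offspring via crossover + mutation. The ``n_offspring``
    lowest-fitness members are dropped and the fittest survivors are retained
    unchanged (implicit elitism), keeping the population size constant.
    """
    _require_scored(pop)
    params.validate(len(pop.members))
    offspring: list[Individual] = []
    for _ in range(params.n_offspring // 2):
        p1, p2 = tournament_select(pop, params, rng)
        for _ in range(2):
            child = mutate(crossover(p1.chromosome, p2.chromosome, rng), params, rng)
            offspring.append(Individual(child))
    # fitness ties broken by earlier index, matching tournament_select
    order = sorted(
        range(len(pop.members)), key=lambda i: (-pop.members[i].fitness, i)
    )
    keep = sorted(order[: len(pop.members) - params.n_offspring])
    survivors = [copy.deepcopy(pop.members[i]) for i in keep]
    return Population(
        members=survivors + offspring,
        generation_index=pop.generation_index + 1,
    )


def axis_angle(c: Chromosome) -> float:
    """Actual axis orientation ``ori * bina`` in signed degrees (0 vertical, ±90 horizontal)."""
    return c.ori * c.bina
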