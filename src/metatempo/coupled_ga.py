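"""Coupled genetic algorithms: two bitstring populations, each the other's
fitness function.

A predator population and a prey population of fixed-length bit genomes
play a zero-sum matching game: sampling an opponent, a predator scores the
fraction of matching bits, the prey the complement. Each population thereby
computes the selection function for the other, which is the minimal
implementation of antagonistic coevolution and produces Red Queen cycling
in mean fitness under plain tournament selection.

Two stabilization mechanisms are built in:

* **fitness memory** — each individual's selected-on fitness is an
  exponential moving average ``lambda*previous + (1-lambda)*instantaneous``
  of its encounter payoffs, inherited (as the parents' mean) by offspring,
  so a lineage remembers how well-adapted it has been in previous
  lifetimes rather than reacting to a single noisy encounter;
* **performance-coupled reproduction** — the two populations share a fixed
  total of ``2*pop_size`` offspring, split in proportion to (mean filtered
  fitness)**kappa, so an underperforming population shrinks. A population
  allotted zero offspring is extinct and the run terminates.

Fitness is evaluated by lifetime sampling: each generation every genome
meets ``lifetime_samples`` opponents drawn without replacement, the
partial-but-continuous alternative to one all-pairs end-of-life score
(which is recovered at ``lifetime_samples = pop_size``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .envstreams import ValidationError

__all__ = [
    "GAParams",
    "BitPopulation",
    "GameSpec",
    "ExtinctionEvent",
    "coupled_fitness",
    "memory_update",
    "step_generation",
    "run_coevolution",
    "best_response",
]

Role = Literal["predator", "prey"]


class ExtinctionEvent(Exception):
    """A population's offspring share reached zero; carries the role and generation."""

    def __init__(self, role: str, generation: int):
        super().__init__(f"population {role!r} went extinct at generation {generation}")
        self.role = role
        self.generation = generation


@dataclass(frozen=True)
class GAParams:
    genome_length: int = 8
    pop_size: int = 32
    mutation_rate: float = 0.01
    crossover_rate: float = 0.5
    selection: Literal["tournament_k", "proportional"] = "tournament_k"
    tournament_k: int = 2
    memory_lambda: float = 0.0
    repro_exponent: float = 0.0
    lifetime_samples: int = 8
    generations: int = 300
    seed: int = 0
    elitism: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValidationError(f"genome_length must be >= 1, got {self.genome_length!r}")
        if self.pop_size < 1:
            raise ValidationError(f"pop_size must be >= 1, got {self.pop_size!r}")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValidationError(f"mutation_rate must lie in [0, 1], got {self.mutation_rate!r}")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValidationError(f"crossover_rate must lie in [0, 1], got {self.crossover_rate!r}")
        if not (0.0 <= self.memory_lambda < 1.0):
            raise ValidationError(f"memory_lambda must lie in [0, 1), got {self.memory_lambda!r}")
        if self.repro_exponent < 0:
            raise ValidationError(f"repro_exponent must be >= 0, got {self.repro_exponent!r}")
        if self.lifetime_samples < 1:
            raise ValidationError(f"lifetime_samples must be >= 1, got {self.lifetime_samples!r}")
        if self.selection not in ("tournament_k", "proportional"):
            raise ValidationError(f"unknown selection {self.selection!r}")


@dataclass
class BitPopulation:
    """Genomes (rows of a uint8 array) plus memory-filtered fitness per genome."""

    genomes: np.ndarray  # shape (n, L), values 0/1
    filtered_fitness: np.ndarray  # shape (n,), in [0, 1]
    role: Role

    def __post_init__(self) -> None:
        self.genomes = np.asarray(self.genomes, dtype=np.uint8)
        self.filtered_fitness = np.asarray(self.filtered_fitness, dtype=float)
        if self.genomes.ndim != 2:
            raise ValidationError("genomes must be a 2-d bit array")
        if self.filtered_fitness.shape[0] != self.genomes.shape[0]:
            raise ValidationError("filtered_fitness length must match population size")
        if np.any((self.filtered_fitness < 0) | (self.filtered_fitness > 1)):
            raise ValidationError("filtered_fitness must lie in [0, 1]")

    @property
    def size(self) -> int:
        return self.genomes.shape[0]

    def diversity(self) -> float:
        """Mean pairwise Hamming distance (in bits)."""
        n = self.size
        if n < 2:
            return 0.0
        ones = self.genomes.sum(axis=0).astype(float)
        # sum over bit positions of (#ones)*(#zeros) counts each unordered
        # discordant pair once
        discordant = float(np.sum(ones * (n - ones)))
        return discordant / (n * (n - 1) / 2)

    @classmethod
    def random(cls, role: Role, pop_size: int, genome_length: int, rng: np.random.Generator) -> "BitPopulation":
        return cls(
            genomes=rng.integers(0, 2, size=(pop_size, genome_length), dtype=np.uint8),
            filtered_fitness=np.full(pop_size, 0.5),
            role=role,
        )


@dataclass(frozen=True)
class GameSpec:
    """The antagonistic encounter game; only bit matching ships.

    Predator payoff = fraction of bits matching the opponent; prey payoff
    is the complement, so every encounter is zero-sum (payoffs add to 1).
    """

    game: Literal["matching"] = "matching"

    def __post_init__(self) -> None:
        if self.game != "matching":
            raise ValidationError(f"unknown game {self.game!r}; only 'matching' is registered")

    def payoff(self, genome: np.ndarray, opponents: np.ndarray, role: Role) -> float:
        match_frac = float((genome[None, :] == opponents).mean())
        return match_frac if role == "predator" else 1.0 - match_frac


def coupled_fitness(
    genome: np.ndarray,
    role: Role,
    opposing: BitPopulation,
    game: GameSpec,
    samples: int,
    rng: np.random.Generator,
) -> float:
    """Mean payoff of one genome against ``samples`` opponents drawn without replacement."""
    if opposing.size == 0:
        raise ExtinctionEvent(opposing.role, -1)
    if samples > opposing.size:
        raise ValidationError(f"samples ({samples}) exceeds opposing population size ({opposing.size})")
    idx = rng.choice(opposing.size, size=samples, replace=False)
    return game.payoff(np.asarray(genome, dtype=np.uint8), opposing.genomes[idx], role)


def memory_update(previous_filtered, instantaneous, memory_lambda: float):
    """Exponential moving average: lambda*previous + (1-lambda)*instantaneous."""
    if not (0.0 <= memory_lambda < 1.0):
        raise ValidationError(f"memory_lambda must lie in [0, 1), got {memory_lambda!r}")
    return memory_lambda * np.asarray(previous_filtered, dtype=float) + (
        1.0 - memory_lambda
    ) * np.asarray(instantaneous, dtype=float)


def _evaluate(pop: BitPopulation, opposing: BitPopulation, game: GameSpec, samples: int, rng) -> np.ndarray:
    """Instantaneous lifetime-sampled fitness for every genome, vectorized."""
    samples = min(samples, opposing.size)
    n = pop.size
    # Independent opponent samples (without replacement) per evaluated genome.
    idx = np.array([rng.choice(opposing.size, size=samples, replace=False) for _ in range(n)])
    opp = opposing.genomes[idx]  # (n, samples, L)
    match = (pop.genomes[:, None, :] == opp).mean(axis=(1, 2))
    return match if pop.role == "predator" else 1.0 - match


def _select_parents(pop: BitPopulation, n_offspring: int, params: GAParams, rng) -> np.ndarray:
    """Indices of 2*n_offspring parents chosen on filtered fitness."""
    n_parents = 2 * n_offspring
    if params.selection == "proportional":
        weights = pop.filtered_fitness + 1e-12
        probs = weights / weights.sum()
        return rng.choice(pop.size, size=n_parents, p=probs)
    k = min(params.tournament_k, pop.size)
    entrants = rng.integers(0, pop.size, size=(n_parents, k))
    winners = entrants[np.arange(n_parents), np.argmax(pop.filtered_fitness[entrants], axis=1)]
    return winners


def _breed(pop: BitPopulation, n_offspring: int, params: GAParams, rng) -> BitPopulation:
    """Tournament selection, single-point crossover, per-bit mutation.

    Offspring inherit the mean filtered fitness of their two parents.
    """
    L = params.genome_length
    parents = _select_parents(pop, n_offspring, params, rng)
    pa, pb = parents[::2], parents[1::2]
    children = pop.genomes[pa].copy()
    other = pop.genomes[pb]

    cross = rng.random(n_offspring) < params.crossover_rate
    if L > 1:
        points = rng.integers(1, L, size=n_offspring)
    else:
        cross = np.zeros(n_offspring, dtype=bool)
        points = np.zeros(n_offspring, dtype=int)
    for i in np.nonzero(cross)[0]:
        children[i, points[i]:] = other[i, points[i]:]

    if params.mutation_rate > 0:
        flips = rng.random((n_offspring, L)) < params.mutation_rate
        children ^= flips.astype(np.uint8)

    inherited = 0.5 * (pop.filtered_fitness[pa] + pop.filtered_fitness[pb])

    if params.elitism > 0 and n_offspring >= params.elitism:
        best = np.argsort(pop.filtered_fitness)[::-1][: params.elitism]
        children[: params.elitism] = pop.genomes[best]
        inherited[: params.elitism] = pop.filtered_fitness[best]

    return BitPopulation(genomes=children, filtered_fitness=inherited, role=pop.role)


def _offspring_split(mean_pred: float, mean_prey: float, total: int, kappa: float) -> tuple[int, int]:
    """Split ``total`` offspring by relative (mean filtered fitness)**kappa."""
    if kappa == 0.0:
        return total // 2, total - total // 2
    wp = mean_pred**kappa
    wq = mean_prey**kappa
    if wp + wq == 0:
        return total // 2, total - total // 2
    n_pred = int(round(total * wp / (wp + wq)))
    return n_pred, total - n_pred


def step_generation(
    predators: BitPopulation,
    prey: BitPopulation,
    params: GAParams,
    game: GameSpec,
    rng: np.random.Generator,
    generation: int = 0,
    freeze: Role | None = None,
) -> tuple[BitPopulation, BitPopulation, dict]:
    """One coevolutionary generation.

    Evaluates lifetime-sampled coupled fitness for every genome, applies
    the memory filter, splits the conserved offspring total by the
    reproduction coupling, and breeds each population. ``freeze`` exempts
    one side from evaluation and breeding (used by the best-response
    oracle). Raises :class:`ExtinctionEvent` if a side's offspring share
    reaches zero.
    """
    if predators.size == 0:
        raise ExtinctionEvent("predator", generation)
    if prey.size == 0:
        raise ExtinctionEvent("prey", generation)

    inst_pred = _evaluate(predators, prey, game, params.lifetime_samples, rng)
    inst_prey = _evaluate(prey, predators, game, params.lifetime_samples, rng)
    pred = replace_fitness(predators, memory_update(predators.filtered_fitness, inst_pred, params.memory_lambda))
    prey_ = replace_fitness(prey, memory_update(prey.filtered_fitness, inst_prey, params.memory_lambda))

    total = 2 * params.pop_size
    n_pred, n_prey = _offspring_split(
        float(pred.filtered_fitness.mean()), float(prey_.filtered_fitness.mean()), total, params.repro_exponent
    )
    stats = {
        "generation": generation,
        "meanfit_pred": float(inst_pred.mean()),
        "meanfit_prey": float(inst_prey.mean()),
        "filtered_pred": float(pred.filtered_fitness.mean()),
        "filtered_prey": float(prey_.filtered_fitness.mean()),
        "div_pred": pred.diversity(),
        "div_prey": prey_.diversity(),
        "size_pred": n_pred,
        "size_prey": n_prey,
        "rate_pred": n_pred / predators.size,
        "rate_prey": n_prey / prey.size,
    }
    if freeze != "predator":
        if n_pred == 0:
            raise ExtinctionEvent("predator", generation)
        new_pred = _breed(pred, n_pred, params, rng)
    else:
        new_pred = pred
    if freeze != "prey":
        if n_prey == 0:
            raise ExtinctionEvent("prey", generation)
        new_prey = _breed(prey_, n_prey, params, rng)
    else:
        new_prey = prey_
    return new_pred, new_prey, stats


def replace_fitness(pop: BitPopulation, filtered: np.ndarray) -> BitPopulation:
    return BitPopulation(genomes=pop.genomes, filtered_fitness=np.clip(filtered, 0.0, 1.0), role=pop.role)


def run_coevolution(
    params: GAParams,
    game: GameSpec | None = None,
    seed: int | None = None,
    freeze: Role | None = None,
    init_predators: BitPopulation | None = None,
    init_prey: BitPopulation | None = None,
) -> tuple[pd.DataFrame, dict, BitPopulation, BitPopulation]:
    """Run the coupled GA for ``params.generations`` or until extinction.

    Returns the per-generation series, an outcome summary
    (``{"status": "completed" | "extinct:<role>", ...}``) and the final
    populations. Extinction is an outcome, not an exception, at this level.
    """
    game = game or GameSpec()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    predators = init_predators or BitPopulation.random("predator", params.pop_size, params.genome_length, rng)
    prey = init_prey or BitPopulation.random("prey", params.pop_size, params.genome_length, rng)

    rows: list[dict] = []
    status = "completed"
    for gen in range(params.generations):
        try:
            predators, prey, stats = step_generation(
                predators, prey, params, game, rng, generation=gen, freeze=freeze
            )
        except ExtinctionEvent as ev:
            status = f"extinct:{ev.role}"
            break
        rows.append(stats)
    series = pd.DataFrame(rows)
    outcome = {
        "status": status,
        "generations_run": len(rows),
        "final_meanfit_pred": float(series["meanfit_pred"].iloc[-1]) if len(rows) else float("nan"),
        "final_meanfit_prey": float(series["meanfit_prey"].iloc[-1]) if len(rows) else float("nan"),
    }
    return series, outcome, predators, prey


def best_response(opposing: BitPopulation, role: Role, game: GameSpec | None = None) -> np.ndarray:
    """Exhaustive best response of ``role`` to a fixed opposing population.

    For the matching game this is, per bit position, the majority bit of
    the opposing population (predator) or its complement (prey); computed
    by direct expected-payoff maximization over bits, which is exact
    because the payoff is additive over positions.
    """
    game = game or GameSpec()
    ones_frac = opposing.genomes.mean(axis=0)
    if role == "predator":
        return (ones_frac >= 0.5).astype(np.uint8)
    return (ones_frac < 0.5).astype(np.uint8)
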