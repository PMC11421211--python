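"""Directed-evolution simulation on NK landscapes.

A population of P cells, each carrying G genes (length-N site vectors),
evolves by rounds of mutation, fitness evaluation, and a configurable
selection policy.  All randomness flows through explicit splittable keys,
so a (config, root seed) pair fully determines every trace, and replicate
runs use independent child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ..engine import RngKey, split_key
from .landscape import NKLandscape, cell_fitness, make_landscape

__all__ = [
    "Population",
    "EvolutionTrace",
    "EvolveConfig",
    "Truncation",
    "Tournament",
    "Uniform",
    "init_population",
    "mutate",
    "select",
    "evolve",
    "compare_policies",
]


@dataclass(frozen=True)
class Population:
    """P cells × G genes × N sites, with an optional cached fitness per cell."""

    genes: np.ndarray  # (P, G, N) int
    generation: int = 0
    fitness: np.ndarray | None = None  # (P,) cache, None when stale

    @property
    def size(self) -> int:
        return self.genes.shape[0]


@dataclass(frozen=True)
class EvolutionTrace:
    """Per-generation population statistics (index 0 is the initial state)."""

    best: np.ndarray
    mean: np.ndarray
    min: np.ndarray
    policy: str
    root_seed_path: tuple[int, ...]

    @property
    def best_ever(self) -> float:
        return float(self.best.max())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(len(self.best)),
                "best": self.best,
                "mean": self.mean,
                "min": self.min,
            }
        )


# ---------------------------------------------------------------------------
# selection policies


@dataclass(frozen=True)
class Truncation:
    """Keep the top ceil(q*P) cells by fitness (ties to the lower index) and
    refill the remaining slots by uniform resampling with replacement from the
    survivors."""

    q: float = 0.1

    def __str__(self) -> str:
        return f"truncation(q={self.q:g})"


@dataclass(frozen=True)
class Tournament:
    """Fill each of P slots with the fittest of k uniformly drawn cells.

    ``exhaustive=True`` makes every tournament draw the whole population
    (a deterministic argmax; intended for tests of the degenerate case).
    """

    k: int = 2
    exhaustive: bool = False

    def __str__(self) -> str:
        return f"tournament(k={self.k})"


@dataclass(frozen=True)
class Uniform:
    """Neutral policy: resample P cells uniformly with replacement."""

    def __str__(self) -> str:
        return "uniform"


SelectionPolicy = Truncation | Tournament | Uniform


def init_population(land: NKLandscape, P: int, G: int, key: RngKey) -> Population:
    if P < 1 or G < 1:
        raise ValueError("population size P and genes-per-cell G must be >= 1")
    rng = key.generator()
    genes = rng.integers(0, land.A, size=(P, G, land.N), dtype=np.int64)
    return Population(genes=genes, generation=0)


def mutate(pop: Population, mu: float, A: int, key: RngKey) -> Population:
    """Independently per gene, with probability ``mu`` substitute one uniformly
    chosen site with one of the A-1 other symbols.  Fitness caches of mutated
    cells are invalidated."""
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mutation probability mu must lie in [0, 1]")
    P, G, N = pop.genes.shape
    rng = key.generator()
    hit = rng.random((P, G)) < mu
    sites = rng.integers(0, N, size=(P, G))
    offsets = rng.integers(1, A, size=(P, G))
    genes = pop.genes.copy()
    p_idx, g_idx = np.nonzero(hit)
    s_idx = sites[p_idx, g_idx]
    old = genes[p_idx, g_idx, s_idx]
    genes[p_idx, g_idx, s_idx] = (old + offsets[p_idx, g_idx]) % A
    fitness = None
    if pop.fitness is not None:
        fitness = pop.fitness.copy()
        fitness[hit.any(axis=1)] = np.nan  # stale
    return replace(pop, genes=genes, fitness=fitness)


def evaluate(land: NKLandscape, pop: Population) -> Population:
    fit = np.asarray(cell_fitness(land, pop.genes))
    return replace(pop, fitness=fit)


def select(pop: Population, fitnesses: np.ndarray, policy: SelectionPolicy, key: RngKey) -> Population:
    """Apply a selection policy, returning a population of the same size."""
    P = pop.size
    fitnesses = np.asarray(fitnesses)
    if fitnesses.shape != (P,):
        raise ValueError("fitnesses must align with the population")
    rng = key.generator()
    if isinstance(policy, Truncation):
        n_keep = int(np.ceil(policy.q * P))
        if n_keep < 1:
            raise ValueError(f"truncation q={policy.q} keeps no survivors for P={P}")
        order = np.argsort(-fitnesses, kind="stable")  # ties -> lower index first
        survivors = order[:n_keep]
        refill = survivors[rng.integers(0, n_keep, size=P - n_keep)]
        chosen = np.concatenate([survivors, refill])
    elif isinstance(policy, Tournament):
        if policy.k < 1:
            raise ValueError("tournament size k must be >= 1")
        if policy.exhaustive:
            cand = np.broadcast_to(np.arange(P), (P, P))
        else:
            cand = rng.integers(0, P, size=(P, policy.k))
        # winner = candidate with max fitness; ties to the lower cell index
        cand_fit = fitnesses[cand]
        winner_slot = np.argmax(cand_fit, axis=1)
        chosen = cand[np.arange(cand.shape[0]), winner_slot]
    elif isinstance(policy, Uniform):
        chosen = rng.integers(0, P, size=P)
    else:
        raise TypeError(f"unknown selection policy: {policy!r}")
    fit = fitnesses[chosen]
    return Population(genes=pop.genes[chosen].copy(), generation=pop.generation + 1, fitness=fit)


@dataclass(frozen=True)
class EvolveConfig:
    P: int = 100
    G: int = 1
    mu: float = 0.5
    policy: SelectionPolicy = field(default_factory=Truncation)
    generations: int = 50
    steps_per_iteration: int = 1  # mutation steps per selection round


def evolve(land: NKLandscape, config: EvolveConfig, key: RngKey) -> EvolutionTrace:
    """Run mutation → evaluation → selection for ``generations`` rounds.

    Statistics are recorded from the evaluated (post-mutation, pre-selection)
    population each round, plus the initial population, so the trace has
    ``generations + 1`` entries and its running max is the best fitness ever
    evaluated.
    """
    if config.generations < 1:
        raise ValueError("generations must be >= 1")
    pop = init_population(land, config.P, config.G, key.child(0))
    pop = evaluate(land, pop)
    best = [float(pop.fitness.max())]
    mean = [float(pop.fitness.mean())]
    mn = [float(pop.fitness.min())]
    for g in range(config.generations):
        gen_key = key.child(g + 1)
        for step in range(config.steps_per_iteration):
            pop = mutate(pop, config.mu, land.A, gen_key.child(step))
        pop = evaluate(land, pop)
        best.append(float(pop.fitness.max()))
        mean.append(float(pop.fitness.mean()))
        mn.append(float(pop.fitness.min()))
        pop = select(pop, pop.fitness, config.policy, gen_key.child(config.steps_per_iteration))
    return EvolutionTrace(
        best=np.asarray(best), mean=np.asarray(mean), min=np.asarray(mn),
        policy=str(config.policy), root_seed_path=key.seed_path,
    )


def compare_policies(
    N: int,
    K: int,
    A: int,
    policies: Sequence[SelectionPolicy],
    replicates: int,
    key: RngKey,
    config: EvolveConfig | None = None,
    *,
    fixed_landscape: bool = False,
) -> pd.DataFrame:
    """Mean ± SE of final best fitness per policy over seeded replicates.

    Each (policy, replicate) pair draws a fresh landscape seed and population
    seed from split child keys, so the landscape itself is part of the
    randomness being averaged over; ``fixed_landscape=True`` reuses one
    landscape across all runs instead.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    config = config or EvolveConfig()
    land_fixed = make_landscape(N, K, A, seed=int(key.child(0).word0 % 2**31)) if fixed_landscape else None
    rows = []
    for p_i, policy in enumerate(policies):
        pol_key = key.child(p_i + 1)
        finals = []
        for r, rep_key in enumerate(split_key(pol_key, replicates)):
            if land_fixed is not None:
                land = land_fixed
            else:
                land = make_landscape(N, K, A, seed=int(rep_key.child(0).word0 % 2**31))
            trace = evolve(land, replace(config, policy=policy), rep_key.child(1))
            finals.append(trace.best[-1])
            rows.append({
                "policy": str(policy), "policy_index": p_i, "replicate": r,
                "final_best": trace.best[-1],
            })
    df = pd.DataFrame(rows)
    summary = (
        df.groupby(["policy_index", "policy"], sort=True)["final_best"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0,
             n="count")
        .reset_index()
    )
    summary.attrs["per_run"] = df
    return summary
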