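"""Population-level evolution of regulatory networks with polycomb silencing.

An *individual* is one genotype expressed in two cells, each developing in
its own fixed environment toward an environment-specific optimal phenotype.
A population of M individuals, founded by clones of a single developmentally
stable founder, iterates selection -> recombination -> mutation ->
development every generation. Fitness combines stabilizing and directional
selection on the joint L1 distance D of both cells' steady states from
their optima:

    Omega = (exp(-D / s) + max(0, 1 - a * D))**2,
    D = (|S1 - S1_opt|_1 + |S2 - S2_opt|_1) / (2 N).

Offspring whose development fails to reach steady state in either
environment are lethal and discarded. The PRE matrix theta starts all-zero
(no gene under polycomb control) and evolves by random 0/1 flips, so any
silencing present at the end of evolution is an emergent product of
selection.

The population is stored as stacked arrays (one leading axis over
individuals) so each generation's development runs as a single vectorized
batch; :class:`Population` also offers a per-individual object view.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .dynamics import (
    BatchDevelopment,
    DevelopmentParams,
    DevelopmentResult,
    RegulatoryGenotype,
    develop_batch,
)

__all__ = [
    "EvolutionWorld",
    "EvolutionConfig",
    "Individual",
    "Population",
    "GenerationStats",
    "EvolutionResult",
    "make_environments",
    "make_founder",
    "distance_D",
    "fitness",
    "recombine",
    "mutate",
    "evolve_generation",
    "evolve",
]


@dataclass
class EvolutionWorld:
    """The fixed stage on which a population evolves.

    Two binary environments (Hamming-separated by a fraction ``delta_e`` of
    positions), the two optimal phenotypes (the env-1 optimum is the
    founder's own steady state there; the env-2 optimum is random but at
    least ``delta_s`` away per gene on average), and the initial expression
    vectors used for development in each environment.
    """

    env1: np.ndarray
    env2: np.ndarray
    s_opt1: np.ndarray
    s_opt2: np.ndarray
    init1: np.ndarray
    init2: np.ndarray
    delta_e: float
    delta_s: float

    @property
    def n_genes(self) -> int:
        return self.s_opt1.shape[0]


@dataclass(frozen=True)
class EvolutionConfig:
    """All knobs of an evolution run.

    mu is the per-nonzero-weight replacement probability per generation;
    mu_theta (defaults to mu) is the per-entry 0<->1 flip probability of the
    PRE matrix. ``evolve_theta=False`` is the no-polycomb control in which
    theta stays identically zero. ``selection_mode='stabilizing_only'``
    drops the directional term from the fitness.
    """

    n_genes: int = 10
    n_prcs: int = 2
    pop_size: int = 200
    generations: int = 1000
    connectivity: float = 0.75
    weight_scale: float = 1.2
    mu: float = 0.01
    mu_theta: float | None = 0.015
    s: float = 0.3
    a: float = 1.0
    delta_e: float = 0.1
    delta_s: float = 0.2
    evolve_theta: bool = True
    selection_mode: str = "both"
    seed: int | None = None
    dev: DevelopmentParams = field(default_factory=DevelopmentParams)
    checkpoints: tuple[int, ...] = (50,)
    founder_attempts: int = 2000
    offspring_attempts: int = 50

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be at least 2")
        for name in ("mu", "connectivity", "delta_e"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mu_theta is not None and not 0 <= self.mu_theta <= 1:
            raise ValueError("mu_theta must lie in [0, 1]")
        if self.s <= 0 or self.a <= 0:
            raise ValueError("selection strengths s and a must be positive")
        if self.selection_mode not in ("both", "stabilizing_only"):
            raise ValueError("selection_mode must be 'both' or 'stabilizing_only'")

    @property
    def theta_rate(self) -> float:
        return self.mu if self.mu_theta is None else self.mu_theta


@dataclass
class Individual:
    """Object view of one population member: genotype, two developed cells, fitness."""

    genotype: RegulatoryGenotype
    dev1: DevelopmentResult
    dev2: DevelopmentResult
    fitness: float


@dataclass
class Population:
    """Stacked-array population of M individuals sharing one world.

    ``w_gg`` (M,N,N), ``w_ge`` (M,N,N), ``theta`` (M,N,P) are the genotypes;
    ``s1``/``s2`` (M,N) the developed steady states in env 1/2;
    ``silenced_by1``/``silenced_by2`` (M,N,P) the silencing attributions;
    ``fitness`` (M,).
    """

    w_gg: np.ndarray
    w_ge: np.ndarray
    theta: np.ndarray
    s1: np.ndarray
    s2: np.ndarray
    silenced_by1: np.ndarray
    silenced_by2: np.ndarray
    fitness: np.ndarray

    @property
    def size(self) -> int:
        return self.w_gg.shape[0]

    @property
    def silenced1(self) -> np.ndarray:
        return self.silenced_by1.any(axis=2)

    @property
    def silenced2(self) -> np.ndarray:
        return self.silenced_by2.any(axis=2)

    def genotype(self, i: int) -> RegulatoryGenotype:
        return RegulatoryGenotype(
            self.w_gg[i].copy(), self.w_ge[i].copy(), self.theta[i].copy()
        )

    def individuals(self) -> Iterable[Individual]:
        for i in range(self.size):
            yield Individual(
                genotype=self.genotype(i),
                dev1=_dev_view(self.s1[i], self.silenced_by1[i]),
                dev2=_dev_view(self.s2[i], self.silenced_by2[i]),
                fitness=float(self.fitness[i]),
            )

    def copy(self) -> "Population":
        return Population(*(getattr(self, f).copy() for f in (
            "w_gg", "w_ge", "theta", "s1", "s2",
            "silenced_by1", "silenced_by2", "fitness")))


def _dev_view(state: np.ndarray, silenced_by: np.ndarray) -> DevelopmentResult:
    return DevelopmentResult(
        final_state=state.copy(), stable=True, steps=-1,
        silenced=silenced_by.any(axis=1), silenced_by=silenced_by.copy(),
        trajectory_tail=np.repeat(state[None], 1, axis=0),
    )


@dataclass
class GenerationStats:
    """Per-generation aggregates over the (stable) population."""

    generation: int
    mean_fitness: float
    mean_dist1: float          # mean L1(S1, opt1)/N
    mean_dist2: float
    fitness_env1: float        # Omega applied to env-1's share of D
    fitness_env2: float
    repressed1: float          # mean genes silenced during env-1 development
    repressed2: float
    eff_connectivity1: float   # mean effective in-degree after removing silenced genes
    eff_connectivity2: float
    lethal: int                # unstable offspring discarded while filling M slots


@dataclass
class EvolutionResult:
    world: EvolutionWorld
    population: Population
    stats: list[GenerationStats]
    checkpoints: dict[int, Population]
    config: EvolutionConfig

    def stats_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s) for s in self.stats])


# ---------------------------------------------------------------------------
# world and founder construction
# ---------------------------------------------------------------------------

def make_environments(n: int, delta_e: float, rng: np.random.Generator):
    """Two binary environment vectors differing at round(delta_e * n) positions."""
    if not 0 <= delta_e <= 1:
        raise ValueError("delta_e must lie in [0, 1]")
    env1 = rng.integers(0, 2, size=n).astype(float)
    k = int(round(delta_e * n))
    flip = rng.choice(n, size=k, replace=False)
    env2 = env1.copy()
    env2[flip] = 1.0 - env2[flip]
    return env1, env2


def _random_weights(n: int, connectivity: float, rng: np.random.Generator,
                    scale: float = 1.0) -> np.ndarray:
    """n x n matrix with exactly round(c * n^2) nonzero Gaussian entries."""
    k = int(round(connectivity * n * n))
    w = np.zeros(n * n)
    pos = rng.choice(n * n, size=k, replace=False)
    w[pos] = scale * rng.standard_normal(k)
    return w.reshape(n, n)


def make_founder(config: EvolutionConfig, rng: np.random.Generator):
    """Rejection-sample a developmentally stable founder and its world.

    theta starts all-zero (no polycomb control before evolution). The env-1
    optimum is the founder's steady state in env 1; the env-2 optimum is a
    random binary vector (an extreme expression pattern, the natural target
    of saturating sigmoid dynamics) redrawn until its mean absolute
    difference from the env-1 optimum is at least delta_s.
    """
    n, p = config.n_genes, config.n_prcs
    theta = np.zeros((n, p), dtype=bool)
    for _ in range(config.founder_attempts):
        env1, env2 = make_environments(n, config.delta_e, rng)
        w_gg = _random_weights(n, config.connectivity, rng, config.weight_scale)
        w_ge = _random_weights(n, config.connectivity, rng, config.weight_scale)
        init1 = rng.random(n)
        init2 = rng.random(n)
        batch = develop_batch(
            np.stack([w_gg, w_gg]), np.stack([w_ge, w_ge]),
            np.stack([theta, theta]), np.stack([env1, env2]),
            np.stack([init1, init2]), config.dev,
        )
        if batch.stable.all():
            break
    else:
        raise RuntimeError(
            f"no developmentally stable founder found in {config.founder_attempts} "
            "attempts (constraint: stable development in both environments)"
        )
    s_opt1 = batch.final[0].copy()
    for _ in range(config.founder_attempts):
        s_opt2 = rng.integers(0, 2, size=n).astype(float)
        if np.abs(s_opt2 - s_opt1).mean() >= config.delta_s:
            break
    else:
        raise RuntimeError(
            "could not draw an env-2 optimum satisfying the delta_s separation"
        )
    genotype = RegulatoryGenotype(w_gg, w_ge, theta.copy(), config.connectivity)
    world = EvolutionWorld(
        env1=env1, env2=env2, s_opt1=s_opt1, s_opt2=s_opt2,
        init1=init1, init2=init2,
        delta_e=config.delta_e, delta_s=config.delta_s,
    )
    return genotype, world


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

def distance_D(s1, s2, s_opt1, s_opt2) -> float:
    """Joint normalized L1 distance from both optima: in [0, 1] for states in [0, 1]."""
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    s_opt1, s_opt2 = np.asarray(s_opt1, float), np.asarray(s_opt2, float)
    if s1.shape[-1] != s_opt1.shape[-1] or s2.shape[-1] != s_opt2.shape[-1]:
        raise ValueError("phenotype/optimum length mismatch")
    n = s1.shape[-1]
    return (np.abs(s1 - s_opt1).sum(axis=-1) + np.abs(s2 - s_opt2).sum(axis=-1)) / (2 * n)


def fitness(D, s: float, a: float, mode: str = "both"):
    """Selection function Omega(D); Omega(0) = 4, strictly decreasing in D."""
    D = np.asarray(D, dtype=float)
    stab = np.exp(-D / s)
    if mode == "stabilizing_only":
        total = stab
    else:
        total = stab + np.maximum(0.0, 1.0 - a * D)
    out = total ** 2
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# variation
# ---------------------------------------------------------------------------

def recombine(parent_a: RegulatoryGenotype, parent_b: RegulatoryGenotype,
              rng: np.random.Generator) -> RegulatoryGenotype:
    """Row-wise sexual recombination.

    For each gene the offspring inherits that gene's regulatory-input row of
    W_GG, W_GE and its PRE row of theta jointly from one parent chosen with
    probability 1/2, keeping each gene's cis-context intact.
    """
    if parent_a.w_gg.shape != parent_b.w_gg.shape:
        raise ValueError("parents must have identical dimensions")
    rows = rng.random(parent_a.n_genes) < 0.5
    pick = lambda a, b: np.where(rows[:, None], a, b)
    return RegulatoryGenotype(
        pick(parent_a.w_gg, parent_b.w_gg),
        pick(parent_a.w_ge, parent_b.w_ge),
        pick(parent_a.theta, parent_b.theta),
    )


def mutate(genotype: RegulatoryGenotype, mu: float, mu_theta: float,
           evolve_theta: bool, rng: np.random.Generator) -> RegulatoryGenotype:
    """Return a mutated copy; the input genotype is left untouched.

    Each *nonzero* weight is independently replaced by a fresh standard
    normal draw with probability mu (the sparsity pattern is immutable).
    Each theta entry flips with probability mu_theta when theta evolution is
    enabled.
    """
    g = genotype.copy()
    for w in (g.w_gg, g.w_ge):
        hit = (w != 0) & (rng.random(w.shape) < mu)
        w[hit] = rng.standard_normal(int(hit.sum()))
    if evolve_theta and mu_theta > 0:
        flip = rng.random(g.theta.shape) < mu_theta
        g.theta = g.theta ^ flip
    return g


# ---------------------------------------------------------------------------
# the generational cycle
# ---------------------------------------------------------------------------

def _develop_population(w_gg, w_ge, theta, world: EvolutionWorld,
                        params: DevelopmentParams):
    b = w_gg.shape[0]
    d1 = develop_batch(w_gg, w_ge, theta, world.env1,
                       np.broadcast_to(world.init1, (b, world.n_genes)), params)
    d2 = develop_batch(w_gg, w_ge, theta, world.env2,
                       np.broadcast_to(world.init2, (b, world.n_genes)), params)
    return d1, d2


def _population_fitness(s1, s2, world, config):
    D = distance_D(s1, s2, world.s_opt1, world.s_opt2)
    return fitness(D, config.s, config.a, config.selection_mode)


def evolve_generation(pop: Population, world: EvolutionWorld,
                      config: EvolutionConfig, rng: np.random.Generator,
                      generation: int = 0):
    """One cycle of selection, recombination, mutation and development.

    Parents are drawn with replacement, with probability proportional to
    fitness (selfing permitted); offspring are produced in vectorized
    batches until M developmentally stable ones are collected.
    """
    m, n, p = config.pop_size, config.n_genes, config.n_prcs
    total = pop.fitness.sum()
    probs = pop.fitness / total if total > 0 else np.full(pop.size, 1.0 / pop.size)

    need = m
    lethal = 0
    parts: list[tuple] = []
    for _ in range(config.offspring_attempts):
        b = max(need + max(4, need // 5), 8)
        ia = rng.choice(pop.size, size=b, p=probs)
        ib = rng.choice(pop.size, size=b, p=probs)
        rows = rng.random((b, n)) < 0.5
        r3 = rows[:, :, None]
        w_gg = np.where(r3, pop.w_gg[ia], pop.w_gg[ib])
        w_ge = np.where(r3, pop.w_ge[ia], pop.w_ge[ib])
        theta = np.where(r3, pop.theta[ia], pop.theta[ib])
        for w in (w_gg, w_ge):
            hit = (w != 0) & (rng.random(w.shape) < config.mu)
            w[hit] = config.weight_scale * rng.standard_normal(int(hit.sum()))
        if config.evolve_theta and config.theta_rate > 0:
            theta = theta ^ (rng.random(theta.shape) < config.theta_rate)
        d1, d2 = _develop_population(w_gg, w_ge, theta, world, config.dev)
        ok = d1.stable & d2.stable
        lethal += int(b - ok.sum())
        keep = np.flatnonzero(ok)[:need]
        if keep.size:
            parts.append((w_gg[keep], w_ge[keep], theta[keep],
                          d1.final[keep], d2.final[keep],
                          d1.silenced_by[keep], d2.silenced_by[keep]))
            need -= keep.size
        if need == 0:
            break
    else:
        raise RuntimeError(
            f"could not collect {m} stable offspring within "
            f"{config.offspring_attempts} batches (lethal rate too high)"
        )

    stacked = [np.concatenate(x) for x in zip(*parts)]
    w_gg, w_ge, theta, s1, s2, sb1, sb2 = stacked
    fit = _population_fitness(s1, s2, world, config)
    new_pop = Population(w_gg, w_ge, theta, s1, s2, sb1, sb2, fit)
    stats = _generation_stats(new_pop, world, config, generation, lethal)
    return new_pop, stats


def _effective_in_degree(w_gg, silenced):
    """Mean in-degree of the nonzero pattern after deleting silenced genes."""
    adj = w_gg != 0
    alive = ~silenced
    sub = adj & alive[:, :, None] & alive[:, None, :]
    n_alive = alive.sum(axis=1)
    edges = sub.sum(axis=(1, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        deg = np.where(n_alive > 0, edges / np.maximum(n_alive, 1), 0.0)
    return deg


def _generation_stats(pop: Population, world: EvolutionWorld,
                      config: EvolutionConfig, generation: int,
                      lethal: int) -> GenerationStats:
    n = config.n_genes
    l1_1 = np.abs(pop.s1 - world.s_opt1).sum(axis=1)
    l1_2 = np.abs(pop.s2 - world.s_opt2).sum(axis=1)
    f1 = fitness(l1_1 / (2 * n), config.s, config.a, config.selection_mode)
    f2 = fitness(l1_2 / (2 * n), config.s, config.a, config.selection_mode)
    return GenerationStats(
        generation=generation,
        mean_fitness=float(pop.fitness.mean()),
        mean_dist1=float((l1_1 / n).mean()),
        mean_dist2=float((l1_2 / n).mean()),
        fitness_env1=float(np.mean(f1)),
        fitness_env2=float(np.mean(f2)),
        repressed1=float(pop.silenced1.sum(axis=1).mean()),
        repressed2=float(pop.silenced2.sum(axis=1).mean()),
        eff_connectivity1=float(_effective_in_degree(pop.w_gg, pop.silenced1).mean()),
        eff_connectivity2=float(_effective_in_degree(pop.w_gg, pop.silenced2).mean()),
        lethal=lethal,
    )


def _clone_population(genotype: RegulatoryGenotype, world: EvolutionWorld,
                      config: EvolutionConfig) -> Population:
    m = config.pop_size
    d1, d2 = _develop_population(
        genotype.w_gg[None], genotype.w_ge[None], genotype.theta[None],
        world, config.dev)
    tile = lambda x: np.repeat(x, m, axis=0)
    s1, s2 = tile(d1.final), tile(d2.final)
    fit = _population_fitness(s1, s2, world, config)
    return Population(
        tile(genotype.w_gg[None]), tile(genotype.w_ge[None]),
        tile(genotype.theta[None]),
        s1, s2, tile(d1.silenced_by), tile(d2.silenced_by), fit,
    )


def evolve(config: EvolutionConfig,
           rng: np.random.Generator | None = None,
           world: EvolutionWorld | None = None,
           population: Population | None = None,
           start_generation: int = 0,
           progress: bool = False) -> EvolutionResult:
    """Run a full evolution: founder construction plus G generational cycles.

    Fully reproducible from ``config.seed``. Checkpoint copies of the
    population are retained at the generations listed in
    ``config.checkpoints`` (the final generation is always kept as the
    result population). A saved run can be resumed by passing ``world``,
    ``population`` and ``start_generation`` together with the archived RNG.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    stats: list[GenerationStats] = []
    checkpoints: dict[int, Population] = {}
    if population is None:
        founder, world = make_founder(config, rng)
        population = _clone_population(founder, world, config)
        stats.append(_generation_stats(population, world, config, 0, 0))
    elif world is None:
        raise ValueError("resuming requires both population and world")
    for g in range(start_generation + 1, config.generations + 1):
        population, st = evolve_generation(population, world, config, rng, g)
        stats.append(st)
        if g in config.checkpoints:
            checkpoints[g] = population.copy()
        if progress and g % 50 == 0:
            print(f"  generation {g}: mean fitness {st.mean_fitness:.3f}, "
                  f"repressed(env1) {st.repressed1:.2f}", flush=True)
    return EvolutionResult(world=world, population=population, stats=stats,
                           checkpoints=checkpoints, config=config)
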