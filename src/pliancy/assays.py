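"""Post-developmental transfer and PRC-breaking assays; pliancy scoring.

The four assay conditions for a developed individual are:

a. developed in environment 1, polycomb intact;
b. developed in environment 2, polycomb intact;
c. developed in environment 1, then post-developmentally transferred to
   environment 2 with polycomb intact;
d. as (c) but with a chosen subset of PRCs broken.

A transfer continues the dynamics from the developed steady state under the
new environment. Silencing decided during development persists, except that
a gene is released when *every* PRC responsible for silencing it is broken;
no new silencing can occur post-developmentally. An individual is pliant at
gene i when the broken-transfer state sits closer to the env-2 phenotype
than both half the a-b separation and the intact-transfer state:

    |S_d_i - S_b_i| < 1/2 |S_a_i - S_b_i|   and   |S_d_i - S_b_i| < |S_c_i - S_b_i|

(strict inequalities, so with no PRC broken the score is exactly 0). The
pliancy score of a cell is the fraction of its N genes that are pliant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (
    DevelopmentParams,
    DevelopmentResult,
    RegulatoryGenotype,
    develop,
    develop_batch,
)
from .evolution import EvolutionWorld, Population

__all__ = [
    "PliancyAssayResult",
    "transfer",
    "gene_pliant",
    "pliancy_assay",
    "population_transfer",
    "population_pliancy",
    "sustained_pliancy",
    "effective_connectivity",
    "repressed_gene_count",
]


def _broken_mask(broken_prcs, n_prcs: int) -> np.ndarray:
    mask = np.zeros(n_prcs, dtype=bool)
    idx = sorted(broken_prcs)
    if idx and (min(idx) < 0 or max(idx) >= n_prcs):
        raise ValueError(f"PRC index out of range for {n_prcs} PRCs: {idx}")
    mask[idx] = True
    return mask


def transfer(dev: DevelopmentResult, genotype: RegulatoryGenotype,
             new_env: np.ndarray, broken_prcs=(),
             params: DevelopmentParams | None = None) -> tuple[np.ndarray, bool]:
    """Continue a developed cell's dynamics in a new environment.

    Returns the new steady state and its stability flag. A gene stays
    silenced iff at least one PRC that silenced it remains intact.
    """
    if not dev.stable:
        raise ValueError("transfer requires a developmentally stable cell")
    params = params or DevelopmentParams()
    broken = _broken_mask(broken_prcs, genotype.n_prcs)
    still = (dev.silenced_by & ~broken[None, :]).any(axis=1)
    res = develop(genotype, new_env, dev.final_state, params,
                  silenced=still, allow_silencing=False)
    return res.final_state, res.stable


def gene_pliant(s_a, s_b, s_c, s_d) -> bool | np.ndarray:
    """Gene-level pliancy criterion (strict in both inequalities)."""
    s_a, s_b, s_c, s_d = map(np.asarray, (s_a, s_b, s_c, s_d))
    d_db = np.abs(s_d - s_b)
    out = (d_db < 0.5 * np.abs(s_a - s_b)) & (d_db < np.abs(s_c - s_b))
    return bool(out) if out.ndim == 0 else out


@dataclass
class PliancyAssayResult:
    """Phenotypes of the four conditions plus per-gene flags and the score."""

    s_a: np.ndarray
    s_b: np.ndarray
    s_c: np.ndarray
    s_d: np.ndarray
    stable: dict[str, bool]
    gene_pliant: np.ndarray | None
    score: float | None
    broken_prcs: tuple[int, ...]

    @property
    def valid(self) -> bool:
        return all(self.stable.values())


def pliancy_assay(genotype: RegulatoryGenotype, world: EvolutionWorld,
                  broken_prcs=(), params: DevelopmentParams | None = None
                  ) -> PliancyAssayResult:
    """Run all four assay conditions for one genotype.

    Gene flags and the score are ``None`` unless every condition reached a
    steady state.
    """
    params = params or DevelopmentParams()
    dev1 = develop(genotype, world.env1, world.init1, params)
    dev2 = develop(genotype, world.env2, world.init2, params)
    s_c, ok_c = (np.full(genotype.n_genes, np.nan), False)
    s_d, ok_d = (np.full(genotype.n_genes, np.nan), False)
    if dev1.stable:
        s_c, ok_c = transfer(dev1, genotype, world.env2, (), params)
        s_d, ok_d = transfer(dev1, genotype, world.env2, broken_prcs, params)
    stable = {"a": dev1.stable, "b": dev2.stable, "c": ok_c, "d": ok_d}
    flags = score = None
    if all(stable.values()):
        flags = gene_pliant(dev1.final_state, dev2.final_state, s_c, s_d)
        score = float(flags.mean())
    return PliancyAssayResult(
        s_a=dev1.final_state, s_b=dev2.final_state, s_c=s_c, s_d=s_d,
        stable=stable, gene_pliant=flags, score=score,
        broken_prcs=tuple(sorted(broken_prcs)),
    )


def population_transfer(pop: Population, world: EvolutionWorld,
                        broken_prcs=(), params: DevelopmentParams | None = None,
                        from_env: int = 1):
    """Vectorized transfer of every cell in a population to the other environment.

    Returns the batch development outcome of the continuation. ``from_env``
    selects which developed cell is moved (1: env1 -> env2, 2: env2 -> env1).
    """
    params = params or DevelopmentParams()
    broken = _broken_mask(broken_prcs, pop.theta.shape[2])
    if from_env == 1:
        start, sil_by, new_env = pop.s1, pop.silenced_by1, world.env2
    elif from_env == 2:
        start, sil_by, new_env = pop.s2, pop.silenced_by2, world.env1
    else:
        raise ValueError("from_env must be 1 or 2")
    still = (sil_by & ~broken[None, None, :]).any(axis=2)
    return develop_batch(pop.w_gg, pop.w_ge, pop.theta, new_env, start,
                         params, silenced=still, allow_silencing=False)


def population_pliancy(pop: Population, world: EvolutionWorld,
                       params: DevelopmentParams | None = None,
                       break_sets: dict | None = None) -> dict:
    """Mean pliancy score and instability fraction per break set.

    By default assays breaking PRC a alone, PRC b alone and both (for a
    2-PRC model; with more PRCs the defaults are each singleton plus the
    full set). Conditions a and b reuse the population's stored developed
    states; condition c (intact transfer) is shared across break sets.

    Returns a dict mapping break-set name to a dict with keys ``score``
    (mean over cells whose four conditions are all stable), ``scores``
    (per-cell array, NaN where invalid), ``frac_unstable`` (fraction of
    cells whose broken transfer failed to stabilize) and
    ``frac_unstable_intact``.
    """
    params = params or DevelopmentParams()
    n_prcs = pop.theta.shape[2]
    if break_sets is None:
        names = "abcdefghij"
        break_sets = {names[j]: (j,) for j in range(n_prcs)}
        break_sets["+".join(names[:n_prcs])] = tuple(range(n_prcs))
    intact = population_transfer(pop, world, (), params)
    out = {}
    for name, prcs in break_sets.items():
        broken = population_transfer(pop, world, prcs, params)
        valid = intact.stable & broken.stable
        pl = gene_pliant(pop.s1, pop.s2, intact.final, broken.final)
        scores = np.where(valid, pl.mean(axis=1), np.nan)
        out[name] = {
            "broken_prcs": tuple(prcs),
            "score": float(np.nanmean(scores)) if valid.any() else np.nan,
            "scores": scores,
            "frac_unstable": float(1.0 - broken.stable.mean()),
            "frac_unstable_intact": float(1.0 - intact.stable.mean()),
        }
    return out


def sustained_pliancy(genotype: RegulatoryGenotype, world: EvolutionWorld,
                      broken_prcs=(), params: DevelopmentParams | None = None
                      ) -> dict:
    """Transfer env1 -> env2 -> env1 with a fixed broken set.

    Checks that phenotypic switching is repeatable rather than a one-way
    escape: a pliant cell moved back to environment 1 should return toward
    its original env-1 phenotype. Returns the three steady states, their
    stability flags, and L1 distances of each stage to the reference
    phenotypes S_a (developed in env 1) and S_b (developed in env 2).
    """
    params = params or DevelopmentParams()
    dev1 = develop(genotype, world.env1, world.init1, params)
    dev2 = develop(genotype, world.env2, world.init2, params)
    if not (dev1.stable and dev2.stable):
        raise ValueError("sustained-pliancy assay requires stable development")
    broken = _broken_mask(broken_prcs, genotype.n_prcs)
    still = (dev1.silenced_by & ~broken[None, :]).any(axis=1)
    fwd = develop(genotype, world.env2, dev1.final_state, params,
                  silenced=still, allow_silencing=False)
    back = develop(genotype, world.env1, fwd.final_state, params,
                   silenced=still, allow_silencing=False)
    s_a, s_b = dev1.final_state, dev2.final_state
    states = [dev1.final_state, fwd.final_state, back.final_state]
    return {
        "states": states,
        "stable": [dev1.stable, fwd.stable, back.stable],
        "dist_to_a": [float(np.abs(s - s_a).sum()) for s in states],
        "dist_to_b": [float(np.abs(s - s_b).sum()) for s in states],
        "broken_prcs": tuple(sorted(broken_prcs)),
    }


def effective_connectivity(genotype: RegulatoryGenotype, silenced_set=(),
                           subset=None, effective: bool = True
                           ) -> tuple[float, float]:
    """Mean in/out degree of the regulatory network's nonzero pattern.

    With ``effective=True`` the silenced genes' rows and columns are deleted
    first (the network with its polycomb holes punched out). With
    ``effective=False`` the plain pre-deletion connectivity is returned,
    optionally restricted to a gene ``subset`` — used to compare repressed
    PRC targets against other genes on the original network.
    """
    adj = genotype.w_gg != 0
    n = genotype.n_genes
    silenced = np.zeros(n, dtype=bool)
    silenced[list(silenced_set)] = True
    if effective:
        alive = ~silenced
        if not alive.any():
            return 0.0, 0.0
        sub = adj[np.ix_(alive, alive)]
        rows = np.arange(int(alive.sum()))
    else:
        sub = adj
        rows = np.arange(n) if subset is None else np.asarray(sorted(subset), int)
        if rows.size == 0:
            return 0.0, 0.0
    mean_in = float(sub[rows, :].sum(axis=1).mean())
    mean_out = float(sub[:, rows].sum(axis=0).mean())
    return mean_in, mean_out


def repressed_gene_count(dev: DevelopmentResult) -> int:
    """Number of genes silenced by at least one PRC during development."""
    return int(dev.silenced_by.any(axis=1).sum())
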