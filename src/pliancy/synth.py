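"""Synthetic labeled expression matrices and simulation-phenotype export.

:func:`synth_expression` emulates the population structure the empirical
analytics assume: three cell populations on a log-expression scale whose
metastatic centroid sits between the primary and normal centroids, with
per-cell heterogeneity in how far each metastatic cell has moved (a latent
pliancy u_c), and designated "polycomb" genes whose expression in
metastatic cells drops in proportion to that movement. This gives the
z-score regression genuine signal when the polycomb effect beta is
positive, and none when beta = 0.

:func:`export_sim_phenotypes` bridges the evolutionary simulator to these
analytics by laying out the four assay-condition phenotypes of every
individual in a population as a labeled matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import population_transfer
from .dynamics import DevelopmentParams
from .empirical import LabeledExpressionMatrix
from .evolution import EvolutionWorld, Population

__all__ = ["SynthExprConfig", "synth_expression", "export_sim_phenotypes"]


@dataclass(frozen=True)
class SynthExprConfig:
    """Generator settings.

    lam : metastatic centroid position between primary (0) and normal (1).
    beta : strength of the link between designated polycomb-gene
        down-regulation and a cell's movement toward normal (log-expression
        units per unit of latent pliancy).
    noise : standard deviation of Gaussian noise on log-scale expression.
    spread : standard deviation of the per-gene population centroids.
    """

    n_genes: int = 2000
    n_primary: int = 300
    n_metastatic: int = 300
    n_normal_primary: int = 150
    n_normal_met: int = 150
    lam: float = 0.8
    beta: float = 2.0
    n_polycomb: int = 53
    noise: float = 1.0
    spread: float = 2.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        for f in ("n_primary", "n_metastatic", "n_normal_primary", "n_normal_met"):
            if getattr(self, f) < 2:
                raise ValueError(f"{f} must be at least 2")
        if not 0 < self.n_polycomb <= self.n_genes:
            raise ValueError("n_polycomb must lie in (0, n_genes]")


def synth_expression(config: SynthExprConfig,
                     rng: np.random.Generator | None = None,
                     fixed_u: float | None = None) -> LabeledExpressionMatrix:
    """Generate a labeled log-scale expression matrix.

    Per-gene primary and normal centroids are independent Gaussians. Each
    metastatic cell draws a latent pliancy u_c ~ Uniform(0, 1) (or the
    constant ``fixed_u``) and is centered at
    ``(1 - lam*u_c) * primary + lam*u_c * normal`` plus Gaussian noise;
    the designated polycomb genes are additionally down-shifted by
    ``beta * u_c`` in metastatic cells. Normal cells at both sites share
    one centroid.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    g, lam = config.n_genes, config.lam
    genes = pd.Index([f"g{i:05d}" for i in range(g)], name="gene")
    mu_p = rng.normal(0.0, config.spread, g)
    mu_n = rng.normal(0.0, config.spread, g)
    pc_idx = rng.choice(g, size=config.n_polycomb, replace=False)
    polycomb = np.zeros(g, dtype=bool)
    polycomb[pc_idx] = True

    blocks, labels, ids = [], [], []

    def add(name, count, centers):
        blocks.append(centers + rng.normal(0.0, config.noise, (g, count)))
        labels.extend([name] * count)
        ids.extend(f"{name}_{i:04d}" for i in range(count))

    add("primary", config.n_primary, mu_p[:, None])
    u = (np.full(config.n_metastatic, fixed_u) if fixed_u is not None
         else rng.random(config.n_metastatic))
    met_centers = (1 - lam * u)[None, :] * mu_p[:, None] + (lam * u)[None, :] * mu_n[:, None]
    met_centers = met_centers - config.beta * u[None, :] * polycomb[:, None]
    add("metastatic", config.n_metastatic, met_centers)
    add("normal_primary_site", config.n_normal_primary, mu_n[:, None])
    add("normal_met_site", config.n_normal_met, mu_n[:, None])

    cells = pd.Index(ids, name="cell")
    values = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=cells)
    return LabeledExpressionMatrix(
        values=values,
        cell_category=pd.Series(labels, index=cells),
        polycomb=pd.Series(polycomb, index=genes),
    )


def export_sim_phenotypes(pop: Population, world: EvolutionWorld,
                          broken_prcs=None,
                          params: DevelopmentParams | None = None
                          ) -> LabeledExpressionMatrix:
    """Lay out the four assay-condition phenotypes of a population as a matrix.

    Columns are cells (4 per individual, one per condition), labeled
    ``env1_intact`` (a), ``env2_intact`` (b), ``transfer_intact`` (c) and
    ``transfer_broken`` (d); rows are the model's N genes. ``broken_prcs``
    defaults to all PRCs. Suitable for PCA / centroid-distance analyses of
    the simulated data; no polycomb flag applies to model genes, so the
    flags are all False.
    """
    params = params or DevelopmentParams()
    if broken_prcs is None:
        broken_prcs = tuple(range(pop.theta.shape[2]))
    intact = population_transfer(pop, world, (), params)
    broken = population_transfer(pop, world, broken_prcs, params)
    m, n = pop.size, pop.w_gg.shape[1]
    conds = [("env1_intact", pop.s1), ("env2_intact", pop.s2),
             ("transfer_intact", intact.final), ("transfer_broken", broken.final)]
    genes = pd.Index([f"gene{i}" for i in range(n)], name="gene")
    blocks, labels, ids = [], [], []
    for name, states in conds:
        blocks.append(states.T)
        labels += [name] * m
        ids += [f"ind{i:04d}_{name}" for i in range(m)]
    cells = pd.Index(ids, name="cell")
    values = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=cells)
    return LabeledExpressionMatrix(
        values=values,
        cell_category=pd.Series(labels, index=cells),
        polycomb=pd.Series(False, index=genes),
    )
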