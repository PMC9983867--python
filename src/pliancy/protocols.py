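"""Reusable study protocols built from the core primitives.

These wrap the multi-population experiments used to quantify the model's
headline behaviors: the post-break instability census and the
broken-vs-intact pliancy comparison across a parameter sweep.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
from scipy import stats

from .assays import population_pliancy, population_transfer
from .dynamics import DevelopmentParams
from .evolution import EvolutionConfig, EvolutionResult, evolve

__all__ = ["post_break_instability", "break_vs_intact_sweep", "spawn_seeds"]


def spawn_seeds(seed: int, n: int) -> list[int]:
    """n child seeds (< 2**31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(n)]


def post_break_instability(n_populations: int = 10, seed: int = 0,
                           config: EvolutionConfig | None = None,
                           progress: bool = False) -> dict:
    """Evolve populations and census post-break developmental instability.

    For each evolved population, every cell developed in environment 1 is
    transferred to environment 2 with each break set ({PRC a}, {PRC b},
    {both}) lifted, and the fraction failing to re-reach steady state is
    recorded. Returns per-break-set fractions, the pooled fraction over all
    break sets and populations, and per-population pliancy summaries.
    """
    base = config or EvolutionConfig()
    seeds = spawn_seeds(seed, n_populations)
    counts = {"a": 0, "b": 0, "a+b": 0}
    cells = 0
    pliancy_rows = []
    results: list[EvolutionResult] = []
    for i, s in enumerate(seeds):
        cfg = dataclasses.replace(base, seed=s)
        res = evolve(cfg)
        results.append(res)
        scores = population_pliancy(res.population, res.world, cfg.dev)
        for name in counts:
            counts[name] += int(round(scores[name]["frac_unstable"]
                                      * res.population.size))
        cells += res.population.size
        pliancy_rows.append({k: v["score"] for k, v in scores.items()})
        if progress:
            print(f"  population {i + 1}/{n_populations} done", flush=True)
    per_set = {k: counts[k] / cells for k in counts}
    pooled = sum(counts.values()) / (3 * cells)
    return {
        "per_break_set": per_set,
        "pooled_fraction": pooled,
        "n_cells": cells,
        "pliancy": pliancy_rows,
        "results": results,
        "seeds": seeds,
    }


def break_vs_intact_sweep(seed: int = 0,
                          connectivities=(0.6, 0.75),
                          mutation_rates=(0.005, 0.01),
                          env_differences=(0.1, 0.2),
                          gammas=(0.4, 0.5),
                          founders_per_setting: int = 10,
                          pop_size: int = 50,
                          generations: int = 150,
                          progress: bool = False) -> dict:
    """Percent pliant cells, broken vs intact, across a parameter grid.

    A cell counts as pliant when its pliancy score is positive (at least
    one gene meets the pliancy criteria). With no PRC broken the score is
    identically zero by construction, so the intact column is a genuine
    computation, not an assumption. Each grid setting is summarized by the
    percent of pliant cells pooled over ``founders_per_setting`` short
    evolutions from independent random founders; the paired one-sided
    Wilcoxon signed-rank test across settings asks whether breakage
    increases the pliant percentage.
    """
    grid = list(itertools.product(connectivities, mutation_rates,
                                  env_differences, gammas))
    seeds = spawn_seeds(seed, len(grid) * founders_per_setting)
    rows = []
    k = 0
    for (c, mu, de, gam) in grid:
        broken_pliant = intact_pliant = total = 0
        for _ in range(founders_per_setting):
            cfg = EvolutionConfig(
                pop_size=pop_size, generations=generations, connectivity=c,
                mu=mu, delta_e=de, dev=DevelopmentParams(gamma=gam),
                seed=seeds[k], checkpoints=())
            k += 1
            res = evolve(cfg)
            scores = population_pliancy(
                res.population, res.world, cfg.dev,
                break_sets={"intact": (), "both": tuple(range(cfg.n_prcs))})
            for name, bucket in (("both", "broken"), ("intact", "intact")):
                s = scores[name]["scores"]
                n_pliant = int(np.nansum(s > 0))
                if bucket == "broken":
                    broken_pliant += n_pliant
                else:
                    intact_pliant += n_pliant
            total += res.population.size
        rows.append({
            "connectivity": c, "mu": mu, "delta_e": de, "gamma": gam,
            "pct_pliant_broken": 100.0 * broken_pliant / total,
            "pct_pliant_intact": 100.0 * intact_pliant / total,
        })
        if progress:
            print(f"  setting {len(rows)}/{len(grid)}: broken "
                  f"{rows[-1]['pct_pliant_broken']:.1f}% vs intact "
                  f"{rows[-1]['pct_pliant_intact']:.1f}%", flush=True)
    broken = np.array([r["pct_pliant_broken"] for r in rows])
    intact = np.array([r["pct_pliant_intact"] for r in rows])
    test = stats.wilcoxon(broken, intact, alternative="greater")
    return {
        "settings": rows,
        "pvalue": float(test.pvalue),
        "mean_pct_broken": float(broken.mean()),
        "mean_pct_intact": float(intact.mean()),
    }
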