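import numpy as np
import pandas as pd
import pytest

import pliancy as pl
from pliancy.dynamics import DevelopmentParams
from pliancy.empirical import LabeledExpressionMatrix
from pliancy.synth import SynthExprConfig, synth_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_run():
    """A short, cheap evolution shared by unit tests (not the acceptance scale)."""
    cfg = pl.EvolutionConfig(pop_size=60, generations=200, seed=11,
                             checkpoints=(50,))
    return pl.evolve(cfg)


@pytest.fixture(scope="session")
def synth_matrix():
    return synth_expression(SynthExprConfig(seed=42))


@pytest.fixture
def tiny_matrix():
    """Hand-sized labeled matrix: 3 genes x 8 cells, values chosen by hand."""
    genes = pd.Index(["g1", "g2", "g3"], name="gene")
    cells = pd.Index([f"c{i}" for i in range(8)], name="cell")
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0, 5.0, 0.0, 1.0, 2.0],
         [4.0, 4.0, 2.0, 2.0, 0.0, 6.0, 6.0, 5.0],
         [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]],
        index=genes, columns=cells)
    cats = pd.Series(["primary", "primary", "metastatic", "metastatic",
                      "metastatic", "normal_primary_site", "normal_met_site",
                      "normal_met_site"], index=cells)
    pc = pd.Series([False, False, True], index=genes)
    return LabeledExpressionMatrix(values=values, cell_category=cats, polycomb=pc)


def naive_develop(w_gg, w_ge, theta, env, init, params: DevelopmentParams):
    """Independent scalar-loop reimplementation of development.

    Deliberately avoids the package's vectorized code path: explicit per-gene
    loops, math on float64 scalars, and its own window bookkeeping. Returns
    (final_state, stable, steps, silenced_mask, silenced_by).
    """
    n = len(init)
    p = len(theta[0])
    s = [float(x) for x in init]
    silenced = [False] * n
    silenced_by = [[False] * p for _ in range(n)]
    history = []
    for t in range(1, params.max_steps + 1):
        new = []
        for i in range(n):
            if silenced[i]:
                new.append(0.0)
                continue
            acc_g = 0.0
            for j in range(n):
                acc_g += w_gg[i][j] * s[j]
            acc_e = 0.0
            for j in range(n):
                acc_e += w_ge[i][j] * env[j]
            acc = acc_g + acc_e
            new.append(float(1.0 / (1.0 + np.exp(-np.float64(acc)))))
        s = new
        if t == params.t_c:
            for i in range(n):
                has_pre = any(theta[i][j] for j in range(p))
                if has_pre and not silenced[i] and s[i] < params.gamma:
                    silenced[i] = True
                    s[i] = 0.0
                    for j in range(p):
                        if theta[i][j]:
                            silenced_by[i][j] = True
        history.append(list(s))
        if t >= params.window:
            tail = history[-params.window:]
            total = 0.0
            for i in range(n):
                vals = [row[i] for row in tail]
                m = sum(vals) / len(vals)
                total += sum((v - m) ** 2 for v in vals) / len(vals)
            if total / n < params.epsilon:
                return s, True, t, silenced, silenced_by
    return s, False, params.max_steps, silenced, silenced_by
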