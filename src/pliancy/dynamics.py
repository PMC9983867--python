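"""Deterministic developmental dynamics of a single regulatory network cell.

A cell is a Wagner-style gene regulatory network: an expression state vector
``S_G`` of length ``N`` updated in discrete time by a sigmoidal map of the
summed genetic (``W_GG @ S_G``) and environmental (``W_GE @ S_E``) inputs.
Polycomb-like silencing is a one-time checkpoint: at the critical
developmental time ``t_c`` every gene that carries a Polycomb response
element (a 1 in the PRE matrix ``theta``) and is expressed below the
threshold ``gamma`` is permanently silenced — its expression is pinned to 0
for the rest of the trajectory, removing its outgoing influence from the
network. Development ends when the trajectory is stationary: the per-gene
variance over a trailing window of states, averaged over genes, drops below
``epsilon``. Cells that never meet the criterion within ``max_steps`` are
developmentally unstable ("lethal").

All heavy lifting is done by :func:`develop_batch`, which develops a stack
of cells in lockstep; :func:`develop` is the single-cell wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "RegulatoryGenotype",
    "DevelopmentParams",
    "DevelopmentResult",
    "BatchDevelopment",
    "sigmoid",
    "step",
    "stability_measure",
    "develop",
    "develop_batch",
]


def sigmoid(x):
    """Standard logistic function 1 / (1 + exp(-x)), range (0, 1)."""
    return expit(x)


@dataclass
class RegulatoryGenotype:
    """Heritable unit: gene-gene weights, gene-environment weights, PRE matrix.

    Parameters
    ----------
    w_gg : (N, N) array
        Entry ``(i, j)`` is the effect of the product of gene ``j`` on gene
        ``i``.
    w_ge : (N, E) array, E = N
        Effect of each environmental factor on each gene.
    theta : (N, P) binary array
        ``theta[i, j] = 1`` iff gene ``i`` carries a PRE for polycomb
        repressive complex ``j`` (i.e. is silenceable by PRC ``j``).
    connectivity : float, optional
        Fraction of nonzero entries used when the genotype was generated;
        informational only.
    """

    w_gg: np.ndarray
    w_ge: np.ndarray
    theta: np.ndarray
    connectivity: float | None = None

    def __post_init__(self):
        self.w_gg = np.asarray(self.w_gg, dtype=float)
        self.w_ge = np.asarray(self.w_ge, dtype=float)
        self.theta = np.asarray(self.theta)
        n = self.w_gg.shape[0]
        if self.w_gg.shape != (n, n):
            raise ValueError(f"w_gg must be square, got {self.w_gg.shape}")
        if self.w_ge.shape[0] != n:
            raise ValueError("w_ge row count must match gene count")
        if self.theta.shape[0] != n:
            raise ValueError("theta row count must match gene count")
        if not np.isin(self.theta, (0, 1)).all():
            raise ValueError("theta entries must be 0 or 1")
        self.theta = self.theta.astype(bool)

    @property
    def n_genes(self) -> int:
        return self.w_gg.shape[0]

    @property
    def n_prcs(self) -> int:
        return self.theta.shape[1]

    def copy(self) -> "RegulatoryGenotype":
        return RegulatoryGenotype(
            self.w_gg.copy(), self.w_ge.copy(), self.theta.copy(), self.connectivity
        )


@dataclass(frozen=True)
class DevelopmentParams:
    """Parameters of the developmental iteration.

    gamma : silencing threshold in expression units (0 < gamma < 1).
    t_c : critical time step at which the one-time silencing decision is made.
    epsilon : stability tolerance on the windowed variance measure.
    max_steps : iteration cap; exceeding it marks the cell unstable.
    window : trailing window length for the stability measure.
    """

    gamma: float = 0.5
    t_c: int = 10
    epsilon: float = 1e-4
    max_steps: int = 100
    window: int = 10

    def __post_init__(self):
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0 < self.t_c < self.max_steps:
            raise ValueError("t_c must lie in (0, max_steps)")
        if self.window > self.max_steps:
            raise ValueError("window cannot exceed max_steps")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class DevelopmentResult:
    """Outcome of developing one cell.

    ``silenced_by`` is an (N, P) boolean matrix: entry ``(i, j)`` is True iff
    gene ``i`` was silenced and PRC ``j`` is responsible (it targeted gene
    ``i`` at the silencing checkpoint). Unsilenced genes have an all-False
    row.
    """

    final_state: np.ndarray
    stable: bool
    steps: int
    silenced: np.ndarray
    silenced_by: np.ndarray
    trajectory_tail: np.ndarray

    def silenced_prcs(self, gene: int) -> set[int]:
        """Set of PRC indices responsible for silencing ``gene`` (empty if none)."""
        return {int(j) for j in np.flatnonzero(self.silenced_by[gene])}

    @property
    def n_repressed(self) -> int:
        return int(self.silenced_by.any(axis=1).sum())


@dataclass
class BatchDevelopment:
    """Vectorized development outcome for a stack of B cells."""

    final: np.ndarray        # (B, N)
    stable: np.ndarray       # (B,) bool
    steps: np.ndarray        # (B,) int
    silenced: np.ndarray     # (B, N) bool
    silenced_by: np.ndarray  # (B, N, P) bool
    tail: np.ndarray         # (window, B, N), chronological

    def __getitem__(self, b: int) -> DevelopmentResult:
        return DevelopmentResult(
            final_state=self.final[b].copy(),
            stable=bool(self.stable[b]),
            steps=int(self.steps[b]),
            silenced=self.silenced[b].copy(),
            silenced_by=self.silenced_by[b].copy(),
            trajectory_tail=self.tail[:, b, :].copy(),
        )


def step(state: np.ndarray, genotype: RegulatoryGenotype, env: np.ndarray,
         silenced: np.ndarray | None = None) -> np.ndarray:
    """One synchronous update: S <- sigmoid(W_GG @ S + W_GE @ S_E).

    Genes flagged in ``silenced`` are held at exactly 0; the mask itself is
    never modified here.
    """
    state = np.asarray(state, dtype=float)
    env = np.asarray(env, dtype=float)
    if state.shape[0] != genotype.n_genes:
        raise ValueError("state length does not match gene count")
    if env.shape[0] != genotype.w_ge.shape[1]:
        raise ValueError("environment length does not match w_ge")
    out = sigmoid(genotype.w_gg @ state + genotype.w_ge @ env)
    if silenced is not None:
        out = np.where(silenced, 0.0, out)
    return out


def stability_measure(tail: Sequence[np.ndarray] | np.ndarray) -> float:
    """Normalized variance of the trailing trajectory window.

    Per-gene population variance across the window, averaged over genes:
    dimensionless in N and exactly 0 iff every gene is constant.
    """
    arr = np.asarray(tail, dtype=float)
    if arr.ndim != 2:
        raise ValueError("tail must be a (window, N) stack of states")
    return float(arr.var(axis=0).mean())


def develop_batch(
    w_gg: np.ndarray,
    w_ge: np.ndarray,
    theta: np.ndarray,
    env: np.ndarray,
    init: np.ndarray,
    params: DevelopmentParams,
    silenced: np.ndarray | None = None,
    allow_silencing: bool = True,
) -> BatchDevelopment:
    """Develop B cells in lockstep.

    Parameters
    ----------
    w_gg, w_ge : (B, N, N) stacks of weight matrices.
    theta : (B, N, P) boolean PRE stack.
    env : (N,) or (B, N) binary environment state(s).
    init : (B, N) initial expression states.
    silenced : optional (B, N) boolean mask of genes already silenced (used
        by post-developmental transfer); silenced genes stay at exactly 0.
    allow_silencing : if False the t_c checkpoint is skipped entirely (no new
        silencing can occur; this is the post-developmental regime).

    Notes
    -----
    The silencing decision is evaluated exactly once, immediately after the
    update at t = t_c: each not-yet-silenced gene with at least one PRE and
    expression below gamma is pinned to 0, and every PRC targeting it is
    recorded as responsible. Cells are frozen at their first stable step so
    their reported state is the one at which the criterion was met.
    """
    w_gg = np.asarray(w_gg, dtype=float)
    w_ge = np.asarray(w_ge, dtype=float)
    theta = np.asarray(theta).astype(bool)
    B, N = w_gg.shape[0], w_gg.shape[1]
    P = theta.shape[2]
    env = np.asarray(env, dtype=float)
    if env.ndim == 1:
        h = w_ge @ env                       # (B, N): environmental drive
    else:
        h = np.einsum("bij,bj->bi", w_ge, env)

    S = np.array(init, dtype=float)
    if S.shape != (B, N):
        raise ValueError(f"init must have shape {(B, N)}, got {S.shape}")
    if silenced is None:
        sil = np.zeros((B, N), dtype=bool)
    else:
        sil = np.array(silenced, dtype=bool)
    S[sil] = 0.0
    silenced_by = np.zeros((B, N, P), dtype=bool)

    win = params.window
    buf = np.empty((win, B, N))
    done = np.zeros(B, dtype=bool)
    steps = np.full(B, params.max_steps, dtype=int)
    final = S.copy()

    for t in range(1, params.max_steps + 1):
        S_new = expit(np.einsum("bij,bj->bi", w_gg, S) + h)
        S_new[sil] = 0.0
        # frozen cells keep their recorded final state
        S = np.where(done[:, None], final, S_new)
        if allow_silencing and t == params.t_c:
            hit = (~done[:, None]) & (~sil) & theta.any(axis=2) & (S < params.gamma)
            silenced_by |= theta & hit[:, :, None]
            sil |= hit
            S[hit] = 0.0
        buf[(t - 1) % win] = S
        if t >= win:
            measure = buf.var(axis=0).mean(axis=1)
            newly = (~done) & (measure < params.epsilon)
            if newly.any():
                steps[newly] = t
                final[newly] = S[newly]
                done[newly] = True
                if done.all():
                    break

    final = np.where(done[:, None], final, S)
    # chronological tail
    last_t = min(t, params.max_steps)
    order = (np.arange(last_t - win, last_t) % win) if last_t >= win else np.arange(win)
    tail = buf[order]
    return BatchDevelopment(
        final=final, stable=done, steps=steps, silenced=sil,
        silenced_by=silenced_by, tail=tail,
    )


def develop(
    genotype: RegulatoryGenotype,
    env: np.ndarray,
    init: np.ndarray,
    params: DevelopmentParams | None = None,
    silenced: np.ndarray | None = None,
    allow_silencing: bool = True,
) -> DevelopmentResult:
    """Develop a single cell to steady state (or to the iteration cap)."""
    params = params or DevelopmentParams()
    res = develop_batch(
        genotype.w_gg[None], genotype.w_ge[None], genotype.theta[None],
        np.asarray(env, dtype=float), np.asarray(init, dtype=float)[None],
        params,
        silenced=None if silenced is None else np.asarray(silenced, bool)[None],
        allow_silencing=allow_silencing,
    )
    return res[0]
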