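# Methods

## Model

### Cell-level dynamics

A cell's state is an expression vector `S_G ∈ [0,1]^N` together with a fixed
binary environment vector `S_E ∈ {0,1}^E`, `E = N`. One synchronous update
is

    S_G(t+1)_i = σ( (W_GG · S_G(t))_i + (W_GE · S_E)_i ),

with σ the logistic `1/(1+e^{-x})`. Silenced genes are pinned to exactly 0
after the update (the silencing mask is applied to the output, so a
silenced gene's outgoing influence disappears with its expression — the
network behaves as if the gene's row and column were deleted).

Polycomb silencing is a one-time developmental checkpoint: immediately
after the update at `t = t_c`, every gene that (i) carries a Polycomb
response element for at least one PRC (`θ_{i,j} = 1` for some `j`) and
(ii) is expressed below the threshold `γ` is permanently silenced, and all
PRCs targeting it are recorded as responsible. There is exactly one
checkpoint; nothing can be silenced after development ("cellular memory" is
the decision made at `t_c`). A gene below `γ` with no PRE is untouched.

Development iterates the update from an initial state until the stability
measure — the per-gene population variance over the trailing `window = 10`
states, averaged over the N genes — drops below `ε = 1e-4`, or until
`max_steps = 100`. Cells that never settle are developmentally unstable
("lethal"). The measure is dimensionless in N and zero iff the trajectory
is constant over the window; because iteration stops at the ε-criterion,
"steady states" carry per-gene wiggle of order `sqrt(ε) ≈ 0.01`, which is
the natural tolerance when comparing them.

The whole loop is vectorized over stacks of cells (`develop_batch`); the
single-cell `develop` wraps a stack of one. An independent scalar-loop
reimplementation lives in the test suite as an oracle; the two agree on all
discrete outcomes and to floating-point reassociation error (~1e-16) on
states.

### Evolution

An individual is one genotype `(W_GG, W_GE, θ)` expressed in two cells,
developed in environments 1 and 2 from fixed initial vectors. Fitness uses
the joint normalized L1 distance from the two optimal phenotypes,

    Ω(D) = (e^{−D/s} + max(0, 1 − a·D))²,
    D = (|S₁−S₁ᵒᵖᵗ|₁ + |S₂−S₂ᵒᵖᵗ|₁)/(2N),

so `Ω(0) = 4`; the exponential term is stabilizing selection, the linear
hinge is directional selection (zero beyond `D = 1/a`). A
`stabilizing_only` mode drops the hinge.

Per generation: parents are drawn with replacement proportionally to
fitness (selfing allowed); recombination is row-wise — each gene's
regulatory-input rows of `W_GG`, `W_GE` and its θ row are inherited jointly
from one parent with probability ½, keeping cis-context intact; mutation
replaces each nonzero weight with a fresh `N(0, weight_scale²)` draw with
probability μ (the sparsity pattern is immutable) and flips each θ entry
with probability μ_θ; both cells develop, and offspring unstable in either
environment are discarded until M stable offspring fill the generation.
Offspring are produced in vectorized batches; the count of discarded
lethal offspring is recorded per generation.

The founder is rejection-sampled: weights with exactly `round(c·N²)`
nonzero Gaussian entries, θ ≡ 0 (no polycomb control exists before
evolution), random uniform initial vectors, and two binary environments
differing at `round(Δe·N)` positions, redrawn until development is stable
in both environments. The env-1 optimum is the founder's own env-1 steady
state; the env-2 optimum is a random *binary* vector redrawn until its mean
absolute difference from the env-1 optimum is ≥ ΔS. Binary optima are the
natural targets of saturating sigmoid dynamics and — because a silenced
gene matches a 0-target exactly — they are what makes recruiting polycomb
silencing adaptive; with interior (uniform) optima, silencing is almost
never the best way to hit a target and neither fidelity nor substantial
repression evolves (this was verified empirically and is the main
genuinely open design choice in the package).

### Transfer and pliancy assays

A post-developmental transfer continues the dynamics from the developed
steady state under a new environment. Silencing persists, except that a
gene is released when **all** PRCs recorded as silencing it are broken
(conservative AND-release; overlap semantics are otherwise underdetermined).
No new silencing can occur after development. The same ε/window criterion
decides stability; a transfer failing to settle is counted as unstable, a
result rather than an error.

The four conditions are a: developed in env 1; b: developed in env 2;
c: a then transferred to env 2 intact; d: as c with a chosen break set.
Gene i is pliant iff `|S_d−S_b|_i < ½|S_a−S_b|_i` and
`|S_d−S_b|_i < |S_c−S_b|_i`, both strict — so with nothing broken, `S_d =
S_c` and the score is exactly 0. The per-cell score is the pliant fraction
over all N genes (silenced genes included in the denominator). Scores are
defined only for cells whose four conditions are all stable.

Supplementary statistics: repressed-gene counts (genes with nonempty
silencing attribution), effective connectivity (mean nonzero in/out degree
of `W_GG` after deleting silenced genes' rows and columns, with a plain
pre-deletion variant restricted to a gene subset), and the sustained assay
(env1 → env2 → env1 with a fixed break set, reporting L1 distances to the
a- and b-phenotypes at each stage).

### Default parameters

| parameter | default | meaning |
|---|---|---|
| N | 10 | genes (= environment factors) |
| P | 2 | polycomb repressive complexes |
| M | 200 | population size |
| G | 1000 | generations |
| c | 0.75 | weight-matrix connectivity |
| weight_scale | 1.2 | sd of nonzero Gaussian weights |
| μ | 0.01 | per-nonzero-weight replacement rate |
| μ_θ | 0.015 | per-entry PRE flip rate |
| s | 0.3 | stabilizing selection strength |
| a | 1.0 | directional selection strength |
| Δe | 0.1 | environment difference fraction |
| ΔS | 0.2 | minimum per-gene optimum separation |
| γ | 0.5 | silencing threshold |
| t_c | 10 | silencing checkpoint step |
| ε, window | 1e-4, 10 | stability criterion |
| max_steps | 100 | iteration cap |

These were chosen so the model's emergent behaviors sit in the intended
regime, and the reasoning is worth recording because the regime is narrow
in two directions:

* **Weight scale.** At scale ≤ 1 the sigmoid dynamics are globally
  contractive: a transferred cell always flows to the new environment's
  unique attractor and fidelity cannot exist. At scale ≥ 2 the dynamics are
  so strongly multistable that releasing silenced genes excites persistent
  limit cycles in ~1–3% of evolved cells — orders of magnitude above the
  rare-instability regime the model is meant to occupy. `weight_scale=1.2`
  gives majority fidelity with post-break instability at the 10⁻³–10⁻⁴
  scale.
* **Environment difference.** With large Δe, selection differentiates the
  two cell types directly through the `W_GE` channel and the transferred
  phenotype simply tracks the new environment. A small Δe (0.1) forces
  differentiation through *differential silencing* — different holes in
  the same network in the two environments — which is precisely the
  mechanism that yields fidelity when silencing is intact and pliancy when
  it is broken.
* **θ flip rate.** Flip rates ≥ 0.02/entry saturate the PRE matrix by
  random drift within ~50 generations, which would erase both the gradual
  rise of repression and pliancy over evolutionary time and the contrast
  between early and late checkpoints; 0.015 keeps θ occupancy
  selection-limited on the 1,000-generation scale.
* **Mutation rate.** μ is per nonzero weight; 0.01 corresponds to ~1.5
  weight replacements per genome per generation. At several-fold higher
  rates, mutation load overwhelms selection and no adaptation (and no
  fidelity) occurs.

All of these are exposed in `EvolutionConfig`; nothing in the library
assumes the defaults.

## Expression-matrix analytics

Inputs are log-scale genes × cells matrices with cell categories
`primary`, `metastatic`, `normal_primary_site`, `normal_met_site` and a
boolean polycomb flag per gene. Count-level normalization, cell filtering
and cell-cycle correction are out of scope — the caller supplies
log-normalized values (a `log1p` of counts is the minimal route). Where
met-site normals were not sampled, operations needing a normal reference
for metastatic cells fall back to primary-site normals.

* **Centroid distance** — Euclidean norm between per-gene group means over
  a gene subset.
* **Gene-wise pliancy** — gene g is pliant iff |μ_g^m − μ_g^n| <
  |μ_g^p − μ_g^n| (strict; ties are not pliant). The proportion over the
  subset is tested against 0.5 with a one-sided exact binomial test — the
  test is a package choice, made explicit here because proportions of this
  kind are often reported without naming one.
* **Pliancy z-score** — z_{g,c} = (x_{g,c} − μ_g^m)/σ_g^m, oriented by
  sign(μ_g^m − μ_g^n) and averaged over genes; negative = toward normal.
  Genes with σ_g^m = 0 are dropped and reported. The metastatic mean of
  z_c is exactly 0 (standardization identity), which the tests assert to
  1e-10. Polycomb-flagged genes are refused in the averaging set by
  default so the score stays independent of the regression predictors.
* **Log-fold-sum permutation test** — per-gene log-fold change is the
  difference of group means of log-scale values. The statistic is
  (Σ_pc met-vs-normal lfc) − (Σ_pc primary-vs-normal lfc); the null
  permutes primary/metastatic identity independently per gene (normals
  fixed); the p-value is one-sided toward metastatic down-regulation with
  +1/(n+1) smoothing. Cells and genes are canonically ordered first so the
  null is reproducible from the seed regardless of input layout.
* **Z-score regression and bootstrap** — OLS of z_c on the metastatic
  cells' polycomb-gene expressions (intercept fitted, not counted). A
  positive coefficient means lower polycomb expression accompanies
  movement toward normal. Fewer metastatic cells than predictors is an
  explicit error, never a silent regularization; a zero-variance response
  returns zero coefficients and r² = 0 by convention. The control repeats
  the fit with k random non-polycomb genes n_boot times; p = smoothed
  fraction of null counts ≥ the observed positive count.
* **Rank-sum DE** — two-sided Wilcoxon rank-sum per gene with
  Benjamini–Hochberg adjustment; provided as plumbing so the pipeline is
  closed on synthetic data, not as a replacement for a dedicated DE
  framework.

All operations are pure (the input matrix is never modified) and all
randomness flows through an explicit `numpy` Generator.

## Synthetic expression generator

The generator emulates exactly the structure the analytics assume: per-gene
primary and normal centroids drawn independently (`N(0, spread²)`,
spread 2), one shared normal centroid for both sites, and for each
metastatic cell a latent pliancy `u_c ~ U(0,1)` placing it at
`(1−λu_c)·primary + λu_c·normal` plus `N(0, noise²)` noise (noise 1). The
designated polycomb genes are additionally shifted by `−β·u_c` in
metastatic cells, linearly tying their down-regulation to the cell's
movement toward normal. Defaults: 2,000 genes, 300/300/150/150 cells,
53 polycomb genes (matching the size of a curated polycomb/trithorax gene
set for this kind of analysis), λ = 0.8, β = 2.

β = 2 makes the designated-gene signal comfortably detectable against the
random-gene bootstrap while β = 0 is correctly indistinguishable from it;
λ = 0.8 puts the metastatic centroid clearly on the normal side without
collapsing onto it. What the generator deliberately does **not** emulate:
count noise (dropout, library size), batch effects, correlated gene
modules, or any cell-type substructure within categories. Passing tests on
this generator therefore demonstrate the correctness and calibration of
the statistics, not robustness to real single-cell artifacts.

`export_sim_phenotypes` bridges the simulator to these analytics: the four
assay-condition steady states of every individual become a labeled matrix
(4M columns) suitable for PCA or centroid analyses.

## Numerical and design notes

* Determinism: every stochastic routine takes a `numpy` Generator; a whole
  evolution is bit-reproducible from its seed, and archives store the
  generator state so a resumed run is identical to an uninterrupted one.
* Steady-state comparisons use tolerances at the `sqrt(ε)` scale; exact
  zeros are asserted only where the model pins them (silenced genes).
* Strict inequalities everywhere ties could arise (gene pliancy both in
  the model and in the matrix analytics): ties are "not pliant", which
  makes the nothing-broken score exactly 0 rather than noise-dependent.
* The pliancy denominator is all N genes, silenced included.
* Degenerate inputs fail loudly: founder or offspring rejection-sampling
  caps, all-genes-dropped z-scores, too few metastatic cells, truncated or
  version-mismatched archives.
* In the no-polycomb control, the intact transfer lands on the env-2
  developed phenotype for ≈99% of cells (identical effective networks);
  the rare exceptions are genuinely bistable networks whose continuation
  settles in a different basin, so the corresponding check is phrased as
  "overwhelming majority", not "all".

## Scales used by the test suite and acceptance script

The shipped experiments run 10 populations at N=10, P=2, M=200, G=1,000
for the instability census and fidelity/pliancy contrasts, and a
16-setting sweep (c × μ × Δe × γ, 10 founders each, M=50, G=150) for the
broken-vs-intact comparison; statistical calibrations use 50–200 generator
replicates. These sizes give stable qualitative outcomes on a single CPU
in minutes while remaining honest population-scale experiments.

## Known limitations

* Two environments / two cell types only; one silencing checkpoint; no
  stochastic expression noise — all by design of the model family.
* The emergent-fidelity regime requires the parameter choices discussed
  above; the package documents rather than hides this sensitivity.
* Per-population post-break instability is heavy-tailed (populations are
  near-clonal, so one oscillation-prone lineage affects many cells);
  small-sample estimates of the instability rate fluctuate accordingly.
* The empirical analytics assume the supplied matrix is already on a
  sensible log scale; they perform no normalization of their own.
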