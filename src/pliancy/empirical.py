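"""Pliancy analytics for labeled gene x cell expression matrices.

These operate on log-scale expression matrices whose cells carry one of the
categories ``primary``, ``metastatic``, ``normal_primary_site``,
``normal_met_site`` and whose genes carry a boolean polycomb flag. They
quantify whether metastatic cells have moved toward the normal phenotype
(centroid distances, gene-wise pliancy), assign each metastatic cell a
*pliancy z-score* (negative = toward normal), and test whether polycomb
gene down-regulation predicts that movement (OLS regression of the score on
polycomb gene expression, with a permutation test on summed log-fold
changes and a random-gene bootstrap as nulls).

All operations are pure: the input matrix is never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CATEGORIES",
    "LabeledExpressionMatrix",
    "ZScoreResult",
    "centroid_distance",
    "genewise_pliancy",
    "pliancy_zscore",
    "logfold_sum_permutation",
    "zscore_regression",
    "positive_coeff_bootstrap",
    "rank_sum_de",
]

CATEGORIES = ("primary", "metastatic", "normal_primary_site", "normal_met_site")


@dataclass
class LabeledExpressionMatrix:
    """Log-scale genes x cells matrix with cell categories and polycomb flags.

    values : DataFrame indexed by gene id, columns are cell ids.
    cell_category : Series (index = cell ids) of category strings.
    polycomb : boolean Series (index = gene ids).
    de_flag : optional boolean Series of differentially expressed genes.
    """

    values: pd.DataFrame
    cell_category: pd.Series
    polycomb: pd.Series
    de_flag: pd.Series | None = None

    def __post_init__(self):
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        missing = v.columns.difference(self.cell_category.index)
        if len(missing):
            raise ValueError(f"cells without a category label: {list(missing[:5])}")
        self.cell_category = self.cell_category.reindex(v.columns)
        self.polycomb = self.polycomb.reindex(v.index, fill_value=False).astype(bool)
        if self.de_flag is not None:
            self.de_flag = self.de_flag.reindex(v.index, fill_value=False).astype(bool)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    def cells_in(self, category: str) -> pd.Index:
        return self.cell_ids[self.cell_category.values == category]

    def require(self, *categories: str) -> None:
        for c in categories:
            if len(self.cells_in(c)) == 0:
                raise ValueError(f"no cells in required category {c!r}")

    def polycomb_genes(self) -> pd.Index:
        return self.gene_ids[self.polycomb.values]


def _group_cells(matrix: LabeledExpressionMatrix, group) -> pd.Index:
    """A group is either a category name or an explicit collection of cell ids."""
    if isinstance(group, str):
        cells = matrix.cells_in(group)
        if len(cells) == 0:
            raise ValueError(f"empty group: no cells in category {group!r}")
        return cells
    cells = pd.Index(group)
    missing = cells.difference(matrix.cell_ids)
    if len(missing):
        raise ValueError(f"unknown cell ids in group: {list(missing[:5])}")
    return cells


def centroid_distance(matrix: LabeledExpressionMatrix, group_a, group_b,
                      gene_subset=None) -> float:
    """Euclidean distance between two cell groups' centroids.

    The centroid of a group is its per-gene mean of log-scale expression,
    over ``gene_subset`` (all genes by default).
    """
    genes = matrix.gene_ids if gene_subset is None else pd.Index(gene_subset)
    if len(genes) == 0:
        raise ValueError("gene_subset is empty")
    sub = matrix.values.loc[genes]
    ca = sub[_group_cells(matrix, group_a)].mean(axis=1)
    cb = sub[_group_cells(matrix, group_b)].mean(axis=1)
    return float(np.linalg.norm(ca.values - cb.values))


def _normal_for_metastatic(matrix: LabeledExpressionMatrix) -> str:
    """Met-site normals when sampled; otherwise fall back to primary-site normals."""
    if len(matrix.cells_in("normal_met_site")):
        return "normal_met_site"
    return "normal_primary_site"


def genewise_pliancy(matrix: LabeledExpressionMatrix, gene_subset=None):
    """Per-gene pliancy of metastatic cells, its proportion and significance.

    A gene is pliant when the metastatic mean is strictly closer to the
    (met-site, else primary-site) normal mean than the primary mean is to
    the primary-site normal mean. The proportion over ``gene_subset`` is
    tested against 0.5 with a one-sided exact binomial test (alternative:
    greater).
    """
    matrix.require("primary", "metastatic", "normal_primary_site")
    genes = matrix.gene_ids if gene_subset is None else pd.Index(gene_subset)
    sub = matrix.values.loc[genes]
    mu_p = sub[matrix.cells_in("primary")].mean(axis=1)
    mu_m = sub[matrix.cells_in("metastatic")].mean(axis=1)
    mu_n_p = sub[matrix.cells_in("normal_primary_site")].mean(axis=1)
    mu_n_m = sub[matrix.cells_in(_normal_for_metastatic(matrix))].mean(axis=1)
    flags = (mu_m - mu_n_m).abs() < (mu_p - mu_n_p).abs()
    k, n = int(flags.sum()), len(flags)
    pval = stats.binomtest(k, n, 0.5, alternative="greater").pvalue
    return flags, k / n, float(pval)


@dataclass
class ZScoreResult:
    """Per-cell pliancy z-scores with the gene-level statistics behind them."""

    z: pd.Series                 # per metastatic cell
    mu_met: pd.Series
    sigma_met: pd.Series
    mu_normal: pd.Series
    sigma_normal: pd.Series
    genes_used: pd.Index
    genes_dropped: pd.Index      # sigma_met == 0


def pliancy_zscore(matrix: LabeledExpressionMatrix, gene_subset=None,
                   allow_polycomb: bool = False) -> ZScoreResult:
    """Pliancy z-score of each metastatic cell.

    For gene g: z_{g,c} = (x_{g,c} - mu_g^m) / sigma_g^m, sign-oriented by
    sign(mu_g^m - mu_g^n) so that a negative value means the cell sits on
    the normal side of the metastatic centroid; the cell score z_c is the
    mean over the genes used. By construction the z_c average to exactly 0
    over metastatic cells. Polycomb-flagged genes are refused by default so
    the score stays independent of the genes later used as regressors.
    """
    matrix.require("metastatic")
    met = matrix.cells_in("metastatic")
    if len(met) < 2:
        raise ValueError("need at least 2 metastatic cells")
    normal_cat = _normal_for_metastatic(matrix)
    matrix.require(normal_cat)
    genes = matrix.gene_ids if gene_subset is None else pd.Index(gene_subset)
    if not allow_polycomb:
        overlap = genes.intersection(matrix.polycomb_genes())
        if len(overlap):
            raise ValueError(
                "gene_subset contains polycomb-flagged genes (pass "
                f"allow_polycomb=True to override): {list(overlap[:5])}")
    sub = matrix.values.loc[genes]
    x_m = sub[met]
    x_n = sub[matrix.cells_in(normal_cat)]
    mu_m, sd_m = x_m.mean(axis=1), x_m.std(axis=1, ddof=0)
    mu_n, sd_n = x_n.mean(axis=1), x_n.std(axis=1, ddof=0)
    keep = sd_m > 0
    if not keep.any():
        raise ValueError("all genes dropped: zero variance across metastatic cells")
    used, dropped = genes[keep.values], genes[~keep.values]
    zg = (x_m.loc[used].sub(mu_m[used], axis=0)).div(sd_m[used], axis=0)
    orient = np.sign(mu_m[used] - mu_n[used])
    z = zg.mul(orient, axis=0).mean(axis=0)
    return ZScoreResult(z=z, mu_met=mu_m, sigma_met=sd_m, mu_normal=mu_n,
                        sigma_normal=sd_n, genes_used=used, genes_dropped=dropped)


def logfold_sum_permutation(matrix: LabeledExpressionMatrix, polycomb_genes=None,
                            n_perm: int = 1000,
                            rng: np.random.Generator | None = None):
    """Permutation test on summed polycomb log-fold changes.

    The observed statistic is (sum over polycomb genes of metastatic-vs-
    normal log-fold change) minus (sum of primary-vs-normal log-fold
    change); log-fold change is the difference of group means of the
    log-scale values. The null permutes the primary/metastatic identity of
    cells independently per gene, n_perm times. The p-value is one-sided
    toward down-regulation in metastatic cells (null <= observed), with
    +1/(n_perm+1) smoothing.

    Returns ``(observed, null, pvalue)`` where observed is a dict with the
    two sums and their difference and null is the n_perm-long array.
    """
    rng = rng or np.random.default_rng()
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    matrix.require("primary", "metastatic", "normal_primary_site")
    genes = (matrix.polycomb_genes() if polycomb_genes is None
             else pd.Index(polycomb_genes))
    # canonical gene and cell ordering makes the null reproducible from the
    # seed regardless of how the input matrix is arranged
    genes = pd.Index(sorted(genes))
    sub = matrix.values.loc[genes]
    prim = pd.Index(sorted(matrix.cells_in("primary")))
    met = pd.Index(sorted(matrix.cells_in("metastatic")))
    mu_n_p = sub[matrix.cells_in("normal_primary_site")].mean(axis=1).values
    mu_n_m = sub[matrix.cells_in(_normal_for_metastatic(matrix))].mean(axis=1).values
    x_p, x_m = sub[prim].values, sub[met].values
    n_p = x_p.shape[1]
    sum_p = float((x_p.mean(axis=1) - mu_n_p).sum())
    sum_m = float((x_m.mean(axis=1) - mu_n_m).sum())
    observed = sum_m - sum_p
    pooled = np.concatenate([x_p, x_m], axis=1)
    const = mu_n_p.sum() - mu_n_m.sum()  # normals are never permuted
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permuted(pooled, axis=1)
        null[i] = (perm[:, n_p:].mean(axis=1).sum()
                   - perm[:, :n_p].mean(axis=1).sum()) + const
    pvalue = (1 + int((null <= observed).sum())) / (n_perm + 1)
    obs = {"sum_primary": sum_p, "sum_metastatic": sum_m, "difference": observed}
    return obs, null, float(pvalue)


def zscore_regression(matrix: LabeledExpressionMatrix, polycomb_genes=None,
                      zscores: pd.Series | None = None,
                      zscore_genes=None):
    """OLS of the pliancy z-score on polycomb gene expression in metastatic cells.

    Positive coefficients mean lower polycomb expression goes with movement
    toward normal (more negative score) — polycomb dysregulation driving
    pliancy. Returns ``(coefficients, r_squared, positive_count)``; the
    intercept is fitted but not counted.
    """
    genes = (matrix.polycomb_genes() if polycomb_genes is None
             else pd.Index(polycomb_genes))
    if len(genes) == 0:
        raise ValueError("no predictor genes")
    met = matrix.cells_in("metastatic")
    if len(met) <= len(genes):
        raise ValueError(
            f"{len(met)} metastatic cells cannot support {len(genes)} predictors; "
            "reduce the gene set or use a regularized fit outside this routine")
    if zscores is None:
        subset = zscore_genes
        if subset is None:
            base = (matrix.gene_ids[matrix.de_flag.values]
                    if matrix.de_flag is not None else matrix.gene_ids)
            subset = base.difference(matrix.polycomb_genes())
        zscores = pliancy_zscore(matrix, subset).z
    y = zscores.reindex(met).values
    X = matrix.values.loc[genes, met].T.values
    if np.ptp(y) == 0:
        coefs = pd.Series(0.0, index=genes)
        return coefs, 0.0, 0
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    coefs = pd.Series(beta[1:], index=genes)
    return coefs, r2, int((coefs > 0).sum())


def positive_coeff_bootstrap(matrix: LabeledExpressionMatrix, k: int | None = None,
                             n_boot: int = 1000,
                             rng: np.random.Generator | None = None,
                             zscores: pd.Series | None = None):
    """Random-gene null for the positive-coefficient count.

    Repeats the z-score regression n_boot times with k random non-polycomb
    genes as predictors and records the number of positive coefficients.
    The p-value is the smoothed fraction of null counts at or above the
    observed polycomb-gene count.

    Returns ``(observed_count, null_counts, pvalue)``.
    """
    rng = rng or np.random.default_rng()
    pc = matrix.polycomb_genes()
    k = len(pc) if k is None else k
    candidates = pd.Index(sorted(matrix.gene_ids.difference(pc)))
    if len(candidates) < k:
        raise ValueError(f"need at least {k} non-polycomb genes, have {len(candidates)}")
    if zscores is None:
        zscores = pliancy_zscore(matrix, candidates).z
    _, _, observed = zscore_regression(matrix, pc, zscores=zscores)
    null = np.empty(n_boot, dtype=int)
    for i in range(n_boot):
        pick = candidates[rng.choice(len(candidates), size=k, replace=False)]
        _, _, null[i] = zscore_regression(matrix, pick, zscores=zscores)
    pvalue = (1 + int((null >= observed).sum())) / (n_boot + 1)
    return observed, null, float(pvalue)


def pca_projection(matrix: LabeledExpressionMatrix, n_components: int = 2,
                   gene_subset=None) -> pd.DataFrame:
    """Plain PCA projection of cells (plumbing for cluster/overlap plots).

    Centers genes and projects cells onto the top principal components via
    SVD. Returns a cells x components DataFrame with the cell category as
    an extra column.
    """
    genes = matrix.gene_ids if gene_subset is None else pd.Index(gene_subset)
    x = matrix.values.loc[genes].values
    xc = x - x.mean(axis=1, keepdims=True)       # center each gene
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components, s.shape[0])
    scores = (s[:k, None] * vt[:k]).T            # cells x components
    df = pd.DataFrame(scores, index=matrix.cell_ids,
                      columns=[f"PC{i + 1}" for i in range(k)])
    df["category"] = matrix.cell_category.values
    return df


def rank_sum_de(matrix: LabeledExpressionMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum differential expression between two groups.

    Log-fold change is the difference of group means of the log-scale
    values (a minus b); p-values are two-sided and Benjamini-Hochberg
    adjusted across genes.
    """
    from statsmodels.stats.multitest import multipletests

    ca = _group_cells(matrix, group_a)
    cb = _group_cells(matrix, group_b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("both groups need at least 2 cells")
    xa = matrix.values[ca].values
    xb = matrix.values[cb].values
    stat, pval = stats.ranksums(xa, xb, axis=1)
    lfc = xa.mean(axis=1) - xb.mean(axis=1)
    _, padj, *_ = multipletests(pval, method="fdr_bh")
    return pd.DataFrame(
        {"log_fold_change": lfc, "statistic": stat, "pvalue": pval, "padj": padj},
        index=matrix.gene_ids,
    )
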