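"""Signed weighted gene coexpression analysis.

Top genes by mean log-expression are correlated across samples (Pearson),
raised to a signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta
(beta 11 for the autosomal-aneuploidy design, 17 for the sex-chromosomal
design), converted to the topological overlap matrix, clustered by
average linkage on 1 - TOM with a static height cut, and summarized per
module by an eigengene (first principal component of the z-scored module
submatrix) with per-genotype means and t-based confidence intervals.
Clusters below the minimum size are left unassigned ("grey").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .preprocess import ExpressionMatrix

MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
)

DEFAULT_BETA_AUTOSOMAL = 11
DEFAULT_BETA_SEX_CHROMOSOMAL = 17


def select_top_genes(log_expr: ExpressionMatrix, n: int = 10000) -> ExpressionMatrix:
    """Keep the n genes with the highest mean log-expression (ties by id)."""
    n_genes = len(log_expr.values)
    if n <= 0:
        raise ValueError("n must be positive")
    if n > n_genes:
        raise ValueError(f"requested {n} genes but only {n_genes} available")
    means = log_expr.values.mean(axis=1)
    order = sorted(log_expr.values.index, key=lambda g: (-means[g], g))
    keep = log_expr.values.index.isin(order[:n])
    return ExpressionMatrix(
        log_expr.values.loc[keep], log_expr.samples.copy(), log_expr.log_scale
    )


def signed_adjacency(expr: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Signed soft-threshold adjacency ((1 + Pearson r)/2)^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X = expr.values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    sd = X.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = list(expr.values.index[dead[:5]])
        raise ValueError(f"zero-variance gene(s): {names}")
    r = np.corrcoef(X)
    a = ((1.0 + r) / 2.0) ** beta
    a = np.clip((a + a.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(a, index=expr.values.index, columns=expr.values.index)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_{u != i,j} a_iu a_uj and connectivity k excluding the
    diagonal; TOM_ii = 1.
    """
    A = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A  # diagonal excluded because diag(A) = 0
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


@dataclass
class ModuleAssignment:
    """Gene -> module labels plus eigengene profiles and PC1 variance."""

    labels: pd.Series  # gene_id -> color label, "grey" = unassigned
    eigengenes: pd.DataFrame = field(default_factory=pd.DataFrame)  # modules x samples
    variance_explained: pd.Series = field(default_factory=pd.Series)

    def module_sizes(self) -> pd.Series:
        return self.labels[self.labels != "grey"].value_counts()


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> ModuleAssignment:
    """Average-linkage clustering on 1 - TOM with a static height cut.

    Clusters smaller than ``min_module_size`` become "grey" (unclustered).
    Modules are labeled by decreasing size with the conventional color
    sequence (turquoise, blue, brown, ...).
    """
    n = len(tom)
    if n < min_module_size:
        raise ValueError("fewer genes than the minimum module size")
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    if np.allclose(diss, diss[0, 1] if n > 1 else 0.0, atol=1e-12):
        warnings.warn("degenerate TOM: all pairwise dissimilarities equal", stacklevel=2)
    Z = average(squareform(np.clip(diss, 0.0, None), checks=False))
    raw = fcluster(Z, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index
    # order surviving clusters by size (desc), ties by first occurrence
    ordered = sorted(big, key=lambda c: (-sizes[c], c))
    name = {}
    for i, c in enumerate(ordered):
        name[c] = MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"
    labels = pd.Series(
        [name.get(c, "grey") for c in raw], index=tom.index, name="module"
    )
    return ModuleAssignment(labels)


def module_eigengene(expr: ExpressionMatrix, modules: ModuleAssignment) -> ModuleAssignment:
    """First principal component per module across samples.

    Genes are z-scored; the eigengene is PC1 of the module submatrix,
    sign-oriented to correlate positively with the module's mean z-scored
    expression profile.  Returns the assignment with ``eigengenes``
    (modules x samples) and ``variance_explained`` filled in.
    """
    labels = modules.labels
    eig, ve = {}, {}
    for mod in labels[labels != "grey"].unique():
        genes = labels.index[labels == mod]
        X = expr.values.loc[genes].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        Z = (X - mu) / sd
        if Z.shape[0] == 1:
            e = Z[0]
            ve[mod] = 1.0
        else:
            U, S, Vt = np.linalg.svd(Z, full_matrices=False)
            e = Vt[0]
            ve[mod] = float(S[0] ** 2 / (S ** 2).sum())
        mean_profile = Z.mean(axis=0)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[mod] = e
    eigengenes = pd.DataFrame(eig, index=expr.values.columns).T
    return ModuleAssignment(labels, eigengenes, pd.Series(ve, name="variance_explained"))


def eigengene_summary(
    eigengenes: pd.DataFrame, genotype_labels: dict | pd.Series, conf: float = 0.95
) -> pd.DataFrame:
    """Per-genotype mean and t-based CI of each module eigengene.

    Rows: (module, genotype); columns mean, ci_low, ci_high, n.  A single
    replicate yields the mean with missing CI bounds.
    """
    grp = pd.Series(genotype_labels).reindex(eigengenes.columns)
    if grp.isna().any():
        raise ValueError("every sample needs a genotype label")
    rows = []
    for mod in eigengenes.index:
        vals = eigengenes.loc[mod]
        for g, sub in vals.groupby(grp, sort=False):
            n = len(sub)
            m = float(sub.mean())
            if n >= 2:
                half = float(
                    stats.t.ppf(0.5 + conf / 2, n - 1) * sub.std(ddof=1) / np.sqrt(n)
                )
                rows.append((mod, g, m, m - half, m + half, n))
            else:
                rows.append((mod, g, m, np.nan, np.nan, n))
    return pd.DataFrame(
        rows, columns=["module", "genotype", "mean", "ci_low", "ci_high", "n"]
    )
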