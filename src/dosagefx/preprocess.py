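"""Normalization, filtering, batch adjustment, and replicate averaging.

Pipeline order is fixed: prefilter low-count genes -> CPM -> temporary
log2(CPM + 0.5) -> empirical-Bayes batch adjustment (only when the design
spans sequencing batches) -> back to CPM scale -> drop genes with any
nonpositive value -> average replicates per genotype group.  Permuting the
batch step and the averaging step changes results; the order above is the
contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import CountMatrix

LOG_OFFSET = 0.5  # pseudo-CPM added before the temporary log2 transform


@dataclass
class ExpressionMatrix:
    """Real-valued genes x samples matrix; ``log_scale`` flags log2 values."""

    values: pd.DataFrame
    samples: pd.DataFrame
    log_scale: bool = False


def cpm(counts: CountMatrix) -> ExpressionMatrix:
    """Counts per million: count / column total * 1e6, per sample."""
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total counts: {list(zero.index)}")
    vals = counts.counts / totals * 1e6
    return ExpressionMatrix(vals, counts.samples.copy(), log_scale=False)


def prefilter_low_counts(counts: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` reads summed over samples."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = counts.counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("prefilter removed every gene", stacklevel=2)
    return CountMatrix(counts.counts.loc[keep], counts.samples.copy())


def remove_nonpositive(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes with any value <= 0 (they would generate extreme ratios)."""
    if expr.log_scale:
        raise ValueError("remove_nonpositive expects CPM scale, not log")
    keep = (expr.values > 0).all(axis=1)
    if not keep.any():
        warnings.warn("no gene survives the nonpositive filter", stacklevel=2)
    return ExpressionMatrix(expr.values.loc[keep], expr.samples.copy(), False)


def log2_transform(expr: ExpressionMatrix, offset: float = LOG_OFFSET) -> ExpressionMatrix:
    if expr.log_scale:
        raise ValueError("already on log scale")
    return ExpressionMatrix(np.log2(expr.values + offset), expr.samples.copy(), True)


def delog(expr: ExpressionMatrix, offset: float = LOG_OFFSET) -> ExpressionMatrix:
    if not expr.log_scale:
        raise ValueError("not on log scale")
    return ExpressionMatrix(np.exp2(expr.values) - offset, expr.samples.copy(), False)


# ---------------------------------------------------------------------------
# ComBat-style batch adjustment
# ---------------------------------------------------------------------------

def combat_adjust(
    log_expr: ExpressionMatrix,
    batch_labels: dict | pd.Series,
    covariate_groups: dict | pd.Series | None = None,
) -> ExpressionMatrix:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per gene, data are standardized under a model with batch and group
    terms; per-batch location (gamma) and scale (delta^2) are estimated and
    shrunk toward parametric priors (normal / inverse-gamma, moment-matched
    across genes), then removed.  Output stays on the log scale.  A final
    per-gene re-centering enforces exact preservation of the grand mean
    across all samples.

    A single batch returns the input unchanged.  A batch perfectly
    confounded with a covariate group (rank-deficient design) is rejected.
    """
    if not log_expr.log_scale:
        raise ValueError("combat_adjust expects log-scale input")
    Y = log_expr.values.to_numpy(dtype=float)  # genes x samples
    sample_ids = list(log_expr.values.columns)
    batch = pd.Series(batch_labels).reindex(sample_ids)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    batches = list(pd.unique(batch))
    if len(batches) == 1:
        return ExpressionMatrix(log_expr.values.copy(), log_expr.samples.copy(), True)
    sizes = batch.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"batch(es) with fewer than 2 samples: {list(small.index)}")

    n_g, n_s = Y.shape
    B = np.column_stack([(batch == b).to_numpy(dtype=float) for b in batches])
    X = B
    if covariate_groups is not None:
        grp = pd.Series(covariate_groups).reindex(sample_ids)
        if grp.isna().any():
            raise ValueError("every sample needs a covariate group")
        levels = list(pd.unique(grp))[1:]  # drop reference level
        if levels:
            C = np.column_stack([(grp == g).to_numpy(dtype=float) for g in levels])
            X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("batch is confounded with the covariate groups")

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # params x genes
    n_batches = len(batches)
    n_per = np.array([sizes[b] for b in batches], dtype=float)
    grand = (n_per / n_s) @ beta[:n_batches]  # per-gene weighted batch mean
    stand_mean = np.tile(grand[:, None], (1, n_s))
    if X.shape[1] > n_batches:
        stand_mean = stand_mean + (X[:, n_batches:] @ beta[n_batches:]).T
    resid = Y - (X @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)[:, None]
    Z = (Y - stand_mean) / sd

    adj = Z.copy()
    for b, n_b in zip(batches, n_per):
        cols = (batch == b).to_numpy()
        Zb = Z[:, cols]
        g_hat = Zb.mean(axis=1)
        d_hat = Zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        g_star, d_star = _it_solve(Zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior)
        adj[:, cols] = (Zb - g_star[:, None]) / np.sqrt(d_star)[:, None]

    out = adj * sd + stand_mean
    out += (Y.mean(axis=1) - out.mean(axis=1))[:, None]  # preserve grand means
    values = pd.DataFrame(out, index=log_expr.values.index, columns=sample_ids)
    return ExpressionMatrix(values, log_expr.samples.copy(), True)


def _it_solve(Zb, g_hat, d_hat, g_bar, t2, a_prior, b_prior, conv=1e-4, max_iter=500):
    """Iterate the coupled EB posterior-mean equations to convergence."""
    n = Zb.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
        change = max(
            np.abs(g_new - g_old).max() / np.maximum(np.abs(g_old), 1e-12).max(),
            np.abs(d_new - d_old).max() / np.maximum(np.abs(d_old), 1e-12).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


# ---------------------------------------------------------------------------
# replicate averaging and the assembled pipeline
# ---------------------------------------------------------------------------

def average_replicates(expr: ExpressionMatrix, grouping: dict | pd.Series) -> pd.DataFrame:
    """Arithmetic per-gene mean per group; returns genes x groups DataFrame."""
    grp = pd.Series(grouping).reindex(expr.values.columns)
    if grp.isna().any():
        missing = list(expr.values.columns[grp.isna()])
        raise ValueError(f"sample(s) without a group: {missing}")
    counts = grp.value_counts()
    if (counts == 0).any():
        raise ValueError("empty group in grouping")
    means = expr.values.T.groupby(grp, sort=False).mean().T
    return means


def preprocess_counts(
    counts: CountMatrix,
    min_total: int = 10,
    log_offset: float = LOG_OFFSET,
) -> pd.DataFrame:
    """Full preprocessing: returns per-genotype group means on CPM scale.

    Batch adjustment runs only when the sample sheet spans >= 2 batches,
    with genotype as the covariate.
    """
    filtered = prefilter_low_counts(counts, min_total)
    expr = cpm(filtered)
    if filtered.samples["batch"].nunique() > 1:
        logged = log2_transform(expr, log_offset)
        adjusted = combat_adjust(
            logged, filtered.samples["batch"], filtered.samples["genotype"]
        )
        expr = delog(adjusted, log_offset)
    expr = remove_nonpositive(expr)
    return average_replicates(expr, filtered.samples["genotype"])
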