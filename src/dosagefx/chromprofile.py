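"""LOWESS-smoothed log2 fold-change profiles along the chromosomes.

Genes are ordered at equidistance (ordinal rank) by chromosomal position,
arm by arm in fixed order X, 2L, 2R, 3L, 3R, 4; log2 fold changes between
two genotype groups are smoothed per arm with locally weighted linear
regression (tricube weights, robustifying iterations), and maximal runs of
one sign are reported as up/down-regulated regions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .synthetic import ARMS


def log2_fold_change(means: pd.DataFrame, experimental: str, control: str) -> pd.Series:
    """log2(experimental mean / control mean) per gene."""
    for g in (experimental, control):
        if g not in means.columns:
            raise ValueError(f"group {g!r} not in means")
    e = means[experimental].to_numpy(dtype=float)
    c = means[control].to_numpy(dtype=float)
    if (e <= 0).any() or (c <= 0).any():
        raise RuntimeError("nonpositive mean reached log2_fold_change; filter upstream")
    return pd.Series(np.log2(e / c), index=means.index, name="log2fc")


def order_equidistant(annotation: pd.DataFrame):
    """Assign consecutive ordinal indices to genes along the genome.

    Sort key: arm (fixed order), position, then gene_id for duplicate
    positions.  Returns the sorted annotation with an ``order`` column and
    a dict arm -> (start, end) half-open index ranges (the vertical
    separators of the genome-wide plot).
    """
    if len(annotation) == 0:
        raise ValueError("empty annotation")
    ann = annotation.copy()
    ann["_arm_rank"] = ann["arm"].map({a: i for i, a in enumerate(ARMS)})
    ann = ann.sort_values(["_arm_rank", "position", "gene_id"], kind="mergesort")
    ann = ann.drop(columns="_arm_rank").reset_index(drop=True)
    ann["order"] = np.arange(len(ann))
    boundaries = {}
    for arm, sub in ann.groupby("arm", sort=False):
        boundaries[arm] = (int(sub["order"].iloc[0]), int(sub["order"].iloc[-1]) + 1)
    return ann, boundaries


def lowess_profile(
    log2fc: np.ndarray,
    arms: np.ndarray,
    frac: float = 0.05,
    iterations: int = 3,
) -> np.ndarray:
    """Per-arm LOWESS smoothing of a profile in genome order.

    Each arm is smoothed independently (no bleed across the separators).
    Arms with fewer than 3 genes pass through unchanged with a warning.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    y = np.asarray(log2fc, dtype=float)
    arms = np.asarray(arms)
    out = np.empty_like(y)
    for arm in pd.unique(arms):
        sel = arms == arm
        n = int(sel.sum())
        if n < 3:
            warnings.warn(f"arm {arm}: fewer than 3 genes, smoothing skipped", stacklevel=2)
            out[sel] = y[sel]
            continue
        x = np.arange(n, dtype=float)
        out[sel] = _sm_lowess(
            y[sel], x, frac=frac, it=iterations, return_sorted=False
        )
    return out


def chromosome_profile(
    means: pd.DataFrame,
    experimental: str,
    control: str,
    annotation: pd.DataFrame,
    frac: float = 0.05,
    iterations: int = 3,
):
    """Assemble the ordered, smoothed genome-wide fold-change profile.

    Returns (profile DataFrame with gene_id, arm, position, order, log2fc,
    smoothed; boundaries dict arm -> (start, end)).  Genes absent from
    ``means`` (filtered upstream) are dropped.
    """
    ann = annotation[annotation["gene_id"].isin(means.index)]
    ordered, boundaries = order_equidistant(ann)
    lfc = log2_fold_change(means.loc[ordered["gene_id"]], experimental, control)
    ordered = ordered.assign(log2fc=lfc.to_numpy())
    ordered["smoothed"] = lowess_profile(
        ordered["log2fc"].to_numpy(), ordered["arm"].to_numpy(), frac, iterations
    )
    return ordered, boundaries


def segment_regions(smoothed: np.ndarray, arms: np.ndarray | None = None) -> list:
    """Maximal runs of one sign per arm: (start, end, direction) half-open.

    Zeros attach to the preceding run; leading zeros join the first signed
    run.  An all-zero arm yields one region of direction "none".
    """
    y = np.asarray(smoothed, dtype=float)
    if arms is None:
        arms = np.zeros(len(y))
    arms = np.asarray(arms)
    regions = []
    start = 0
    for arm in pd.unique(arms):
        sel = np.flatnonzero(arms == arm)
        s = np.sign(y[sel])
        nz = np.flatnonzero(s != 0)
        if nz.size == 0:
            regions.append((int(sel[0]), int(sel[-1]) + 1, "none"))
            continue
        # forward-fill zeros with the previous sign, leading zeros backward
        filled = s.copy()
        for i in range(1, len(filled)):
            if filled[i] == 0:
                filled[i] = filled[i - 1]
        for i in range(nz[0] - 1, -1, -1):
            filled[i] = filled[i + 1]
        run_start = 0
        for i in range(1, len(filled) + 1):
            if i == len(filled) or filled[i] != filled[run_start]:
                direction = "up" if filled[run_start] > 0 else "down"
                regions.append((int(sel[run_start]), int(sel[i - 1]) + 1, direction))
                run_start = i
    return regions
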