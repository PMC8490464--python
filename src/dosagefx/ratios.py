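"""Ratio distributions of gene expression between karyotypes.

Per-gene ratios (experimental group mean / control group mean) are
partitioned by chromosome class relative to the dosage-varied arm, binned
at constant width (0.05 by default, 0.1 for percentage plots), and
summarized by the modal bin.  Two distributions are compared with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ARMS


def compute_ratios(
    means: pd.DataFrame,
    experimental: str,
    control: str,
    annotation: pd.DataFrame,
    varied_arm: str,
) -> pd.DataFrame:
    """Experimental/control ratio per gene, tagged by chromosome class.

    ``chrom_class`` is ``varied_arm`` for genes on the dosage-varied arm,
    ``X`` for X genes (when X is not the varied arm), else
    ``other_autosome``.  Control means must be strictly positive — the
    nonpositive filter upstream guarantees it; a violation here is an
    internal contract error.
    """
    for g in (experimental, control):
        if g not in means.columns:
            raise ValueError(f"group {g!r} not in means")
    if varied_arm not in ARMS:
        raise ValueError(f"unknown chromosome arm {varied_arm!r}")
    ann = annotation.set_index("gene_id")["arm"]
    genes = means.index.intersection(ann.index)
    exp_m = means.loc[genes, experimental].to_numpy(dtype=float)
    ctl_m = means.loc[genes, control].to_numpy(dtype=float)
    if (ctl_m <= 0).any() or (exp_m <= 0).any():
        raise RuntimeError(
            "nonpositive group mean reached ratio computation; "
            "the upstream filter contract is broken"
        )
    arm = ann.loc[genes].to_numpy()
    chrom_class = np.where(
        arm == varied_arm, "varied_arm", np.where(arm == "X", "X", "other_autosome")
    )
    return pd.DataFrame(
        {"gene_id": genes, "ratio": exp_m / ctl_m, "chrom_class": chrom_class}
    ).set_index("gene_id")


@dataclass
class RatioDistribution:
    """Constant-width binned ratio frequencies with an overflow count."""

    bin_edges: np.ndarray
    frequencies: np.ndarray  # counts, or percentages if as_percent
    overflow: int  # ratios >= the upper range limit
    n: int  # ratios inside the binned range
    as_percent: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def bin_distribution(
    ratios,
    width: float = 0.05,
    lo: float = 0.0,
    hi: float = 3.0,
    as_percent: bool = False,
) -> RatioDistribution:
    """Bin ratios into half-open bins [lo+k*w, lo+(k+1)*w).

    Ratios >= ``hi`` go to the overflow count, not a bin.  With
    ``as_percent`` frequencies are percentages of the in-range total
    (summing to 100), matching percentage-style plots at width 0.1.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if lo >= hi:
        raise ValueError("lo must be < hi")
    r = np.asarray(
        ratios["ratio"] if isinstance(ratios, pd.DataFrame) else ratios, dtype=float
    )
    if r.size == 0:
        raise ValueError("empty ratio set")
    n_bins = int(np.ceil((hi - lo) / width - 1e-9))
    edges = lo + width * np.arange(n_bins + 1)
    in_range = r[(r >= lo) & (r < edges[-1])]
    overflow = int((r >= edges[-1]).sum())
    idx = np.floor((in_range - lo) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)  # guard float roundoff at edges
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    n = int(len(in_range))
    if as_percent:
        freq = freq / n * 100.0
    else:
        freq = freq.astype(int)
    return RatioDistribution(edges, freq, overflow, n, as_percent)


def modal_peak(dist: RatioDistribution) -> float:
    """Center of the maximal-frequency bin.

    Ties resolve to the bin whose center is nearest ratio 1.0 (the
    no-change line); remaining ties to the lower bin.
    """
    freq = np.asarray(dist.frequencies, dtype=float)
    if not (freq > 0).any():
        raise ValueError("all bin frequencies are zero")
    centers = dist.bin_centers
    best = np.flatnonzero(freq == freq.max())
    order = sorted(best, key=lambda i: (abs(centers[i] - 1.0), centers[i]))
    return float(centers[order[0]])


@dataclass
class KSResult:
    D: float
    p_value: float


def ks_two_sample(a, b) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |F_a - F_b| over the pooled sample points;
    the p-value is the asymptotic series Q(lambda) = 2 sum_k (-1)^{k-1}
    exp(-2 k^2 lambda^2) with the standard small-sample correction
    lambda = (sqrt(n_e) + 0.12 + 0.11/sqrt(n_e)) D, n_e = n_a n_b/(n_a+n_b),
    clamped to (0, 1].
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    d = float(np.abs(fa - fb).max())
    n_e = a.size * b.size / (a.size + b.size)
    lam = (np.sqrt(n_e) + 0.12 + 0.11 / np.sqrt(n_e)) * d
    p = _ks_q(lam)
    return KSResult(d, float(min(max(p, np.finfo(float).tiny), 1.0)))


def _ks_q(lam: float, terms: int = 101) -> float:
    if lam <= 0:
        return 1.0
    k = np.arange(1, terms)
    s = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k ** 2 * lam ** 2))
    return float(s)
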