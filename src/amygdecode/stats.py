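"""Nonparametric statistics shared across the pipeline.

Implements the paired Wilcoxon signed-rank test (exact enumeration of the
sign-flip null for small samples), the tie-corrected Friedman test with a
batched variant used by the sliding-window and shuffle-null machinery,
Spearman rank correlation with an exact permutation p for small n, and
rank-based ROC AUC with the reflection convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "wilcoxon_signed_rank",
    "friedman_statistic",
    "friedman_chi2_batch_k3",
    "friedman_permutation_p",
    "spearman",
    "auc",
    "reflect_auc",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    pvalue: float


@dataclass(frozen=True)
class CorrelationResult:
    rs: float
    pvalue: float


def _signed_rank_cdf(double_ranks: np.ndarray) -> np.ndarray:
    """Exact pmf support of W+ = sum of ranks of positive differences.

    ``double_ranks`` are mid-ranks scaled by 2 so they are integers even
    with ties.  Returns the pmf over W+ on the grid 0..sum(double_ranks)
    (in units of half-ranks), built by dynamic-programming convolution of
    the 2^n equally likely sign assignments.
    """
    total = int(double_ranks.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in double_ranks.astype(int):
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    return pmf


def wilcoxon_signed_rank(paired_a, paired_b) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are discarded (Wilcoxon's original treatment) and tied
    absolute differences receive mid-ranks.  The null distribution of the
    positive-rank sum W+ is enumerated exactly for n <= 25 remaining pairs;
    larger samples use the normal approximation with tie and continuity
    corrections.  All differences zero yields p = 1 with a warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("need two equal-length 1-D samples")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(statistic=0.0, pvalue=1.0)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        double_ranks = np.rint(2 * ranks).astype(int)
        pmf = _signed_rank_cdf(double_ranks)
        k = int(round(2 * w_plus))
        p_le = pmf[: k + 1].sum()
        p_ge = pmf[k:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        sd = np.sqrt(var)
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(statistic=w_plus, pvalue=max(p, np.finfo(float).tiny))


def _midrank_small_k(x: np.ndarray) -> np.ndarray:
    """Mid-ranks along the last axis via pairwise comparisons (O(k^2));
    efficient for the k = 3 treatment axis used throughout."""
    less = (x[..., None, :] < x[..., :, None]).sum(axis=-1)
    equal = (x[..., None, :] == x[..., :, None]).sum(axis=-1)
    return 1.0 + less + 0.5 * (equal - 1)


def friedman_chi2_batch_k3(tables: np.ndarray) -> np.ndarray:
    """Tie-corrected Friedman chi-square for a batch of blocks x 3 tables.

    ``tables`` has shape (..., b, 3); returns chi2 with shape (...).
    Blocks whose three values are completely tied contribute tied mid-ranks;
    a table in which every block is fully tied yields chi2 = 0.
    """
    tables = np.asarray(tables, dtype=float)
    b, k = tables.shape[-2], tables.shape[-1]
    if k != 3:
        raise ValueError("batched variant requires exactly 3 treatments")
    r = _midrank_small_k(tables)  # (..., b, 3)
    col_sums = r.sum(axis=-2)  # (..., 3)
    ssbn = (col_sums**2).sum(axis=-1)
    uncorrected = 12.0 / (b * k * (k + 1)) * ssbn - 3.0 * b * (k + 1)
    # tie term per block: t^3 - t summed over tied groups; for k = 3 the
    # only patterns are one tied pair (6) or a fully tied triple (24)
    e01 = tables[..., :, 0] == tables[..., :, 1]
    e02 = tables[..., :, 0] == tables[..., :, 2]
    e12 = tables[..., :, 1] == tables[..., :, 2]
    all_eq = e01 & e02
    pair_count = e01.astype(int) + e02.astype(int) + e12.astype(int)
    tie_term = np.where(all_eq, 24, 6 * pair_count).sum(axis=-1)
    c = 1.0 - tie_term / (b * k * (k**2 - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(c > 0, uncorrected / np.where(c > 0, c, 1.0), 0.0)
    return np.maximum(chi2, 0.0)


def friedman_statistic(table) -> FriedmanResult:
    """Tie-corrected Friedman test on a blocks x k table (k treatments).

    Within-block mid-ranks; chi-square statistic with the standard tie
    correction; df = k - 1; p from the chi-square upper tail.  A table whose
    blocks are all completely tied gives chi2 = 0, p = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("need a 2-D table with at least 2 blocks")
    b, k = table.shape
    if k == 3:
        chi2 = float(friedman_chi2_batch_k3(table))
    else:
        r = np.apply_along_axis(sps.rankdata, 1, table)
        ssbn = (r.sum(axis=0) ** 2).sum()
        uncorrected = 12.0 / (b * k * (k + 1)) * ssbn - 3.0 * b * (k + 1)
        tie = 0.0
        for row in table:
            _, counts = np.unique(row, return_counts=True)
            tie += (counts**3 - counts).sum()
        c = 1.0 - tie / (b * k * (k**2 - 1))
        chi2 = max(uncorrected / c, 0.0) if c > 0 else 0.0
    df = k - 1
    p = float(sps.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return FriedmanResult(chi2=chi2, df=df, pvalue=max(p, np.finfo(float).tiny))


def friedman_permutation_p(
    table, n_permutations: int = 2000, seed: int | None = None
) -> float:
    """Permutation p for the Friedman chi-square: values are permuted
    independently within each block (the exact within-block exchangeability
    null), the tie-corrected statistic recomputed, and the upper tail
    estimated with the add-one rule."""
    table = np.asarray(table, dtype=float)
    b, k = table.shape
    if k != 3:
        raise ValueError("permutation p implemented for 3 treatments")
    observed = friedman_statistic(table).chi2
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, b, k))
    for i in range(b):
        idx = rng.permuted(
            np.broadcast_to(np.arange(k), (n_permutations, k)).copy(), axis=1
        )
        perms[:, i, :] = table[i, idx]
    chi2 = friedman_chi2_batch_k3(perms)
    exceed = int((chi2 >= observed - 1e-12).sum())
    return (1 + exceed) / (n_permutations + 1)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    p is computed by exhaustive permutation enumeration for n <= 9 and by
    the t approximation otherwise.  Constant input raises ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D samples, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman correlation undefined")
    n = x.size
    rs = float(sps.spearmanr(x, y).statistic)
    if n <= EXACT_SPEARMAN_MAX_N:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rs_all = (ryc[perms] @ rxc) / denom
        p = float((np.abs(rs_all) >= abs(rs) - 1e-12).mean())
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(rs=rs, pvalue=p)


def auc(sample_a, sample_b) -> float:
    """Rank-based ROC area: P(a > b) + 0.5 P(a = b) for random draws from
    the two samples (the Mann-Whitney statistic scaled to [0, 1])."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = sps.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return float((r_a - a.size * (a.size + 1) / 2.0) / (a.size * b.size))


def reflect_auc(a: float) -> float:
    """Fold an AUC below 0.5 to its equivalent above 0.5 (0.45 -> 0.55)."""
    if not 0.0 <= a <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    return max(a, 1.0 - a)
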