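"""Sorted-split screening: a lossless upper bound for the pairwise scan.

For one SNP pair, order the 9 joint-genotype cells by their case
proportion t_i / (s_i + t_i). A classical result on optimal binary splits
of a categorical predictor with two classes says the best binary grouping
of the categories is one of the 8 contiguous splits of this sorted order;
with fixed class margins the 2x2 chi-square is a fixed positive multiple
of the Gini gain, so the maximum chi-square over the 8 contiguous splits
equals the maximum over all 2^9 - 2 binary partitions of the cells. Every
compositional model's risk collapse is one such partition, hence
``max_split_statistic`` dominates every model statistic and screening at a
threshold tau never discards a pair whose best model statistic reaches
tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import PairCounts

__all__ = [
    "SortedRatioTable",
    "ScreenResult",
    "sorted_ratio_table",
    "max_split_statistic",
    "screen_pairs",
    "split_statistics_block",
]


@dataclass(frozen=True)
class SortedRatioTable:
    """The 9 genotype cells of a pair ordered by case proportion.

    ``order[m]`` is the row-major flat index (0..8) of the cell placed at
    sorted position m. Empty cells carry ratio -1 so they sort first; ties
    keep original cell order.
    """

    s: np.ndarray  # control counts, sorted order
    t: np.ndarray  # case counts, sorted order
    ratio: np.ndarray  # case proportions (-1 marks an empty cell)
    order: np.ndarray


@dataclass(frozen=True)
class ScreenResult:
    """Screening outcome for one SNP pair."""

    i: int
    j: int
    screen_statistic: float
    best_split: int  # cutpoint m, 1 <= m < 9: low group = sorted positions 1..m
    counts: PairCounts | None = None


def sorted_ratio_table(counts: PairCounts) -> SortedRatioTable:
    """Arrange the 9 cells of a pair's counts in ascending case proportion."""
    flat = counts.flat().astype(np.float64)
    s, t = flat[:, 0], flat[:, 1]
    tot = s + t
    ratio = np.where(tot > 0, t / np.maximum(tot, 1.0), -1.0)
    order = np.argsort(ratio, kind="stable")
    return SortedRatioTable(s=s[order], t=t[order], ratio=ratio[order], order=order)


def split_statistics_block(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Screening statistic for a block of count tables at once.

    Parameters
    ----------
    block : ndarray of shape (P, 3, 3, 2) or (P, 9, 2)
        Count tables for P pairs.

    Returns
    -------
    (statistics, cutpoints) : each of shape (P,)
        Max Eq-4 chi-square over the 8 contiguous sorted-ratio splits and
        the first cutpoint attaining it (1-based).
    """
    flat = np.asarray(block, dtype=np.float64).reshape(-1, 9, 2)
    s, t = flat[:, :, 0], flat[:, :, 1]
    tot = s + t
    ratio = np.where(tot > 0, t / np.maximum(tot, 1.0), -1.0)
    order = np.argsort(ratio, axis=1, kind="stable")
    cs = np.take_along_axis(s, order, axis=1).cumsum(axis=1)
    ct = np.take_along_axis(t, order, axis=1).cumsum(axis=1)
    a = cs[:, :8]
    c = ct[:, :8]
    b = cs[:, -1:] - a
    d = ct[:, -1:] - c
    n = cs[:, -1:] + ct[:, -1:]
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = (a * d - b * c) ** 2 * n
    stats = np.where(denom > 0, num / np.maximum(denom, 1.0), 0.0)
    return stats.max(axis=1), stats.argmax(axis=1) + 1


def max_split_statistic(counts: PairCounts) -> ScreenResult:
    """Maximum 2x2 chi-square over all binary groupings of the 9 cells.

    Computed from the 8 contiguous splits of the sorted ratio table; this
    equals the max over all 2^9 - 2 partitions and therefore bounds every
    model statistic for these counts.
    """
    stat, cut = split_statistics_block(counts.table[None])
    return ScreenResult(
        i=-1, j=-1, screen_statistic=float(stat[0]), best_split=int(cut[0]), counts=counts
    )


def screen_pairs(dataset, tau: float, keep_counts: bool = True) -> list[ScreenResult]:
    """Evaluate all L(L-1)/2 pairs and keep those with screening statistic >= tau.

    Pairs are visited in (i, j), i < j column order, so the output order is
    deterministic. Counting runs on the dataset's bit-planes.
    """
    if dataset.n_snps < 2:
        raise ValueError("screening requires at least 2 SNPs")
    if tau < 0:
        raise ValueError("tau must be non-negative")
    results: list[ScreenResult] = []
    for p in range(dataset.n_snps - 1):
        block = dataset.pair_counts_block(p)  # (L - p - 1, 3, 3, 2)
        stats, cuts = split_statistics_block(block)
        for off in np.flatnonzero(stats >= tau):
            q = p + 1 + int(off)
            results.append(
                ScreenResult(
                    i=p,
                    j=q,
                    screen_statistic=float(stats[off]),
                    best_split=int(cuts[off]),
                    counts=PairCounts(block[off]) if keep_counts else None,
                )
            )
    return results
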