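"""Contingency tables and the compositional-epistasis chi-square test.

For a pair of SNPs the data are a 3x3x2 table of genotype-by-phenotype
counts ``n_ijk`` (k = 0 controls, k = 1 cases). A candidate model collapses
the 9 genotype cells into low- and high-risk groups, giving a 2x2 risk
table (a, b / c, d) whose Pearson statistic

    X^2 = (ad - bc)^2 (a+b+c+d) / ((a+b)(c+d)(a+c)(b+d)),  df = 1,

measures how well the model's risk partition separates cases from
controls. A zero margin makes independence unassessable; by convention the
statistic is then 0 and the result is flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

from .models import ModelClass, N_LABELS, PenetranceTable, table_of_label

__all__ = [
    "PairCounts",
    "RiskTable",
    "ModelTestResult",
    "count_pair",
    "collapse_to_risk",
    "chi_square_2x2",
    "chi2_p_value",
    "model_statistic",
    "label_statistics",
    "MISSING",
]

MISSING = 3  # internal sentinel for a missing genotype call


@dataclass(frozen=True)
class PairCounts:
    """3x3x2 genotype-by-phenotype contingency table for one SNP pair.

    ``table[i, j, k]`` counts subjects with first-SNP genotype ``i``,
    second-SNP genotype ``j`` (0 = AA, 1 = Aa, 2 = aa) and phenotype ``k``
    (0 = control, 1 = case).
    """

    table: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.table, dtype=np.int64)
        if arr.shape != (3, 3, 2):
            raise ValueError(f"pair counts must have shape (3, 3, 2), got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        arr.setflags(write=False)
        object.__setattr__(self, "table", arr)

    @property
    def n(self) -> int:
        return int(self.table.sum())

    def flat(self) -> np.ndarray:
        """Counts flattened to shape (9, 2), cells in row-major order."""
        return self.table.reshape(9, 2)

    def swapped(self) -> "PairCounts":
        """Counts with the roles of the two SNPs exchanged."""
        return PairCounts(self.table.transpose(1, 0, 2))


@dataclass(frozen=True)
class RiskTable:
    """Collapsed 2x2 table: controls/cases split into low/high risk groups."""

    a: int  # control, low risk
    b: int  # control, high risk
    c: int  # case, low risk
    d: int  # case, high risk

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("risk-table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ModelTestResult:
    """Chi-square test of one model class against one pair's counts."""

    canonical_label: int
    statistic: float
    p_raw: float
    degenerate_flag: bool


def count_pair(
    genotypes_p: np.ndarray,
    genotypes_q: np.ndarray,
    phenotype: np.ndarray,
) -> PairCounts:
    """Tally the 3x3x2 contingency table for two genotype vectors.

    Genotype codes are 0/1/2; anything else (the sentinel 3, negatives)
    counts as missing. A subject missing at either SNP is dropped from the
    whole table (pairwise deletion).
    """
    gp = np.asarray(genotypes_p)
    gq = np.asarray(genotypes_q)
    ph = np.asarray(phenotype)
    if not (gp.shape == gq.shape == ph.shape) or gp.ndim != 1:
        raise ValueError("genotype and phenotype vectors must be 1-D and equal length")
    if not np.isin(ph, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    keep = (gp >= 0) & (gp <= 2) & (gq >= 0) & (gq <= 2)
    gp = gp[keep].astype(np.int64)
    gq = gq[keep].astype(np.int64)
    ph = ph[keep].astype(np.int64)
    idx = (gp * 3 + gq) * 2 + ph
    return PairCounts(np.bincount(idx, minlength=18).reshape(3, 3, 2))


def collapse_to_risk(counts: PairCounts, table: PenetranceTable) -> RiskTable:
    """Collapse a 3x3x2 count table into the model's 2x2 risk table."""
    high = table.values.astype(bool)
    ctrl = counts.table[:, :, 0]
    case = counts.table[:, :, 1]
    return RiskTable(
        a=int(ctrl[~high].sum()),
        b=int(ctrl[high].sum()),
        c=int(case[~high].sum()),
        d=int(case[high].sum()),
    )


def chi_square_2x2(risk: RiskTable) -> float:
    """Pearson chi-square (df = 1) of a 2x2 risk table, no continuity correction.

    Returns 0 when any margin is zero (degenerate table).
    """
    a, b, c, d = risk.a, risk.b, risk.c, risk.d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0
    return float((a * d - b * c) ** 2) * risk.n / denom


def chi2_p_value(statistic: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution."""
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be non-negative, got {statistic}")
    if df < 1:
        raise ValueError("degrees of freedom must be a positive integer")
    return float(sps.chi2.sf(statistic, df))


@lru_cache(maxsize=1)
def _high_masks() -> np.ndarray:
    """(512, 9) 0/1 matrix: row L marks the high-risk cells of label L."""
    bits = (np.arange(N_LABELS)[:, None] >> np.arange(8, -1, -1)[None, :]) & 1
    return bits.astype(np.float64)


def label_statistics(counts: PairCounts) -> np.ndarray:
    """Eq-4 chi-square statistic of every one of the 512 labels at once.

    Vectorized over labels; the workhorse of the testing stage.
    """
    flat = counts.flat().astype(np.float64)  # (9, 2)
    masks = _high_masks()  # (512, 9)
    n = flat.sum()
    tot_ctrl, tot_case = flat[:, 0].sum(), flat[:, 1].sum()
    b = masks @ flat[:, 0]
    d = masks @ flat[:, 1]
    a = tot_ctrl - b
    c = tot_case - d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    num = (a * d - b * c) ** 2 * n
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, num / np.maximum(denom, 1.0), 0.0)
    return stat


def model_statistic(counts: PairCounts, model: ModelClass) -> ModelTestResult:
    """Chi-square statistic of one model class: max over the class's orbit.

    A class's member tables induce different collapses of an asymmetric
    count table; taking the max over the orbit makes the class statistic
    invariant to swapping SNP roles or relabelling alleles. Complementary
    members give identical statistics, so at most 8 distinct collapses
    matter.
    """
    if model.is_degenerate:
        raise ValueError(
            "the constant model class {0, 511} has an empty risk column and "
            "cannot be tested"
        )
    best = 0.0
    all_degenerate = True
    for lab in model.members:
        risk = collapse_to_risk(counts, table_of_label(lab))
        stat = chi_square_2x2(risk)
        degenerate = (
            (risk.a + risk.b) == 0
            or (risk.c + risk.d) == 0
            or (risk.a + risk.c) == 0
            or (risk.b + risk.d) == 0
        )
        if not degenerate:
            all_degenerate = False
        if stat > best:
            best = stat
    return ModelTestResult(
        canonical_label=model.canonical_label,
        statistic=best,
        p_raw=chi2_p_value(best, 1),
        degenerate_flag=all_degenerate,
    )
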