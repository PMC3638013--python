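"""Two-stage (screen, then test) genome-wide compositional-epistasis scan.

The screening stage bounds every pair's best achievable model statistic by
the sorted-split maximum (see :mod:`cescan.screening`) and discards pairs
below tau; because the bound is exact the surviving set provably contains
every pair any model could call significant at the reporting threshold.
The testing stage evaluates each survivor against all 50 non-degenerate
model classes and Bonferroni-adjusts each raw p-value for the full family
of tests — pairs before screening times model classes, L(L-1)/2 x 50 —
which is what holds the family-wise error rate at its nominal level (the
best-model statistic is a maximum over all model collapses, with a null
tail about 50 times the df=1 tail).

The scan is exposed statsmodels-style: build an :class:`EpistasisScan`
from a dataset and a :class:`ScanConfig`, call ``fit()``, and read the
returned :class:`ScanResults` (``summary()``, ``frame()``,
``significant``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .models import ModelClass, nondegenerate_classes
from .screening import ScreenResult, screen_pairs
from .stats import PairCounts, chi2_p_value, label_statistics

__all__ = [
    "ScanConfig",
    "PairResult",
    "ScanResults",
    "EpistasisScan",
    "scan",
    "test_candidates",
    "comparison_p_value",
    "PATTERN_SEARCH_FACTOR",
]

# number of free sorted-ratio splits examined per pair; the per-pair p-value
# used in power comparisons is multiplied by this factor
PATTERN_SEARCH_FACTOR = 8


@dataclass(frozen=True)
class ScanConfig:
    """Configuration of the two-stage scan.

    tau
        Screening threshold on the chi-square scale. The default 20
        corresponds to an unadjusted p of 7.744e-6 — deliberately liberal,
        since Bonferroni is conservative.
    alpha
        Family-wise significance level applied to Bonferroni-adjusted
        p-values.
    single_locus_prefilter_p
        When set, SNPs whose single-locus test p-value falls below this
        threshold (significant individual effects) are removed before
        pairing.
    models_correction
        When True (default) the Bonferroni factor is pairs x models
        (L(L-1)/2 x 50). The per-pair best statistic is a maximum over all
        50 model classes, whose null tail is ~50x the df=1 tail, so the
        extra factor is what keeps the family-wise error at its nominal
        level; set False for the pairs-only convention (anti-conservative).
    pattern_correction_factor
        Extra multiplier on raw p-values (set to 8 to reproduce the
        power-comparison convention pair-wide).
    """

    tau: float = 20.0
    alpha: float = 0.1
    single_locus_prefilter_p: float | None = None
    models_correction: bool = True
    pattern_correction_factor: int = 1

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.pattern_correction_factor < 1:
            raise ValueError("pattern_correction_factor must be >= 1")


@dataclass(frozen=True)
class PairResult:
    """Testing-stage outcome for one SNP pair."""

    i: int
    j: int
    snp1_id: str
    snp2_id: str
    screen_statistic: float
    best_model_label: int
    best_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool
    model_statistics: dict[int, float] = field(repr=False)
    model_p_adjusted: dict[int, float] = field(repr=False)


def _class_member_arrays(
    classes: tuple[ModelClass, ...]
) -> list[tuple[int, np.ndarray]]:
    return [(c.canonical_label, np.fromiter(c.members, dtype=np.int64)) for c in classes]


def test_candidates(
    candidates: list[ScreenResult],
    classes: tuple[ModelClass, ...],
    config: ScanConfig,
    n_snps: int,
    dataset=None,
    snp_ids=None,
) -> list[PairResult]:
    """Test each screened pair against every non-degenerate model class.

    ``n_snps`` is L, the number of SNPs before screening; each raw p-value
    is Bonferroni-adjusted by L(L-1)/2 times the number of model classes
    (see :class:`ScanConfig.models_correction`) times any configured
    pattern factor. A class's statistic is the max over its orbit members'
    collapses, computed vectorized over all 512 labels at once.
    """
    n_tests = n_snps * (n_snps - 1) // 2
    members = _class_member_arrays(tuple(c for c in classes if not c.is_degenerate))
    factor = n_tests * config.pattern_correction_factor
    if config.models_correction:
        factor *= len(members)
    results: list[PairResult] = []
    for cand in candidates:
        counts = cand.counts
        if counts is None:
            if dataset is None:
                raise ValueError("candidate carries no counts and no dataset given")
            counts = dataset.pair_counts(cand.i, cand.j)
        stats = label_statistics(counts)
        model_stats: dict[int, float] = {}
        model_p_adj: dict[int, float] = {}
        best_label, best_stat = -1, -1.0
        for canonical, member_idx in members:
            stat = float(stats[member_idx].max())
            model_stats[canonical] = stat
            p_raw = chi2_p_value(stat, 1)
            model_p_adj[canonical] = min(1.0, p_raw * factor)
            if stat > best_stat:
                best_label, best_stat = canonical, stat
        p_raw = chi2_p_value(best_stat, 1)
        p_adj = min(1.0, p_raw * factor)
        ids = snp_ids or (dataset.snp_ids if dataset is not None else None)
        results.append(
            PairResult(
                i=cand.i,
                j=cand.j,
                snp1_id=ids[cand.i] if ids else f"SNP{cand.i + 1}",
                snp2_id=ids[cand.j] if ids else f"SNP{cand.j + 1}",
                screen_statistic=cand.screen_statistic,
                best_model_label=best_label,
                best_statistic=best_stat,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=p_adj <= config.alpha,
                model_statistics=model_stats,
                model_p_adjusted=model_p_adj,
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.i, r.j))
    return results


def comparison_p_value(counts: PairCounts) -> float:
    """Per-pair p-value used when comparing tests head-to-head.

    The best model statistic is found by searching the 8 sorted-ratio
    splits, so its raw df=1 tail probability is multiplied by 8.
    """
    stats = label_statistics(counts)
    stats[0] = stats[511] = 0.0  # constant class is untestable
    best = float(stats.max())
    return min(1.0, PATTERN_SEARCH_FACTOR * chi2_p_value(best, 1))


class ScanResults:
    """Results of a fitted epistasis scan.

    Attributes
    ----------
    pairs : list of PairResult
        All tested pairs, ordered by adjusted p-value.
    significant : list of PairResult
        The subset with ``p_adjusted <= alpha``.
    """

    def __init__(self, pairs, config, n_snps, n_subjects, snp_ids, n_screened):
        self.pairs = pairs
        self.config = config
        self.n_snps = n_snps
        self.n_subjects = n_subjects
        self.snp_ids = snp_ids
        self.n_screened = n_screened

    @property
    def n_tests(self) -> int:
        return self.n_snps * (self.n_snps - 1) // 2

    @property
    def significant(self) -> list[PairResult]:
        return [r for r in self.pairs if r.significant]

    def frame(self) -> pd.DataFrame:
        """Results as a DataFrame, one row per tested pair."""
        return pd.DataFrame(
            {
                "snp1_index": [r.i for r in self.pairs],
                "snp2_index": [r.j for r in self.pairs],
                "snp1_id": [r.snp1_id for r in self.pairs],
                "snp2_id": [r.snp2_id for r in self.pairs],
                "screen_stat": [r.screen_statistic for r in self.pairs],
                "best_model": [f"M{r.best_model_label}" for r in self.pairs],
                "best_stat": [r.best_statistic for r in self.pairs],
                "p_raw": [r.p_raw for r in self.pairs],
                "p_adjusted": [r.p_adjusted for r in self.pairs],
                "significant": [r.significant for r in self.pairs],
            }
        )

    def save(self, path, all_models: bool = False) -> None:
        from .io import write_results

        write_results(self.pairs, path, all_models=all_models)

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [
            "Compositional epistasis scan",
            "=" * 64,
            f"SNPs: {self.n_snps}    subjects: {self.n_subjects}"
            f"    pairs: {self.n_tests}",
            f"screening tau: {self.config.tau:g}"
            f"    pairs past screening: {self.n_screened}",
            f"Bonferroni tests: {self.n_tests}    alpha: {self.config.alpha:g}",
            f"significant pairs: {len(self.significant)}",
        ]
        if self.significant:
            lines.append("-" * 64)
            lines.append(
                f"{'snp1':>10} {'snp2':>10} {'model':>6} {'stat':>10} {'p_adj':>12}"
            )
            for r in self.significant[:20]:
                lines.append(
                    f"{r.snp1_id:>10} {r.snp2_id:>10} {'M' + str(r.best_model_label):>6}"
                    f" {r.best_statistic:>10.4g} {r.p_adjusted:>12.4e}"
                )
        return "\n".join(lines)


class EpistasisScan:
    """Two-stage compositional-epistasis scan over a case-control dataset.

    Parameters
    ----------
    dataset : GenotypeDataset
    config : ScanConfig, optional

    Examples
    --------
    >>> results = EpistasisScan(dataset, ScanConfig(tau=20, alpha=0.1)).fit()
    >>> print(results.summary())
    """

    def __init__(self, dataset, config: ScanConfig | None = None):
        if dataset.n_snps < 2:
            raise ValueError("scanning requires at least 2 SNPs")
        self.dataset = dataset
        self.config = config or ScanConfig()

    @classmethod
    def from_file(cls, path, format: str = "boost", config: ScanConfig | None = None):
        from .io import read_dataset

        return cls(read_dataset(path, format), config)

    def fit(self) -> ScanResults:
        """Run screening and testing; return the results object."""
        dataset = self.dataset
        config = self.config
        if config.single_locus_prefilter_p is not None:
            keep = [
                idx
                for idx in range(dataset.n_snps)
                if reference.single_locus_test(
                    dataset.genotypes[:, idx], dataset.phenotype
                )[1]
                >= config.single_locus_prefilter_p
            ]
            dataset = dataset.subset_snps(keep)
            if dataset.n_snps < 2:
                return ScanResults([], config, dataset.n_snps, dataset.n_subjects,
                                   dataset.snp_ids, 0)
        candidates = screen_pairs(dataset, config.tau)
        pairs = test_candidates(
            candidates,
            nondegenerate_classes(),
            config,
            dataset.n_snps,
            dataset=dataset,
        )
        return ScanResults(
            pairs,
            config,
            dataset.n_snps,
            dataset.n_subjects,
            dataset.snp_ids,
            len(candidates),
        )


def scan(dataset, config: ScanConfig | None = None) -> ScanResults:
    """Functional wrapper: ``EpistasisScan(dataset, config).fit()``."""
    return EpistasisScan(dataset, config).fit()


def reference_scan(dataset, which: str, config: ScanConfig | None = None) -> pd.DataFrame:
    """Exhaustive pairwise scan with one of the statistical-epistasis LRTs.

    ``which`` is ``"interaction"`` (df 4) or ``"full"`` (df 8). No
    screening applies — these statistics are not bounded by the
    sorted-split maximum — but the optional single-locus prefilter is
    honoured. Returns a DataFrame ordered by adjusted p-value.
    """
    if which not in ("interaction", "full"):
        raise ValueError("which must be 'interaction' or 'full'")
    config = config or ScanConfig()
    if config.single_locus_prefilter_p is not None:
        keep = [
            idx
            for idx in range(dataset.n_snps)
            if reference.single_locus_test(dataset.genotypes[:, idx], dataset.phenotype)[1]
            >= config.single_locus_prefilter_p
        ]
        dataset = dataset.subset_snps(keep)
    test = (
        reference.interaction_test if which == "interaction" else reference.full_association_test
    )
    n_tests = dataset.n_snps * (dataset.n_snps - 1) // 2
    rows = []
    for p in range(dataset.n_snps - 1):
        block = dataset.pair_counts_block(p)
        for off in range(block.shape[0]):
            q = p + 1 + off
            stat, p_raw = test(PairCounts(block[off]))
            rows.append(
                (
                    p,
                    q,
                    dataset.snp_ids[p],
                    dataset.snp_ids[q],
                    stat,
                    p_raw,
                    min(1.0, p_raw * n_tests),
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=["snp1_index", "snp2_index", "snp1_id", "snp2_id", "stat", "p_raw", "p_adjusted"],
    )
    frame["significant"] = frame["p_adjusted"] <= config.alpha
    return frame.sort_values(
        ["p_adjusted", "snp1_index", "snp2_index"], kind="stable"
    ).reset_index(drop=True)
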