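"""Two-locus disease-model simulator and power / type-I experiment drivers.

Disease models are specified on the odds scale by a 3x3 table built from a
baseline odds ``alpha`` and an effect parameter ``theta`` (four canonical
shapes are built in), or by an explicit 3x3 penetrance table. Genotypes at
the two causal loci follow Hardy-Weinberg equilibrium at a given minor
allele frequency and are independent across loci; the population disease
prevalence and the (broad-sense, observed-scale) heritability

    p(D)  = sum_i p(D|G_i) p(G_i)
    h^2   = sum_i (p(D|G_i) - p(D))^2 p(G_i) / (p(D) (1 - p(D)))

are controlled by solving numerically for (alpha, theta). Case-control
data are ascertained by rejection: draw a joint genotype, assign disease
by its penetrance, keep subjects until the case and control quotas fill.
Unassociated SNPs are HWE draws at frequencies uniform on a given range,
independent of the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import reference
from .io import GenotypeDataset
from .scan import ScanConfig, comparison_p_value, scan
from .stats import PairCounts, count_pair

__all__ = [
    "DiseaseModelSpec",
    "SimulatedDataset",
    "odds_table",
    "penetrance_from_odds",
    "odds_from_penetrance",
    "genotype_distribution",
    "prevalence",
    "heritability",
    "solve_parameters",
    "build_model",
    "simulate_case_control",
    "simulate_null",
    "power_experiment",
    "type1_experiment",
    "variance_decomposition",
    "PowerSetting",
]

N_MODELS = 4


def _odds_multipliers(model_id: int, theta: float) -> np.ndarray:
    u = 1.0 + theta
    if model_id == 1:  # multiplicative-within-epistatic block
        return np.array([[1, 1, 1], [1, u, u**2], [1, u**2, u**4]])
    if model_id == 2:  # threshold / interference shape
        return np.array([[1, u, u], [u, 1, 1], [u, 1, 1]])
    if model_id == 3:  # diagonal shape
        return np.array([[1, 1, u], [1, u, 1], [u, 1, 1]])
    if model_id == 4:  # checkerboard (XOR-like)
        return np.array([[1, u, 1], [u, 1, u], [1, u, 1]])
    raise ValueError(f"unknown disease model id {model_id}; expected 1-4")


def odds_table(model_id: int, alpha: float, theta: float) -> np.ndarray:
    """3x3 disease-odds table of one of the four built-in model shapes.

    Rows are genotypes AA, Aa, aa of the first locus; columns BB, Bb, bb
    of the second. ``alpha`` is the baseline odds; ``theta`` scales the
    effect.
    """
    if alpha <= 0:
        raise ValueError("alpha (baseline odds) must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return alpha * _odds_multipliers(model_id, theta)


def penetrance_from_odds(odds) -> np.ndarray:
    """Elementwise odds -> probability: p = odd / (1 + odd)."""
    odds = np.asarray(odds, dtype=np.float64)
    if (odds <= 0).any():
        raise ValueError("odds must be positive")
    return odds / (1.0 + odds)


def odds_from_penetrance(penetrance) -> np.ndarray:
    """Elementwise probability -> odds: odd = p / (1 - p)."""
    pen = np.asarray(penetrance, dtype=np.float64)
    if ((pen <= 0) | (pen >= 1)).any():
        raise ValueError("penetrance must lie strictly in (0, 1) to have finite odds")
    return pen / (1.0 - pen)


def genotype_distribution(maf, maf2: float | None = None) -> np.ndarray:
    """Joint distribution of the 9 two-locus genotypes under HWE and independence.

    Genotype order AA, Aa, aa per locus: frequencies (1-f)^2, 2f(1-f), f^2.
    """
    f1 = float(maf)
    f2 = f1 if maf2 is None else float(maf2)
    for f in (f1, f2):
        if not 0 < f < 0.5:
            raise ValueError(f"minor allele frequency must lie in (0, 0.5), got {f}")
    g1 = np.array([(1 - f1) ** 2, 2 * f1 * (1 - f1), f1**2])
    g2 = np.array([(1 - f2) ** 2, 2 * f2 * (1 - f2), f2**2])
    return np.outer(g1, g2)


def prevalence(penetrance, dist) -> float:
    """Population disease probability: penetrance averaged over genotypes."""
    return float((np.asarray(penetrance) * np.asarray(dist)).sum())


def heritability(penetrance, dist) -> float:
    """Observed-scale heritability: genotype variance of penetrance / p(1-p)."""
    pen = np.asarray(penetrance, dtype=np.float64)
    d = np.asarray(dist, dtype=np.float64)
    p = prevalence(pen, d)
    if not 0 < p < 1:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {p}")
    return float((((pen - p) ** 2) * d).sum() / (p * (1 - p)))


def _solve_alpha(model_id: int, theta: float, dist: np.ndarray, target_p: float) -> float:
    def gap(alpha: float) -> float:
        pen = penetrance_from_odds(odds_table(model_id, alpha, theta))
        return prevalence(pen, dist) - target_p

    # prevalence is monotone increasing in alpha, 0 at 0+ and 1 at infinity
    lo, hi = 1e-12, 1.0
    while gap(hi) < 0:
        hi *= 10.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid targets
            raise RuntimeError("failed to bracket alpha")
    return brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)


def solve_parameters(
    model_id: int,
    maf: float,
    target_prevalence: float,
    target_h2: float,
    theta_cap: float = 1e6,
) -> tuple[float, float]:
    """Solve (alpha, theta) so the model hits a target prevalence and heritability.

    Nested monotone root-finding: the inner solve fixes theta and finds the
    alpha matching the prevalence (monotone in alpha); the outer solve
    adjusts theta for the heritability (monotone in theta for the built-in
    shapes). Raises with the attainable supremum when the heritability
    target is out of reach.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    if target_h2 < 0:
        raise ValueError("target heritability must be non-negative")
    dist = genotype_distribution(maf)

    def h2_at(theta: float) -> float:
        alpha = _solve_alpha(model_id, theta, dist, target_prevalence)
        pen = penetrance_from_odds(odds_table(model_id, alpha, theta))
        return heritability(pen, dist)

    if target_h2 == 0:
        return _solve_alpha(model_id, 0.0, dist, target_prevalence), 0.0

    lo, hi = 0.0, 1.0
    while h2_at(hi) < target_h2:
        hi *= 4.0
        if hi > theta_cap:
            raise ValueError(
                f"heritability {target_h2} unattainable for model {model_id} at "
                f"MAF {maf}; attainable supremum ~ {h2_at(theta_cap):.6g}"
            )
    theta = brentq(lambda t: h2_at(t) - target_h2, lo, hi, xtol=1e-12, rtol=8.9e-16)
    alpha = _solve_alpha(model_id, theta, dist, target_prevalence)
    return alpha, theta


@dataclass(frozen=True)
class DiseaseModelSpec:
    """A fully specified two-locus disease model for simulation."""

    penetrance: np.ndarray
    maf: float
    maf2: float | None = None
    model_id: int | None = None
    alpha: float | None = None
    theta: float | None = None

    def __post_init__(self) -> None:
        pen = np.asarray(self.penetrance, dtype=np.float64)
        if pen.shape != (3, 3) or ((pen < 0) | (pen > 1)).any():
            raise ValueError("penetrance must be a 3x3 table of probabilities")
        pen.setflags(write=False)
        object.__setattr__(self, "penetrance", pen)

    @property
    def distribution(self) -> np.ndarray:
        return genotype_distribution(self.maf, self.maf2)

    @property
    def prevalence(self) -> float:
        return prevalence(self.penetrance, self.distribution)

    @property
    def heritability(self) -> float:
        return heritability(self.penetrance, self.distribution)


def build_model(
    model_id: int, maf: float, target_prevalence: float, target_h2: float
) -> DiseaseModelSpec:
    """Solve the parameters and assemble a ready-to-simulate model spec."""
    alpha, theta = solve_parameters(model_id, maf, target_prevalence, target_h2)
    pen = penetrance_from_odds(odds_table(model_id, alpha, theta))
    return DiseaseModelSpec(
        penetrance=pen, maf=maf, model_id=model_id, alpha=alpha, theta=theta
    )


class SimulatedDataset(GenotypeDataset):
    """A simulated case-control dataset; remembers its causal pair and seed."""

    def __init__(self, genotypes, phenotype, snp_ids=None, causal_pair=None, seed=None):
        super().__init__(genotypes, phenotype, snp_ids)
        self.causal_pair = causal_pair
        self.seed = seed

    def causal_counts(self) -> PairCounts:
        if self.causal_pair is None:
            raise ValueError("dataset has no embedded causal pair")
        p, q = self.causal_pair
        return count_pair(self.genotypes[:, p], self.genotypes[:, q], self.phenotype)


def _draw_causal_pair(
    penetrance: np.ndarray,
    dist: np.ndarray,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator,
    method: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint genotypes at the causal loci for cases (first) then controls."""
    pen = penetrance.reshape(9)
    probs = dist.reshape(9)
    if method == "conditional":
        case_w = probs * pen
        ctrl_w = probs * (1 - pen)
        if n_cases > 0 and case_w.sum() <= 0:
            raise ValueError("penetrance is identically 0: cannot ascertain cases")
        if n_controls > 0 and ctrl_w.sum() <= 0:
            raise ValueError("penetrance is identically 1: cannot ascertain controls")
        case_g = rng.choice(9, size=n_cases, p=case_w / case_w.sum())
        ctrl_g = rng.choice(9, size=n_controls, p=ctrl_w / ctrl_w.sum())
    elif method == "rejection":
        if n_cases > 0 and (probs * pen).sum() <= 0:
            raise ValueError("penetrance is identically 0: cannot ascertain cases")
        if n_controls > 0 and (probs * (1 - pen)).sum() <= 0:
            raise ValueError("penetrance is identically 1: cannot ascertain controls")
        cases: list[np.ndarray] = []
        controls: list[np.ndarray] = []
        need_cases, need_controls = n_cases, n_controls
        chunk = max(1024, 2 * (n_cases + n_controls))
        while need_cases > 0 or need_controls > 0:
            g = rng.choice(9, size=chunk, p=probs)
            diseased = rng.random(chunk) < pen[g]
            if need_cases > 0:
                take = g[diseased][:need_cases]
                cases.append(take)
                need_cases -= take.size
            if need_controls > 0:
                take = g[~diseased][:need_controls]
                controls.append(take)
                need_controls -= take.size
        case_g = np.concatenate(cases) if cases else np.empty(0, dtype=np.int64)
        ctrl_g = np.concatenate(controls) if controls else np.empty(0, dtype=np.int64)
    else:
        raise ValueError("method must be 'rejection' or 'conditional'")
    joint = np.concatenate([case_g, ctrl_g])
    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    return joint // 3, joint % 3, phenotype


def simulate_case_control(
    spec: DiseaseModelSpec,
    n_cases: int,
    n_controls: int,
    n_snps: int,
    null_maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator | None = None,
    causal_indices: tuple[int, int] = (0, 1),
    method: str = "rejection",
) -> SimulatedDataset:
    """Simulate a case-control dataset with one embedded epistatic pair.

    The two causal SNPs are ascertained through the disease model; the
    remaining ``n_snps - 2`` SNPs are HWE draws at frequencies uniform on
    ``null_maf_range``, independent of the phenotype.
    """
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs to embed a causal pair")
    p_idx, q_idx = causal_indices
    if p_idx == q_idx or not (0 <= p_idx < n_snps and 0 <= q_idx < n_snps):
        raise ValueError("causal indices must be two distinct valid SNP positions")
    rng = np.random.default_rng(seed)
    g1, g2, phenotype = _draw_causal_pair(
        spec.penetrance, spec.distribution, n_cases, n_controls, rng, method
    )
    n = n_cases + n_controls
    genotypes = np.empty((n, n_snps), dtype=np.int8)
    null_cols = [idx for idx in range(n_snps) if idx not in (p_idx, q_idx)]
    if null_cols:
        mafs = rng.uniform(*null_maf_range, size=len(null_cols))
        genotypes[:, null_cols] = rng.binomial(2, mafs[None, :], size=(n, len(null_cols)))
    genotypes[:, p_idx] = g1
    genotypes[:, q_idx] = g2
    return SimulatedDataset(
        genotypes,
        phenotype,
        causal_pair=(p_idx, q_idx),
        seed=seed if isinstance(seed, int) else None,
    )


def simulate_null(
    n_snps: int,
    n_samples: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator | None = None,
) -> SimulatedDataset:
    """Null dataset: all SNPs independent of a balanced phenotype."""
    if n_snps < 1 or n_samples < 2:
        raise ValueError("need at least 1 SNP and 2 subjects")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(*maf_range, size=n_snps)
    genotypes = rng.binomial(2, mafs[None, :], size=(n_samples, n_snps)).astype(np.int8)
    phenotype = np.zeros(n_samples, dtype=np.int8)
    phenotype[: n_samples // 2] = 1
    return SimulatedDataset(
        genotypes,
        phenotype,
        causal_pair=None,
        seed=seed if isinstance(seed, int) else None,
    )


@dataclass(frozen=True)
class PowerSetting:
    """One cell of the power study: a disease model and a sample size."""

    model_id: int
    maf: float
    h2: float
    prevalence: float = 0.1
    n_samples: int = 800  # balanced: half cases, half controls
    n_snps: int = 1000


def power_experiment(
    settings,
    n_replicates: int = 100,
    alpha_levels=(0.1, 0.2, 0.3),
    tests=("compositional", "interaction", "full"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Empirical power of the three pairwise tests over replicate datasets.

    For each replicate the causal pair's per-pair p-value (the x8
    split-search correction for the compositional test; the df-4 / df-8
    tails for the LRTs) is Bonferroni-adjusted by L(L-1)/2 and compared
    with each family-wise level. Returns a tidy DataFrame with columns
    (model_id, maf, h2, n_samples, test, alpha, power).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for setting in settings:
        spec = build_model(setting.model_id, setting.maf, setting.prevalence, setting.h2)
        n_half = setting.n_samples // 2
        n_tests = setting.n_snps * (setting.n_snps - 1) // 2
        hits = {t: {a: 0 for a in alpha_levels} for t in tests}
        for _ in range(n_replicates):
            ds = simulate_case_control(
                spec, n_half, setting.n_samples - n_half, setting.n_snps, seed=rng
            )
            counts = ds.causal_counts()
            p_values = {}
            if "compositional" in tests:
                p_values["compositional"] = comparison_p_value(counts)
            if "interaction" in tests:
                p_values["interaction"] = reference.interaction_test(counts)[1]
            if "full" in tests:
                p_values["full"] = reference.full_association_test(counts)[1]
            for t, p in p_values.items():
                p_adj = min(1.0, p * n_tests)
                for a in alpha_levels:
                    hits[t][a] += p_adj <= a
        for t in tests:
            for a in alpha_levels:
                rows.append(
                    (
                        setting.model_id,
                        setting.maf,
                        setting.h2,
                        setting.n_samples,
                        t,
                        a,
                        hits[t][a] / n_replicates,
                    )
                )
    return pd.DataFrame(
        rows, columns=["model_id", "maf", "h2", "n_samples", "test", "alpha", "power"]
    )


def type1_experiment(
    n_datasets: int = 100,
    n_snps: int = 2000,
    n_samples: int = 2000,
    alpha_levels=(0.01, 0.05, 0.1),
    config: ScanConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Family-wise type-I error of the full scan on null datasets.

    Each null dataset is scanned end to end (screening + testing); the
    empirical FWER at a nominal level is the fraction of datasets whose
    smallest Bonferroni-adjusted p-value falls at or below it.
    """
    base = config or ScanConfig()
    rng = np.random.default_rng(seed)
    min_p_adj = np.empty(n_datasets)
    for d in range(n_datasets):
        ds = simulate_null(n_snps, n_samples, seed=rng)
        results = scan(ds, base)
        min_p_adj[d] = min((r.p_adjusted for r in results.pairs), default=1.0)
    rows = [(a, float((min_p_adj <= a).mean())) for a in alpha_levels]
    return pd.DataFrame(rows, columns=["alpha", "fwer"])


def variance_decomposition(penetrance, dist) -> tuple[float, float, float]:
    """Split the heritability into marginal and interaction components.

    Under locus independence the centred penetrance decomposes
    orthogonally into two marginal (main-effect) deviations plus an
    interaction residual; the three scaled variances satisfy
    ``h2_total = h2_marginal + h2_interaction``. Requires an independent
    (rank-one) joint genotype distribution.
    """
    pen = np.asarray(penetrance, dtype=np.float64)
    d = np.asarray(dist, dtype=np.float64)
    row_m = d.sum(axis=1)
    col_m = d.sum(axis=0)
    if not np.allclose(d, np.outer(row_m, col_m), atol=1e-12):
        raise ValueError("variance decomposition requires independent loci")
    p = prevalence(pen, d)
    if not 0 < p < 1:
        raise ValueError("degenerate prevalence")
    denom = p * (1 - p)
    a = (pen * col_m[None, :]).sum(axis=1) - p  # row (locus 1) deviations
    b = (pen * row_m[:, None]).sum(axis=0) - p  # column (locus 2) deviations
    h2_marg = float(((a**2) * row_m).sum() + ((b**2) * col_m).sum()) / denom
    resid = pen - p - a[:, None] - b[None, :]
    h2_int = float(((resid**2) * d).sum()) / denom
    return h2_marg + h2_int, h2_marg, h2_int
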