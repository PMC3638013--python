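"""Comparison statistics: single-locus test and the two statistical-epistasis LRTs.

Statistical epistasis is tested on the logistic scale with nested
likelihood-ratio statistics over the 9 joint-genotype cells:

* null model: intercept only (1 parameter, log-likelihood ``L_0``);
* main-effects model: intercept plus two indicator terms per SNP
  (5 parameters, ``L_M``; requires an iterative fit);
* saturated ("full") model: one probability per cell (9 parameters,
  ``L_F``; closed form from the cell case proportions).

The interaction test is ``2 (L_F - L_M)`` on 4 df; the full-association
test is ``2 (L_F - L_0)`` on 8 df. Indicator (dummy) coding with two
levels per SNP is the only coding consistent with those degrees of
freedom. The two statistics telescope: full = interaction + main-effects.

The main-effects fit runs a Newton/IRLS iteration on the 9 weighted
covariate patterns, so its cost is independent of the sample size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import PairCounts, chi2_p_value

__all__ = [
    "LogisticFit",
    "single_locus_test",
    "full_association_test",
    "fit_main_effects",
    "interaction_test",
    "null_log_likelihood",
    "saturated_log_likelihood",
]


@dataclass(frozen=True)
class LogisticFit:
    """A fitted logistic model over the 9 genotype patterns."""

    params: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # 0 * log(0) == 0 convention
    out = np.zeros_like(np.broadcast_arrays(x, y)[0], dtype=np.float64)
    mask = x > 0
    out[mask] = x[mask] * np.log(np.broadcast_to(y, out.shape)[mask])
    return out


def single_locus_test(genotypes, phenotype) -> tuple[float, float]:
    """Pearson chi-square of the 3x2 genotype-by-phenotype table.

    Degrees of freedom start at 2 and drop by one for each genotype with
    no observations. A constant phenotype (or a single occupied genotype)
    gives statistic 0 and p = 1.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotype)
    if g.shape != y.shape or g.ndim != 1:
        raise ValueError("genotype and phenotype vectors must be 1-D and equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("phenotype must be binary 0/1")
    keep = (g >= 0) & (g <= 2)
    idx = g[keep].astype(np.int64) * 2 + y[keep].astype(np.int64)
    table = np.bincount(idx, minlength=6).reshape(3, 2).astype(np.float64)
    table = table[table.sum(axis=1) > 0]
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any():
        return 0.0, 1.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[0] - 1
    return stat, chi2_p_value(stat, df)


def null_log_likelihood(counts: PairCounts) -> float:
    """Log-likelihood of the intercept-only logistic model."""
    flat = counts.flat().astype(np.float64)
    n0, n1 = flat[:, 0].sum(), flat[:, 1].sum()
    n = n0 + n1
    if n == 0:
        return 0.0
    return float(_xlogy(np.array(n0), np.array(n0 / n)) + _xlogy(np.array(n1), np.array(n1 / n)))


def saturated_log_likelihood(counts: PairCounts) -> float:
    """Closed-form maximized log-likelihood of the saturated cell model."""
    flat = counts.flat().astype(np.float64)  # (9, 2)
    totals = flat.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = np.where(totals[:, None] > 0, flat / np.maximum(totals, 1.0)[:, None], 0.0)
    return float(_xlogy(flat, probs).sum())


def full_association_test(counts: PairCounts) -> tuple[float, float]:
    """LRT of the saturated model against the intercept-only model, df = 8."""
    stat = 2.0 * (saturated_log_likelihood(counts) - null_log_likelihood(counts))
    stat = max(stat, 0.0)
    return stat, chi2_p_value(stat, 8)


# design matrix over the 9 patterns: intercept + I(g_p=1), I(g_p=2), I(g_q=1), I(g_q=2)
_DESIGN = np.array(
    [
        [1.0, float(i == 1), float(i == 2), float(j == 1), float(j == 2)]
        for i in range(3)
        for j in range(3)
    ]
)


def fit_main_effects(
    counts: PairCounts, tol: float = 1e-8, max_iter: int = 50
) -> LogisticFit:
    """Maximize the main-effects logistic likelihood by Newton/IRLS.

    Works on the 9 weighted covariate patterns (trials = cell total,
    successes = cases). Starts at the intercept-only optimum, so the
    log-likelihood path is monotone from ``L_0`` upward (step halving
    guards each Newton step). Non-convergence within ``max_iter`` —
    typically quasi-separation — is flagged, not raised; the attained
    likelihood is still valid and sandwiched in ``[L_0, L_F]``.
    """
    flat = counts.flat().astype(np.float64)
    trials = flat.sum(axis=1)
    cases = flat[:, 1]
    n = trials.sum()
    n1 = cases.sum()
    beta = np.zeros(5)
    if n > 0 and 0 < n1 < n:
        beta[0] = np.log(n1 / (n - n1))
    elif n > 0:
        # all-case or all-control data: likelihood is maximized at +/- inf;
        # stay at a large finite intercept and report non-convergence
        beta[0] = 30.0 if n1 == n else -30.0

    def loglik(b: np.ndarray) -> float:
        eta = _DESIGN @ b
        # n_i * log(1 + exp(eta)) stabilised
        return float(cases @ eta - trials @ np.logaddexp(0.0, eta))

    ll = loglik(beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = _DESIGN @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = trials * mu * (1.0 - mu)
        grad = _DESIGN.T @ (cases - trials * mu)
        hess = _DESIGN.T @ (w[:, None] * _DESIGN)
        try:
            step = np.linalg.solve(hess + 1e-10 * np.eye(5), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # damped Newton: halve until the likelihood does not decrease
        scale = 1.0
        new_ll = loglik(beta + step)
        while new_ll < ll - 1e-12 and scale > 1e-8:
            scale *= 0.5
            new_ll = loglik(beta + scale * step)
        beta = beta + scale * step
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll
    return LogisticFit(
        params=beta, log_likelihood=ll, converged=converged, iterations=iterations
    )


def interaction_test(counts: PairCounts) -> tuple[float, float]:
    """LRT of the saturated model against the main-effects model, df = 4."""
    l_full = saturated_log_likelihood(counts)
    l_main = fit_main_effects(counts).log_likelihood
    stat = max(2.0 * (l_full - l_main), 0.0)
    return stat, chi2_p_value(stat, 4)
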