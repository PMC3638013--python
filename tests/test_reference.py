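"""Single-locus test and the nested likelihood-ratio statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from cescan import (
    PairCounts,
    build_model,
    count_pair,
    fit_main_effects,
    full_association_test,
    interaction_test,
    simulate_case_control,
    single_locus_test,
)
from cescan.reference import null_log_likelihood, saturated_log_likelihood
from conftest import perfect_model_counts


def statsmodels_lrt(counts, design_builder):
    """Independent LRT oracle via statsmodels IRLS on dummy-coded cells.

    Returns 2 * (ll_model - ll_null). Raw log-likelihoods are not directly
    comparable (the GLM binomial family carries the combinatorial constant),
    but the constant cancels in every likelihood ratio.
    """
    import statsmodels.api as sm

    flat = counts.flat().astype(float)
    keep = flat.sum(axis=1) > 0
    endog = np.column_stack([flat[keep, 1], flat[keep, 0]])  # successes, failures
    design = design_builder()[keep]
    model_ll = float(
        sm.GLM(endog, design, family=sm.families.Binomial()).fit().llf
    )
    null_ll = float(
        sm.GLM(endog, np.ones((int(keep.sum()), 1)), family=sm.families.Binomial())
        .fit()
        .llf
    )
    return 2.0 * (model_ll - null_ll)


class TestSingleLocus:
    def test_identical_distributions_score_zero(self):
        g = np.array([0, 0, 1, 1, 2, 2] * 10)
        y = np.array([0, 1] * 30)
        stat, p = single_locus_test(g, y)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_textbook_pearson(self):
        # 3x2 table [[10,20],[20,20],[30,10]]
        g = np.repeat([0, 0, 1, 1, 2, 2], [10, 20, 20, 20, 30, 10])
        y = np.tile([0, 1], 1)  # placeholder, build directly below
        g = np.concatenate(
            [np.full(10, 0), np.full(20, 0), np.full(20, 1), np.full(20, 1),
             np.full(30, 2), np.full(10, 2)]
        )
        y = np.concatenate(
            [np.zeros(10), np.ones(20), np.zeros(20), np.ones(20),
             np.zeros(30), np.ones(10)]
        ).astype(int)
        stat, p = single_locus_test(g, y)
        expected_stat, expected_p, dof, _ = sps.chi2_contingency(
            [[10, 20], [20, 20], [30, 10]], correction=False
        )
        assert dof == 2
        assert stat == pytest.approx(expected_stat, abs=1e-10)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_constant_phenotype_degenerates_gracefully(self):
        stat, p = single_locus_test(np.array([0, 1, 2, 1]), np.zeros(4, dtype=int))
        assert (stat, p) == (0.0, 1.0)

    def test_df_reduction_with_empty_genotype(self):
        # only genotypes 0 and 2 present -> df 1
        g = np.repeat([0, 0, 2, 2], [30, 10, 10, 30])
        y = np.concatenate([np.zeros(30), np.ones(10), np.zeros(10), np.ones(30)]).astype(int)
        stat, p = single_locus_test(g, y)
        assert p == pytest.approx(float(sps.chi2.sf(stat, 1)))


class TestFullAssociation:
    def test_identical_case_control_distribution_scores_zero(self):
        table = np.stack([np.full((3, 3), 5), np.full((3, 3), 5)], axis=-1)
        stat, p = full_association_test(PairCounts(table))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_closed_form_matches_statsmodels_oracle(self, random_counts_tables):
        checked = 0
        for counts in random_counts_tables[:40]:
            flat = counts.flat()
            # avoid separation-degenerate tables where the saturated IRLS fit
            # stops short of the boundary optimum
            if counts.n == 0 or (flat.min(axis=1) == 0).any():
                continue
            expected = statsmodels_lrt(counts, lambda: np.eye(9))
            got, _ = full_association_test(counts)
            assert got == pytest.approx(expected, abs=1e-6)
            checked += 1
        assert checked >= 10

    def test_p_value_uses_eight_df(self, random_counts_tables):
        counts = random_counts_tables[1]
        stat, p = full_association_test(counts)
        assert p == pytest.approx(float(sps.chi2.sf(stat, 8)))


class TestMainEffectsFit:
    def test_no_interaction_data_leaves_small_interaction_lrt(self, rng):
        # multiplicative odds across loci: logistic-additive, so L_M ~ L_F
        beta = np.array([-1.0, 0.4, 0.8, -0.3, -0.6])
        design = np.array(
            [[1, i == 1, i == 2, j == 1, j == 2] for i in range(3) for j in range(3)],
            dtype=float,
        )
        probs = 1 / (1 + np.exp(-design @ beta))
        n_per_cell = 4000
        flat = np.empty((9, 2), dtype=np.int64)
        flat[:, 1] = rng.binomial(n_per_cell, probs)
        flat[:, 0] = n_per_cell - flat[:, 1]
        counts = PairCounts(flat.reshape(3, 3, 2))
        fit = fit_main_effects(counts)
        assert fit.converged
        stat, p = interaction_test(counts)
        # 4-df chi-square under the null: grossly large values indicate a bug
        assert stat < 30.0
        assert fit.log_likelihood <= saturated_log_likelihood(counts) + 1e-9

    def test_separation_is_flagged_not_raised(self):
        table = np.zeros((3, 3, 2), dtype=np.int64)
        table[0, 0, 1] = 50  # all cases in one cell
        table[2, 2, 0] = 50
        counts = PairCounts(table)
        fit = fit_main_effects(counts)
        assert np.isfinite(fit.log_likelihood)
        assert null_log_likelihood(counts) <= fit.log_likelihood + 1e-9
        assert fit.log_likelihood <= saturated_log_likelihood(counts) + 1e-9

    def test_single_occupied_cell_does_not_crash(self):
        table = np.zeros((3, 3, 2), dtype=np.int64)
        table[1, 1, 0] = 7
        table[1, 1, 1] = 3
        fit = fit_main_effects(PairCounts(table))
        assert np.isfinite(fit.log_likelihood)

    def test_nested_likelihood_ordering(self, random_counts_tables):
        for counts in random_counts_tables[:40]:
            if counts.n == 0:
                continue
            l0 = null_log_likelihood(counts)
            lm = fit_main_effects(counts).log_likelihood
            lf = saturated_log_likelihood(counts)
            assert l0 <= lm + 1e-8 <= lf + 2e-8
            assert lf <= 0.0 + 1e-12

    def test_fit_matches_statsmodels_main_effects(self, random_counts_tables):
        def design():
            return np.array(
                [[1, i == 1, i == 2, j == 1, j == 2] for i in range(3) for j in range(3)],
                dtype=float,
            )

        checked = 0
        for counts in random_counts_tables[:15]:
            flat = counts.flat()
            if counts.n == 0 or (flat.min(axis=1) == 0).any():
                continue
            expected = statsmodels_lrt(counts, design)
            ours = 2.0 * (
                fit_main_effects(counts).log_likelihood - null_log_likelihood(counts)
            )
            assert ours == pytest.approx(expected, abs=1e-6)
            checked += 1
        assert checked >= 5


class TestLRTIdentities:
    def test_telescoping_identity(self, random_counts_tables):
        for counts in random_counts_tables[:40]:
            if counts.n == 0:
                continue
            full_stat, _ = full_association_test(counts)
            int_stat, _ = interaction_test(counts)
            main_stat = 2.0 * (
                fit_main_effects(counts).log_likelihood - null_log_likelihood(counts)
            )
            assert full_stat == pytest.approx(int_stat + main_stat, abs=1e-6)

    def test_xor_pattern_interaction_without_main_effects(self):
        # checkerboard (label 170): at MAF ~0.5 its marginal penetrances are
        # constant, so all signal is interaction
        spec_pen = np.where(
            np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]) > 0, 0.9, 0.05
        )
        from cescan import DiseaseModelSpec

        spec = DiseaseModelSpec(penetrance=spec_pen, maf=0.4999)
        ds = simulate_case_control(spec, 500, 500, 2, seed=11)
        counts = ds.causal_counts()
        int_stat, int_p = interaction_test(counts)
        assert int_p < 1e-6
        sl_ps = [
            single_locus_test(ds.genotypes[:, k], ds.phenotype)[1] for k in (0, 1)
        ]
        assert min(sl_ps) > 1e-4  # no strong marginal signal

    def test_interaction_p_uniform_under_no_interaction(self, model1_spec, rng):
        # model-1 disease data have main effects but its interaction term is real;
        # use a multiplicative model instead: odds exp(additive) => no interaction
        design = np.array(
            [[1, i == 1, i == 2, j == 1, j == 2] for i in range(3) for j in range(3)],
            dtype=float,
        )
        beta = np.array([-2.0, 0.5, 1.0, 0.3, 0.6])
        probs = 1 / (1 + np.exp(-design @ beta))
        p_values = []
        for _ in range(200):
            flat = np.empty((9, 2), dtype=np.int64)
            draws = rng.multinomial(800, np.full(9, 1 / 9))
            flat[:, 1] = rng.binomial(draws, probs)
            flat[:, 0] = draws - flat[:, 1]
            p_values.append(interaction_test(PairCounts(flat.reshape(3, 3, 2)))[1])
        # calibration: roughly uniform p-values
        frac = np.mean(np.array(p_values) < 0.05)
        assert 0.005 <= frac <= 0.12
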