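"""Polychorics, KMO, parallel analysis, EFA/CFA, Mokken scalability."""

import warnings

import numpy as np
import pytest

import promis_irt as pi
from promis_irt.assumptions import (
    cfa_one_factor,
    efa_wls,
    kmo,
    mokken_h,
    parallel_analysis,
    polychoric_corr,
    polychoric_matrix,
)


def discretize(z, cuts):
    return np.digitize(z, cuts)


CUTS = [0.36, 1.15, 1.83, 2.43]


class TestPolychoric:
    def test_unit_diagonal_and_symmetry(self, anxiety_cohort):
        sub = anxiety_cohort.select(anxiety_cohort.responses.index[:300])
        R = polychoric_matrix(sub)
        np.testing.assert_allclose(np.diag(R), 1.0)
        np.testing.assert_allclose(R, R.T, atol=1e-12)

    def test_recovers_bivariate_normal_correlation(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 5000)
        r = polychoric_corr(discretize(z[:, 0], CUTS), discretize(z[:, 1], CUTS))
        assert r == pytest.approx(0.5, abs=0.05)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(4)
        x = discretize(rng.normal(size=4000), CUTS)
        y = discretize(rng.normal(size=4000), [-1.0, 0.0, 1.0, 2.0])
        assert abs(polychoric_corr(x, y)) < 0.06

    def test_single_category_item_rejected(self):
        with pytest.raises(ValueError):
            polychoric_corr(np.zeros(100, dtype=int), np.arange(100) % 5)


class TestKMO:
    def test_equicorrelated_closed_form(self):
        # for an equicorrelated matrix the anti-image partial correlation is
        # -rho/(1+(p-2)rho); KMO follows in closed form from the definition
        rho, p = 0.5, 3
        R = np.full((p, p), rho)
        np.fill_diagonal(R, 1.0)
        q = rho / (1 + (p - 2) * rho)
        expected = rho**2 / (rho**2 + q**2)
        overall, per_item = kmo(R)
        assert overall == pytest.approx(expected, abs=1e-10)
        np.testing.assert_allclose(per_item, expected, atol=1e-10)

    def test_strong_single_factor_is_excellent(self):
        lam = np.full(15, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        overall, _ = kmo(R)
        assert overall > 0.90

    def test_two_block_structure_scores_lower(self):
        lam = np.full(15, 0.8)
        R1 = np.outer(lam, lam)
        np.fill_diagonal(R1, 1.0)
        R2 = np.eye(15)
        for block in (slice(0, 8), slice(8, 15)):
            sub = np.full((R2[block, block].shape[0],) * 2, 0.64)
            np.fill_diagonal(sub, 1.0)
            R2[block, block] = sub
        assert kmo(R2)[0] < kmo(R1)[0]


class TestParallelAnalysisAndEFA:
    def test_one_factor_data_retains_one(self, anxiety_bank):
        rng = np.random.default_rng(21)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 400), rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eig, retained, _ = parallel_analysis(m, n_random=10, seed=1)
        assert retained == 1
        assert eig[0] / eig[1] > 4
        assert eig[0] / len(anxiety_bank) > 0.20

    def test_independent_items_retain_none(self, anxiety_bank):
        rng = np.random.default_rng(22)
        # each item answered by an unrelated person: no common factor
        cols = {
            it.item_id: pi.simulate_responses(
                anxiety_bank.subset([it.item_id]), rng.normal(0, 1, 300), rng
            ).responses.iloc[:, 0].to_numpy()
            for it in anxiety_bank
        }
        import pandas as pd

        m = pi.ResponseMatrix(pd.DataFrame(cols))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, retained, _ = parallel_analysis(m, n_random=10, seed=2)
        assert retained == 0

    def test_rank_one_structure_recovered(self):
        lam = np.array([0.8, 0.7, 0.6, 0.5, 0.75])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        L, prop = efa_wls(R, 1)
        np.testing.assert_allclose(np.abs(L[:, 0]), lam, atol=1e-4)
        assert prop == pytest.approx(np.sum(lam**2) / 5, abs=1e-3)

    def test_simulated_bank_first_factor_share(self, anxiety_cohort):
        sub = anxiety_cohort.select(anxiety_cohort.responses.index[:400])
        R = polychoric_matrix(sub)
        _, prop = efa_wls(R, 1)
        assert prop > 0.20

    def test_agreement_with_direct_least_squares_oracle(self):
        R = np.array([
            [1.0, 0.42, 0.30, 0.35],
            [0.42, 1.0, 0.38, 0.33],
            [0.30, 0.38, 1.0, 0.45],
            [0.35, 0.33, 0.45, 1.0],
        ])
        from scipy.optimize import minimize

        mask = ~np.eye(4, dtype=bool)

        def loss(lam):
            res = R - np.outer(lam, lam)
            return np.sum(res[mask] ** 2)

        sol = minimize(loss, np.full(4, 0.6), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        L, _ = efa_wls(R, 1)
        np.testing.assert_allclose(np.abs(L[:, 0]), np.abs(sol.x), atol=0.02)


class TestCFA:
    def test_true_one_factor_model_fits(self, anxiety_cohort):
        sub = anxiety_cohort.select(anxiety_cohort.responses.index[:450])
        R = polychoric_matrix(sub)
        fit, residual, flagged = cfa_one_factor(R, 450)
        assert np.abs(residual).max() < 0.10
        assert fit["srmr"] < 0.08
        assert fit["cfi"] > 0.95
        assert flagged == []  # "no local dependence" verdict

    def test_planted_dependent_pair_flagged(self):
        lam = np.full(10, 0.7)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        R[2, 5] = R[5, 2] = R[2, 5] + 0.3  # extra association beyond the factor
        fit, residual, flagged = cfa_one_factor(R, 1000)
        assert any({i, j} == {2, 5} for i, j, _ in flagged)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            cfa_one_factor(np.eye(5), n=4)


class TestMokken:
    def test_perfect_guttman_scale_has_unit_h(self):
        # deterministic cumulative data: person i endorses the first items up
        # to their level; every pair is maximally covarying given marginals
        theta = np.repeat(np.arange(5), 20)
        data = np.column_stack([
            np.clip(theta - shift, 0, 4) for shift in (0, 1, 2)
        ])
        h_items, h_scale, _ = mokken_h(data, n_boot=0)
        np.testing.assert_allclose(h_items, 1.0, atol=1e-12)
        assert h_scale == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(31)
        data = rng.integers(0, 5, (3000, 6))
        _, h_scale, _ = mokken_h(data, n_boot=0)
        assert abs(h_scale) < 0.05

    def test_fixture_cohort_scales_strongly(self, anxiety_cohort):
        h_items, h_scale, se = mokken_h(anxiety_cohort, n_boot=30, seed=0)
        assert h_scale > 0.50
        assert np.all(h_items > 0.30)
        assert 0 < se < 0.1

    def test_zero_variance_item_rejected(self):
        data = np.column_stack([np.zeros(50, dtype=int), np.arange(50) % 5])
        with pytest.raises(ValueError):
            mokken_h(data, n_boot=0)
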