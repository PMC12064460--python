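"""Ordinal-logistic DIF: model fits, McFadden pseudo-R^2, scan operating
characteristics (specificity / sensitivity on planted effects)."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import promis_irt as pi
from promis_irt.dif import DIF_R2_THRESHOLD, null_loglik, ordinal_logistic_fit

from conftest import two_group_matrix


def simulate_polr(beta, n, rng, cutpoints=(-1.0, 0.0, 1.0, 2.0)):
    """Draw proportional-odds data with a single standard-normal covariate."""
    x = rng.normal(size=n)
    eta = beta * x
    cut = np.asarray(cutpoints)
    p_le = expit(cut[None, :] - eta[:, None])
    u = rng.random((n, 1))
    y = (u > p_le).sum(axis=1)
    return y, x


class TestOrdinalLogisticFit:
    def test_intercept_only_equals_closed_form(self):
        rng = np.random.default_rng(0)
        y, _ = simulate_polr(0.8, 500, rng)
        ll_null = null_loglik(y)
        counts = np.bincount(y)
        counts = counts[counts > 0]
        assert ll_null == pytest.approx(
            float(np.sum(counts * np.log(counts / counts.sum()))), abs=1e-12
        )

    def test_slope_recovery(self):
        rng = np.random.default_rng(1)
        y, x = simulate_polr(1.0, 2000, rng)
        beta, cut, ll = ordinal_logistic_fit(y, x[:, None])
        assert beta[0] == pytest.approx(1.0, abs=0.1)
        assert np.all(np.diff(cut) > 0)

    def test_agreement_with_derivative_free_oracle(self):
        """Direct Nelder-Mead maximization of the cumulative-logit
        likelihood reproduces the fit log-likelihood."""
        rng = np.random.default_rng(2)
        y, x = simulate_polr(0.7, 200, rng)
        _, _, ll_fit = ordinal_logistic_fit(y, x[:, None])
        cats = np.unique(y)
        y_rel = np.searchsorted(cats, y)
        m = cats.size

        def negll(params):
            beta, cut = params[0], np.sort(params[1:])
            p_le = expit(cut[None, :] - (beta * x)[:, None])
            full = np.hstack([np.zeros((len(y), 1)), p_le, np.ones((len(y), 1))])
            probs = full[np.arange(len(y)), y_rel + 1] - full[np.arange(len(y)), y_rel]
            return -np.sum(np.log(np.maximum(probs, 1e-12)))

        x0 = np.concatenate([[0.0], np.linspace(-1, 2, m - 1)])
        sol = minimize(negll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert ll_fit == pytest.approx(-sol.fun, abs=1e-4)

    def test_rank_deficiency_rejected(self):
        rng = np.random.default_rng(3)
        y, x = simulate_polr(0.5, 100, rng)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError):
            ordinal_logistic_fit(y, X)


class TestMcFadden:
    def test_identical_models_give_zero_change(self):
        assert pi.mcfadden_delta_r2(-100.0, -100.0, -150.0) == 0.0

    def test_nonnegative_and_nesting_guard(self):
        assert pi.mcfadden_delta_r2(-101.0, -100.0, -150.0) > 0
        with pytest.raises(ValueError):
            pi.mcfadden_delta_r2(-100.0, -101.0, -150.0)

    def test_planted_group_effect_exceeds_threshold(self):
        rng = np.random.default_rng(4)
        n = 1000
        g = np.repeat([0.0, 1.0], n // 2)
        y = np.zeros(n, dtype=int)
        y[: n // 2], _ = simulate_polr(0.0, n // 2, rng, cutpoints=(-1, 0, 1, 2))
        y[n // 2 :], _ = simulate_polr(0.0, n // 2, rng, cutpoints=(0.5, 1.5, 2.5, 3.5))
        ll_null = null_loglik(y)
        _, _, ll_g = ordinal_logistic_fit(y, g[:, None])
        assert pi.mcfadden_delta_r2(ll_null, ll_g, ll_null) > DIF_R2_THRESHOLD


class TestDIFScanInvariants:
    def test_nested_loglik_ordering_and_affine_invariance(self, anxiety_bank):
        rng = np.random.default_rng(5)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 400), rng)
        g = (rng.random(400) < 0.5).astype(float)
        theta, _ = pi.eap_score_matrix(m.values, anxiety_bank)
        y = m.values[:, 0].astype(int)
        ll_null = null_loglik(y)
        _, _, ll0 = ordinal_logistic_fit(y, theta[:, None])
        _, _, ll1 = ordinal_logistic_fit(y, np.column_stack([theta, g]))
        _, _, ll2 = ordinal_logistic_fit(y, np.column_stack([theta, g, theta * g]))
        assert ll_null <= ll0 + 1e-6 <= ll1 + 2e-6 <= ll2 + 3e-6
        # affine rescaling of the matching variable leaves the R^2 unchanged
        theta2 = 2.5 * theta - 1.0
        _, _, ll0b = ordinal_logistic_fit(y, theta2[:, None])
        d_a = pi.mcfadden_delta_r2(ll0, ll1, ll_null)
        _, _, ll1b = ordinal_logistic_fit(y, np.column_stack([theta2, g]))
        d_b = pi.mcfadden_delta_r2(ll0b, ll1b, ll_null)
        assert d_a == pytest.approx(d_b, abs=1e-4)

    def test_small_group_skipped_with_warning(self, anxiety_bank):
        rng = np.random.default_rng(6)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 60), rng)
        g = np.array(["a"] * 50 + ["b"] * 10)
        with pytest.warns(UserWarning, match="< 25"):
            assert pi.dif_scan(m, g, anxiety_bank) == []


class TestDIFOperatingCharacteristics:
    N_SEEDS = 20
    N_PER_GROUP = 750

    def test_specificity_no_dif_data(self, anxiety_bank):
        """Same bank in both groups: false-flag rate stays at or below 5%
        of item x seed combinations."""
        flags = 0
        total = 0
        for seed in range(self.N_SEEDS):
            rng = np.random.default_rng(1000 + seed)
            m, g = two_group_matrix(
                anxiety_bank, anxiety_bank, anxiety_bank, self.N_PER_GROUP, rng
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = pi.dif_scan(m, g, anxiety_bank)
            total += len(results)
            flags += sum(r.flagged for r in results)
        assert flags / total <= 0.05

    def test_sensitivity_uniform_shift(self, anxiety_bank):
        """+0.5 threshold shift on one focal-group item is flagged as
        uniform DIF in at least 90% of seeds."""
        target = "3150bR2r"
        focal = pi.inject_dif(anxiety_bank, [target], b_shift=0.5)
        hits = 0
        for seed in range(self.N_SEEDS):
            rng = np.random.default_rng(2000 + seed)
            m, g = two_group_matrix(
                anxiety_bank, anxiety_bank, focal, self.N_PER_GROUP, rng
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = pi.dif_scan(m, g, anxiety_bank)
            by_id = {r.item_id: r for r in results}
            hits += by_id[target].flagged and by_id[target].dif_type == "uniform"
        assert hits / self.N_SEEDS >= 0.90
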