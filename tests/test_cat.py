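"""Post-hoc CAT: item selection, stopping behavior, decile summaries."""

import numpy as np
import pandas as pd
import pytest

import promis_irt as pi
from promis_irt.grm import item_information


class TestItemSelection:
    def test_starting_item_is_argmax_information_at_zero(self, anxiety_bank):
        start = pi.select_starting_item(anxiety_bank)
        info = {i.item_id: item_information(i, 0.0) for i in anxiety_bank}
        assert start == max(info, key=info.get)

    def test_tie_break_prefers_bank_order(self):
        a = pi.ItemParameters("first", 2.0, (-0.5, 0.0, 0.5, 1.0))
        b = pi.ItemParameters("second", 2.0, (-0.5, 0.0, 0.5, 1.0))
        bank = pi.ItemBank("twins", (a, b))
        assert pi.select_starting_item(bank) == "first"

    def test_single_item_bank(self):
        bank = pi.ItemBank("solo", (pi.ItemParameters("only", 1.5, (0, 1, 2, 3)),))
        assert pi.select_starting_item(bank) == "only"
        assert pi.select_next_item(0.3, bank, ["only"]) == "only"

    def test_next_item_equals_exhaustive_argmax(self, anxiety_bank):
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = float(rng.uniform(-3, 3))
            remaining = list(rng.permutation(anxiety_bank.item_ids)[:8])
            chosen = pi.select_next_item(theta, anxiety_bank, remaining)
            info = [item_information(anxiety_bank[i], theta) for i in remaining]
            assert chosen == remaining[int(np.argmax(info))]

    def test_extreme_theta_prefers_high_thresholds(self):
        low = pi.ItemParameters("low", 2.0, (-2.0, -1.5, -1.0, -0.5))
        high = pi.ItemParameters("high", 2.0, (1.0, 1.5, 2.0, 2.5))
        bank = pi.ItemBank("pair", (low, high))
        assert pi.select_next_item(3.0, bank, ["low", "high"]) == "high"
        assert pi.select_next_item(-3.0, bank, ["low", "high"]) == "low"


class TestRunCAT:
    def test_huge_se_stop_halts_at_min_items(self, anxiety_bank):
        row = np.ones(15) * 2
        res = pi.run_cat(row, anxiety_bank, pi.CATConfig(se_stop=10.0, min_items=3))
        assert len(res.administered_items) == 3
        assert res.stopped_by == "se_rule"

    def test_tiny_se_stop_exhausts_bank_and_matches_full_eap(self, anxiety_bank):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 5, 15).astype(float)
        res = pi.run_cat(row, anxiety_bank, pi.CATConfig(se_stop=1e-6))
        assert res.stopped_by == "exhausted"
        assert len(res.administered_items) == 15
        full = pi.eap_score(row, anxiety_bank)
        assert res.final.theta == pytest.approx(full.theta, abs=1e-10)
        assert res.final.se == pytest.approx(full.se, abs=1e-10)

    def test_administered_items_unique(self, anxiety_bank):
        rng = np.random.default_rng(2)
        row = rng.integers(0, 5, 15).astype(float)
        res = pi.run_cat(row, anxiety_bank)
        assert len(set(res.administered_items)) == len(res.administered_items)

    def test_missing_recorded_response_skipped_with_warning(self, anxiety_bank):
        row = np.full(15, 2.0)
        start = pi.select_starting_item(anxiety_bank)
        row[anxiety_bank.item_ids.index(start)] = np.nan
        with pytest.warns(UserWarning, match="no recorded response"):
            res = pi.run_cat(row, anxiety_bank, pi.CATConfig(se_stop=1e-6))
        assert start not in res.administered_items
        assert len(res.administered_items) == 14

    def test_stop_rule_soundness_and_reliability(self, anxiety_bank):
        """stopped_by=se_rule implies SE <= 0.316 implies reliability >= 0.90."""
        rng = np.random.default_rng(3)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 200), rng)
        for i in range(200):
            res = pi.run_cat(m.values[i], anxiety_bank)
            if res.stopped_by == "se_rule":
                assert res.final.se <= 0.316
                assert res.final.reliability >= 0.90

    def test_se_mostly_monotone_within_administration(self, anxiety_bank):
        """EAP posterior SD shrinks with extra items in >= 95% of steps."""
        rng = np.random.default_rng(4)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 1000), rng)
        cfg = pi.CATConfig(se_stop=1e-6)  # force full administrations
        drops = total = 0
        for i in range(1000):
            res = pi.run_cat(m.values[i], anxiety_bank, cfg)
            ses = [t.se for t in res.theta_trace]
            diffs = np.diff(ses)
            drops += int((diffs <= 1e-12).sum())
            total += len(diffs)
        assert drops / total >= 0.95

    def test_mid_trait_tests_shorter_than_extreme_low(self, anxiety_bank):
        """The bank is informative around/above the mean, so a mid-trait
        simulee satisfies the precision rule sooner than a floor simulee."""
        rng = np.random.default_rng(5)
        mid = pi.simulate_responses(anxiety_bank, np.full(40, 0.5), rng)
        low = pi.simulate_responses(anxiety_bank, np.full(40, -1.5), rng)
        n_mid = np.mean([len(pi.run_cat(mid.values[i], anxiety_bank).administered_items)
                         for i in range(40)])
        n_low = np.mean([len(pi.run_cat(low.values[i], anxiety_bank).administered_items)
                         for i in range(40)])
        assert n_mid < n_low


class TestPosthocSimulation:
    def test_full_bank_mode_is_identity(self, anxiety_bank):
        rng = np.random.default_rng(6)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 60), rng)
        s = pi.posthoc_simulation(m, anxiety_bank, pi.CATConfig(se_stop=1e-9))
        assert s.overall["correlation_cat_vs_full"] == pytest.approx(1.0, abs=1e-12)
        assert s.overall["mean_rmse"] == pytest.approx(0.0, abs=1e-12)
        assert s.overall["mean_bias"] == pytest.approx(0.0, abs=1e-12)

    def test_small_samples_get_no_decile_table(self, anxiety_bank):
        rng = np.random.default_rng(7)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 12), rng)
        s = pi.posthoc_simulation(m, anxiety_bank)
        assert s.deciles is None
        assert s.overall["n"] == 12

    def test_decile_structure_and_low_end_gradient(self, anxiety_bank):
        """Deciles partition the sample; the lowest-trait deciles need the
        longest tests (information is concentrated above the mean)."""
        rng = np.random.default_rng(8)
        thetas = pi.thetas_from_decile_means(
            pi.ANXIETY_VALIDATION_DECILES["means"],
            pi.ANXIETY_VALIDATION_DECILES["counts"],
            jitter_sd=0.15,
            seed=rng,
        )
        m = pi.simulate_responses(anxiety_bank, thetas, rng)
        s = pi.posthoc_simulation(m, anxiety_bank)
        d = s.deciles
        assert list(d.index) == [f"D{i}" for i in range(1, 11)]
        assert d["n"].sum() == 196
        assert d["mean_theta"].is_monotonic_increasing
        assert d["mean_test_length"].iloc[0] == d["mean_test_length"].max()
        assert np.all(d["rmse"] >= d["mean_bias"].abs() - 1e-12)
        assert np.all((d["proportion_stop_satisfied"] >= 0)
                      & (d["proportion_stop_satisfied"] <= 1))

    def test_true_theta_reference(self, anxiety_bank):
        rng = np.random.default_rng(9)
        m = pi.simulate_responses(anxiety_bank, rng.normal(0, 1, 50), rng)
        s = pi.posthoc_simulation(m, anxiety_bank, reference="true_theta")
        assert s.reference == "true_theta"
        np.testing.assert_allclose(
            np.sort(s.per_person["ref_theta"]),
            np.sort(m.covariates["true_theta"]),
        )
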