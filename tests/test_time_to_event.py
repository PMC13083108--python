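"""Kaplan-Meier incidence, log-rank, Cox, competing-risk CIFs, Gray test."""

import numpy as np
import pandas as pd
import pytest

from vcipreterm import time_to_event as tte


class TestKmIncidence:
    def test_no_censoring_equals_empirical_cdf(self):
        times = np.array([200, 210, 220, 230, 240.0])
        codes = np.ones(5, dtype=int)
        curve = tte.km_incidence(times, codes)
        for i, t in enumerate(sorted(times)):
            assert curve.at(t) == pytest.approx((i + 1) / 5)

    def test_hand_product_limit_arithmetic(self):
        # events at 200, 220, 230, 250; term deliveries (censored) at 210, 240
        times = np.array([200, 210, 220, 230, 240, 250.0])
        codes = np.array([1, 2, 1, 1, 2, 1])
        curve = tte.km_incidence(times, codes)
        assert curve.at(200) == pytest.approx(1 - 5 / 6)
        assert curve.at(220) == pytest.approx(1 - 5 / 6 * 3 / 4)
        assert curve.at(230) == pytest.approx(1 - 5 / 6 * 3 / 4 * 2 / 3)
        assert curve.at(250) == pytest.approx(1.0)

    def test_all_competing_means_zero_incidence(self):
        curve = tte.km_incidence([260, 270, 280.0], [2, 2, 2])
        assert curve.at(300) == 0.0

    def test_landmark_evaluation_is_right_continuous(self):
        curve = tte.km_incidence([224, 260.0], [1, 2])
        assert curve.at(224) == pytest.approx(0.5)  # event on the landmark day
        assert curve.at(223.9) == 0.0


class TestLogrank:
    def test_identical_groups_give_zero(self):
        t = np.array([200, 220, 260, 280.0] * 2)
        c = np.array([1, 1, 2, 2] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        chi2, p = tte.logrank_test(t, c, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_two_event_time_hand_arithmetic(self):
        # A: events at 10, 20; B: term (censored) at 15, 25
        t = np.array([10, 20, 15, 25.0])
        c = np.array([1, 1, 2, 2])
        g = np.array(["a", "a", "b", "b"])
        chi2, p = tte.logrank_test(t, c, g)
        # t=10: E_A=1/2, V=1/4; t=20: E_A=1/2, V=1/4 -> (2-1)^2 / 0.5 = 2
        assert chi2 == pytest.approx(2.0, abs=1e-10)

    def test_complete_separation_is_significant(self):
        t = np.r_[np.linspace(200, 250, 50), np.full(50, 280.0)]
        c = np.r_[np.ones(50, int), np.full(50, 2, int)]
        g = np.array(["a"] * 50 + ["b"] * 50)
        _, p = tte.logrank_test(t, c, g)
        assert p < 0.01

    def test_zero_events_undefined(self):
        with pytest.raises(ValueError, match="zero events"):
            tte.logrank_test([260, 270.0], [2, 2], ["a", "b"])


class TestCox:
    def test_null_permutation_hr_centred_at_one(self):
        rng = np.random.default_rng(41)
        t = np.r_[rng.integers(200, 259, 30), rng.integers(259, 288, 170)]
        c = np.r_[np.ones(30, int), np.full(170, 2, int)]
        log_hrs = []
        for _ in range(100):
            x = rng.permutation(np.r_[np.ones(100), np.zeros(100)])
            hr, _, _, flagged = tte.cox_hr(t, c, x)
            if not flagged:
                log_hrs.append(np.log(hr))
        assert abs(np.mean(log_hrs)) < 0.15

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(43)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            x = np.r_[np.ones(1000), np.zeros(1000)]
            lam = 0.01 * np.where(x == 1, 3.0, 1.0)
            t = rng.exponential(1 / lam)
            c = np.ones(2000, dtype=int)
            hr, _, _, _ = tte.cox_hr(t, c, x)
            hits += 2.6 <= hr <= 3.4
        assert hits >= 0.9 * n_rep

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="constant"):
            tte.cox_hr([200, 210, 220, 230.0], [1, 1, 1, 1], [1, 1, 1, 1])
        hr, ci, p, flagged = tte.cox_hr(
            [200, 210, 260, 270.0], [1, 1, 2, 2], [1, 1, 0, 0]
        )
        assert flagged and np.isinf(hr)


class TestCifCompeting:
    def test_reduces_to_km_without_competing_events(self):
        rng = np.random.default_rng(47)
        t = rng.integers(200, 290, 40).astype(float)
        c = rng.choice([0, 1], 40, p=[0.3, 0.7])
        if not (c == 1).any():
            c[0] = 1
        cif = tte.cif_competing(t, c)
        km = tte.km_incidence(t, c)
        for ut in cif.index:
            assert cif.loc[ut, "cif_preterm"] == pytest.approx(km.at(ut), abs=1e-12)

    def test_eight_record_hand_arithmetic(self):
        t = np.array([200, 205, 210, 215, 220, 225, 230, 235.0])
        c = np.array([1, 2, 1, 0, 2, 1, 2, 1])
        cif = tte.cif_competing(t, c)
        assert cif.loc[210, "cif_preterm"] == pytest.approx(0.25)
        assert cif.loc[225, "cif_preterm"] == pytest.approx(0.40625)
        assert cif.loc[235, "cif_preterm"] == pytest.approx(0.5625)
        assert cif.loc[235, "cif_term"] == pytest.approx(0.4375)

    def test_all_competing_gives_zero_cif(self):
        cif = tte.cif_competing([260, 270, 280.0], [2, 2, 2])
        assert (cif["cif_preterm"] == 0).all()

    def test_conservation_at_every_jump(self, cohort):
        rec = tte.events_from_cohort(cohort)
        cif = tte.cif_competing(rec["time"], rec["code"])
        total = cif["cif_preterm"] + cif["cif_term"] + cif["surv"]
        assert np.allclose(total, 1.0, atol=1e-10)

    def test_km_dominates_cause_specific_cif(self, cohort):
        """1-KM (term censored) >= Aalen-Johansen CIF1 everywhere."""
        rec = tte.events_from_cohort(cohort)
        cif = tte.cif_competing(rec["time"], rec["code"])
        km = tte.km_incidence(rec["time"], rec["code"])
        for ut in cif.index:
            assert km.at(ut) >= cif.loc[ut, "cif_preterm"] - 1e-12


class TestGray:
    def test_reduces_to_logrank_without_competing_events(self):
        rng = np.random.default_rng(53)
        t = rng.integers(200, 290, 60).astype(float)
        c = np.ones(60, dtype=int)
        g = rng.choice(["a", "b"], 60)
        g[:2] = ["a", "b"]
        chi2_gray, _ = tte.gray_test(t, c, g)
        chi2_lr, _ = tte.logrank_test(t, c, g)
        assert chi2_gray == pytest.approx(chi2_lr, abs=1e-6)

    def test_identical_groups_are_null(self):
        t = np.array([200, 220, 260, 280.0] * 2)
        c = np.array([1, 1, 2, 2] * 2)
        g = np.array(["a"] * 4 + ["b"] * 4)
        chi2, _ = tte.gray_test(t, c, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_permutation_reference(self):
        rng = np.random.default_rng(59)
        n = 200
        grp = np.array(["a"] * 100 + ["b"] * 100)
        latent_risk = np.where(grp == "b", 0.25, 0.12)
        preterm = rng.random(n) < latent_risk
        t = np.where(preterm, rng.integers(200, 259, n), rng.integers(259, 288, n))
        c = np.where(preterm, 1, 2)
        chi2, p = tte.gray_test(t.astype(float), c, grp)
        stat_obs = chi2
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            gp = rng.permutation(grp)
            s, _ = tte.gray_test(t.astype(float), c, gp)
            hits += s >= stat_obs - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_perm)
        assert abs(p - p_perm) < max(5 * se, 0.04)

    def test_no_events_undefined(self):
        with pytest.raises(ValueError, match="cause-1"):
            tte.gray_test([260, 270.0], [2, 2], ["a", "b"])


class TestIncidenceTable:
    def test_landmark_table_structure(self, cohort):
        table = tte.incidence_table(cohort)
        assert len(table) == 8  # 2 groups x 4 landmarks
        assert set(table["landmark_days"]) == {224, 238, 252, 259}
        for _, grp in table.groupby("group"):
            inc = grp.sort_values("landmark_days")["cumulative_incidence"]
            assert (inc.diff().dropna() >= -1e-12).all()
            assert ((grp["ci_low"] <= grp["cumulative_incidence"] + 1e-12)
                    & (grp["cumulative_incidence"] <= grp["ci_high"] + 1e-12)).all()

    def test_vci_exceeds_control_incidence_at_term_landmark(self, cohort):
        table = tte.incidence_table(cohort).set_index(["group", "landmark_days"])
        assert (
            table.loc[("vci", 259), "cumulative_incidence"]
            > table.loc[("control", 259), "cumulative_incidence"]
        )

    def test_event_record_window_validation(self, cohort):
        bad = cohort.copy()
        bad.loc[bad.index[0], "ga_delivery"] = 190
        with pytest.raises(ValueError, match="196"):
            tte.events_from_cohort(bad)
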