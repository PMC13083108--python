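"""Tier assignment and the stratification validation battery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from vcipreterm import risk_strata as rs


class TestAssignTier:
    @pytest.mark.parametrize(
        "p, tier",
        [(0.05, "low"), (0.10, "moderate"), (0.30, "moderate"),
         (0.31, "high"), (0.0, "low"), (1.0, "high")],
    )
    def test_boundary_policy(self, p, tier):
        assert rs.assign_tier(p) == tier

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            rs.assign_tier(0.5, low=0.3, high=0.1)

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        p = rng.random(500)
        tiers = rs.assign_tier(p)
        assert set(tiers) <= {"low", "moderate", "high"}
        counts = {t: (tiers == t).sum() for t in rs.TIER_NAMES}
        assert sum(counts.values()) == 500


class TestCochranArmitage:
    def test_flat_rates_are_null(self):
        chi2, z, p = rs.cochran_armitage_trend([20, 20, 20], [100, 100, 100])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_steep_gradient_is_significant(self):
        _, _, p = rs.cochran_armitage_trend([10, 30, 60], [100, 100, 100])
        assert p < 0.001

    def test_matches_permutation_null(self):
        events, totals = [4, 8, 14], [40, 35, 30]
        chi2, z, p = rs.cochran_armitage_trend(events, totals)
        # permutation reference: shuffle outcomes across tiers
        rng = np.random.default_rng(17)
        y = np.r_[np.ones(sum(events)), np.zeros(sum(totals) - sum(events))]
        tier = np.repeat([1, 2, 3], totals)
        n_perm = 20_000
        s = np.asarray(totals, float)
        hits = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            e = np.array([yp[tier == t].sum() for t in (1, 2, 3)])
            pbar = y.mean()
            num = ((np.arange(1, 4)) * (e - s * pbar)).sum()
            hits += num >= (z * np.sqrt(
                pbar * (1 - pbar)
                * ((s * np.arange(1, 4) ** 2).sum()
                   - (s * np.arange(1, 4)).sum() ** 2 / s.sum())
            )) - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p - p_perm) < max(5 * se, 0.01)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            rs.cochran_armitage_trend([0, 0, 0], [10, 10, 10])


class TestSpearman:
    def test_identical_distinct_vectors(self):
        v = [0.1, 0.4, 0.2, 0.9]
        rho, _ = rs.spearman_outcome_correlation(v, v)
        assert rho == pytest.approx(1.0)

    def test_matches_rank_pearson_formula(self):
        """Events ranked above all non-events: rho equals the Pearson
        correlation of the (midrank) rank vectors, computed directly."""
        p = np.r_[np.linspace(0.5, 0.9, 10), np.linspace(0.05, 0.3, 30)]
        y = np.r_[np.ones(10), np.zeros(30)]
        rho, _ = rs.spearman_outcome_correlation(p, y)
        rp = stats.rankdata(p)
        ry = stats.rankdata(y)
        direct = np.corrcoef(rp, ry)[0, 1]
        assert rho == pytest.approx(direct, abs=1e-12)

    def test_null_permutation_behaviour(self):
        rng = np.random.default_rng(23)
        small = 0
        n_rep = 200
        for _ in range(n_rep):
            p = rng.random(500)
            y = rng.permutation([1] * 80 + [0] * 420)
            rho, _ = rs.spearman_outcome_correlation(p, y)
            small += abs(rho) < 0.1
        assert small >= 0.95 * n_rep

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rs.spearman_outcome_correlation([0.2] * 5, [1, 0, 1, 0, 1])


def _fisher_p_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum of tables no more probable than
    observed, at fixed margins."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    rv = stats.hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())


class TestFisherExact:
    def test_low_risk_vs_control_worked_example(self):
        orr, p, (lo, hi) = rs.fisher_exact_2x2(4, 58, 6, 99)
        assert orr == pytest.approx(1.14, abs=0.005)
        assert lo == pytest.approx(0.31, abs=0.005)
        assert hi == pytest.approx(4.20, abs=0.005)

    def test_symmetric_table(self):
        orr, p, _ = rs.fisher_exact_2x2(1, 1, 1, 1)
        assert orr == 1.0
        assert p == 1.0

    def test_transposition_invariance_of_p(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            a, b, c, d = rng.integers(1, 15, 4)
            _, p1, _ = rs.fisher_exact_2x2(a, b, c, d)
            _, p2, _ = rs.fisher_exact_2x2(a, c, b, d)
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 16, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            _, p, _ = rs.fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(_fisher_p_oracle(a, b, c, d), abs=1e-10)

    def test_zero_cell_or_convention(self):
        orr, _, (lo, hi) = rs.fisher_exact_2x2(0, 10, 5, 5)
        assert orr == 0.0
        assert 0 < lo < hi < np.inf  # Haldane-corrected CI stays finite


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x, n, lo, hi",
        [(13, 28, 0.275, 0.661), (4, 62, 0.018, 0.157), (7, 45, 0.065, None)],
    )
    def test_worked_examples_to_three_decimals(self, x, n, lo, hi):
        got_lo, got_hi = rs.clopper_pearson(x, n)
        assert got_lo == pytest.approx(lo, abs=5e-4)
        if hi is not None:
            assert got_hi == pytest.approx(hi, abs=5e-4)

    def test_boundary_cases(self):
        lo, hi = rs.clopper_pearson(0, 10)
        assert lo == 0.0
        lo, hi = rs.clopper_pearson(10, 10)
        assert hi == 1.0

    def test_exhaustive_coverage_small_n(self):
        """Coverage >= nominal for every n <= 30 over a fine p grid."""
        for n in range(1, 31):
            xs = np.arange(n + 1)
            bounds = np.array([rs.clopper_pearson(int(x), n) for x in xs])
            for p in np.linspace(0.01, 0.99, 49):
                pmf = stats.binom.pmf(xs, n, p)
                inside = (bounds[:, 0] <= p) & (p <= bounds[:, 1])
                assert pmf[inside].sum() >= 0.95 - 1e-9


class TestStratificationReport:
    def test_reproduces_printed_tier_rates(self):
        """62/45/28 split with 4/7/13 events gives 6.5/15.6/46.4% rates."""
        p = np.r_[np.full(62, 0.05), np.full(45, 0.2), np.full(28, 0.5)]
        y = np.r_[np.ones(4), np.zeros(58), np.ones(7), np.zeros(38),
                  np.ones(13), np.zeros(15)]
        ctrl = np.r_[np.ones(6), np.zeros(99)]
        rep = rs.stratification_report(p, y, ctrl)
        rates = rep.tiers.set_index("tier")["event_rate"]
        assert rates["low"] == pytest.approx(0.065, abs=5e-4)
        assert rates["moderate"] == pytest.approx(0.156, abs=5e-4)
        assert rates["high"] == pytest.approx(0.464, abs=5e-4)
        assert rep.fisher_or == pytest.approx(1.14, abs=0.005)
        assert rep.overall_df == 2
        assert rep.trend_p < 0.001

    def test_single_tier_degenerate_report(self):
        p = np.full(30, 0.02)
        y = np.r_[np.ones(2), np.zeros(28)]
        with pytest.warns(UserWarning, match="empty tier"):
            rep = rs.stratification_report(p, y, np.zeros(20))
        assert rep.trend_chi2 is None
        assert set(rep.empty_tiers) == {"moderate", "high"}

    def test_tier_counts_partition_cohort(self, scored_vci):
        from vcipreterm import model_build as mb

        fitted = mb.build_model(4, scored_vci, seed=0)
        rep = rs.stratification_report(
            fitted.predicted, scored_vci["preterm"], np.zeros(10)
        )
        assert rep.tiers["n"].sum() == len(scored_vci)

    def test_monotone_tier_rates_on_calibrated_cohorts(self):
        """Tier event rates are nondecreasing in most synthetic replicates."""
        import vcipreterm.growth_reference as gr
        import vcipreterm.model_build as mb
        import vcipreterm.synthetic_cohort as sc

        ok = 0
        n_rep = 30
        for s in range(n_rep):
            cfg = dataclasses.replace(sc.SimConfig(), seed=900 + s)
            c = sc.generate_cohort(cfg)
            curves = gr.fit_reference_curves(c[c.group == "control"])
            scored = gr.score_cohort(c, curves)
            vci = scored[scored.group == "vci"].reset_index(drop=True)
            fitted = mb.build_model(4, vci, seed=0)
            rep = rs.stratification_report(
                fitted.predicted, vci["preterm"],
                scored.loc[scored.group == "control", "preterm"],
            )
            rates = rep.tiers["event_rate"].to_numpy()
            rates = rates[np.isfinite(rates)]
            ok += bool(np.all(np.diff(rates) >= -1e-12))
        assert ok >= 0.7 * n_rep
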