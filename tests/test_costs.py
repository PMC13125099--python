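import numpy as np
import pandas as pd
import pytest

from survext import (
    CostSeries,
    ScenarioConfig,
    cost_per_life_year,
    cpi_adjust,
    extrapolate_costs,
    lifetime_cost,
    make_cohort,
    make_costs,
    make_cpi,
    make_life_table,
    mean_monthly_cost,
    terminal_profile,
)
from survext.costs import discount_factors
from survext.survival import EXTRAPOLATED, OBSERVED, SurvivalCurve

from conftest import build_cohort


def cost_rows(rows):
    return pd.DataFrame(rows, columns=["id", "month", "cost", "year"])


class TestCpiAdjustment:
    def test_pure_fx_division(self):
        raw = cost_rows([(0, 0, 3044.0, 2017)])
        cpi = pd.Series({2017: 100.0})
        out = cpi_adjust(raw, cpi, base_year=2017, fx=30.44)
        assert out["cost"].iloc[0] == pytest.approx(100.0, abs=1e-10)

    def test_deflation_arithmetic(self):
        raw = cost_rows([(0, 0, 1000.0, 2010)])
        cpi = pd.Series({2010: 95.0, 2017: 100.0})
        out = cpi_adjust(raw, cpi, base_year=2017, fx=1.0)
        assert out["cost"].iloc[0] == pytest.approx(1000.0 * 100 / 95, abs=1e-9)

    def test_round_trip(self):
        raw = cost_rows([(0, m, 100.0 + m, 2000 + m) for m in range(5)])
        cpi = pd.Series({2000 + m: 90.0 + m for m in range(5)} | {2017: 104.0})
        fwd = cpi_adjust(raw, cpi, base_year=2017, fx=30.44)
        inv = pd.Series({y: 1.0 / v for y, v in cpi.items()})
        back = cpi_adjust(fwd, inv, base_year=2017, fx=1.0 / 30.44)
        np.testing.assert_allclose(back["cost"], raw["cost"], atol=1e-9)

    def test_missing_cpi_year_rejected(self):
        raw = cost_rows([(0, 0, 1.0, 1999)])
        with pytest.raises(ValueError, match="does not cover"):
            cpi_adjust(raw, pd.Series({2017: 100.0}), base_year=2017, fx=1.0)


class TestMeanMonthlyCost:
    def test_hand_computed_example(self):
        # A alive months 0-2 at 100/month, B alive only month 0 with 300
        cohort = build_cohort([3, 1], [0, 1])
        costs = cost_rows(
            [(0, 0, 100.0, 2000), (0, 1, 100.0, 2000), (0, 2, 100.0, 2000),
             (1, 0, 300.0, 2000)]
        )
        series = mean_monthly_cost(costs, cohort)
        np.testing.assert_allclose(series.c, [200.0, 100.0, 100.0])

    def test_no_claims_contribute_zero(self):
        cohort = build_cohort([4], [0])
        series = mean_monthly_cost(cost_rows([(0, 1, 50.0, 2000)]), cohort)
        np.testing.assert_allclose(series.c, [0.0, 50.0, 0.0, 0.0])

    def test_single_patient_costs_pass_through(self):
        cohort = build_cohort([3], [1])
        costs = cost_rows([(0, m, 10.0 * (m + 1), 2000) for m in range(3)])
        series = mean_monthly_cost(costs, cohort)
        np.testing.assert_allclose(series.c, [10.0, 20.0, 30.0])

    def test_orphan_and_late_rows_rejected(self):
        cohort = build_cohort([3], [0])
        with pytest.raises(ValueError, match="orphan"):
            mean_monthly_cost(cost_rows([(9, 0, 1.0, 2000)]), cohort)
        with pytest.raises(ValueError, match="exit month"):
            mean_monthly_cost(cost_rows([(0, 3, 1.0, 2000)]), cohort)


class TestTerminalProfile:
    def test_exact_change_point_on_noise_free_surge(self):
        # decedents spend 100/month except 1000 in their final 3 months
        n, f = 6, 10
        cohort = build_cohort([f] * n, [1] * n)
        rows = []
        for pid in range(n):
            for m in range(f):
                k = (f - 1) - m
                rows.append((pid, m, 1000.0 if k < 3 else 100.0, 2000))
        profile = terminal_profile(cost_rows(rows), cohort, max_L=12)
        assert profile.L == 3
        np.testing.assert_allclose(profile.c_term, [1000.0] * 3)
        assert profile.c_stable == pytest.approx(100.0)

    def test_flat_costs_degenerate_to_l1(self):
        cohort = build_cohort([6, 6], [1, 1])
        rows = [(pid, m, 77.0, 2000) for pid in range(2) for m in range(6)]
        profile = terminal_profile(cost_rows(rows), cohort, max_L=6)
        assert profile.L == 1
        assert profile.c_term[0] == pytest.approx(profile.c_stable)

    def test_scan_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        n, f, max_L = 15, 24, 12
        died = [1] * 10 + [0] * 5
        cohort = build_cohort([f] * n, died)
        cost = rng.lognormal(4, 0.8, size=(n, f))
        cost[:10, -4:] *= 6  # surge in final 4 months of decedents
        rows = [(pid, m, cost[pid, m], 2000) for pid in range(n) for m in range(f)]
        profile = terminal_profile(cost_rows(rows), cohort, max_L=max_L)

        # brute force over all candidate window lengths
        k = np.full((n, f), -1)
        for pid in range(10):
            k[pid] = (f - 1) - np.arange(f)
        best = None
        for L in range(1, max_L + 1):
            term = (k >= 0) & (k < L)
            diff = abs(cost[term].mean() - cost[~term].mean())
            if best is None or diff > best[0] + 1e-12:
                best = (diff, L)
        assert profile.L == best[1]
        expected_term = [cost[k == kk].mean() for kk in range(profile.L)]
        np.testing.assert_allclose(profile.c_term, expected_term, rtol=1e-12)

    def test_requires_a_decedent(self):
        cohort = build_cohort([5], [0])
        with pytest.raises(ValueError, match="decedent"):
            terminal_profile(cost_rows([(0, 0, 1.0, 2000)]), cohort)


def ext_curve(S_obs, S_ext):
    S = np.concatenate([S_obs, S_ext])
    src = np.concatenate(
        [np.full(len(S_obs), OBSERVED, object), np.full(len(S_ext), EXTRAPOLATED, object)]
    )
    return SurvivalCurve(np.arange(len(S)), S, np.full(len(S), np.nan), src)


def obs_series(c):
    return CostSeries(np.arange(len(c)), c, np.full(len(c), OBSERVED, object))


class TestCostExtrapolation:
    def test_equal_terminal_and_stable_costs_are_hazard_free(self):
        from survext.costs import TerminalProfile

        curve = ext_curve([1.0, 0.9, 0.8], np.exp(-0.3 * np.arange(1, 6)) * 0.8)
        profile = TerminalProfile(L=3, c_term=[80.0] * 3, c_stable=80.0)
        full = extrapolate_costs(obs_series([80.0, 80.0]), profile, curve)
        np.testing.assert_allclose(full.c, 80.0)

    def test_certain_death_weights_terminal_cost_only(self):
        from survext.costs import TerminalProfile

        # hazard ~1 at the takeoff month: next-month survival collapses
        curve = ext_curve([1.0, 0.9, 0.8], [0.8 * 1e-9])
        profile = TerminalProfile(L=2, c_term=[900.0, 500.0], c_stable=50.0)
        full = extrapolate_costs(obs_series([50.0, 50.0]), profile, curve)
        # p_0 ~ 1 => cost ~ c_term[0]
        assert full.c[-1] == pytest.approx(900.0, rel=1e-6)

    def test_matches_monte_carlo_over_constant_hazard(self):
        from survext.costs import TerminalProfile

        rho = 0.85
        S_obs = rho ** np.arange(25)
        S_ext = rho ** np.arange(25, 60)
        curve = ext_curve(S_obs, S_ext)
        profile = TerminalProfile(L=3, c_term=[900.0, 600.0, 300.0], c_stable=100.0)
        full = extrapolate_costs(obs_series(100.0 * np.ones(25)), profile, curve)

        rng = np.random.default_rng(22)
        n = 200_000
        resid = rng.geometric(1 - rho, n) - 1  # months until death from any alive month
        draws = np.where(
            resid < 3, np.asarray([900.0, 600.0, 300.0])[np.minimum(resid, 2)], 100.0
        )
        mc, se = draws.mean(), draws.std(ddof=1) / np.sqrt(n)
        # constant hazard: the extrapolated mean cost is the same at every
        # month, except the final L-1 months that see the curve-end truncation
        assert np.allclose(full.c[25:-3], full.c[25], rtol=1e-9)
        assert abs(full.c[25] - mc) < 3 * se


class TestLifetimeCost:
    def test_zero_cost_is_exactly_zero(self):
        curve = ext_curve([1.0, 0.9], [0.5, 0.2])
        series = CostSeries(np.arange(4), np.zeros(4),
                            np.array([OBSERVED] * 2 + [EXTRAPOLATED] * 2, object))
        assert lifetime_cost(series, curve) == 0.0

    def test_geometric_closed_form_undiscounted(self):
        T = 300
        rho = np.exp(-0.02)
        S = rho ** np.arange(T + 1)
        curve = SurvivalCurve(np.arange(T + 1), S, np.full(T + 1, np.nan))
        series = obs_series(100.0 * np.ones(T + 1))
        expected = 100.0 * (1 - rho ** (T + 1)) / (1 - rho)
        assert lifetime_cost(series, curve, annual_discount=0.0) == pytest.approx(
            expected, abs=1e-6
        )

    def test_geometric_closed_form_discounted_from_diagnosis(self):
        T = 300
        rho = np.exp(-0.02)
        S = rho ** np.arange(T + 1)
        curve = SurvivalCurve(np.arange(T + 1), S, np.full(T + 1, np.nan))
        series = obs_series(100.0 * np.ones(T + 1))
        r = rho * 1.03 ** (-1 / 12)
        expected = 100.0 * (1 - r ** (T + 1)) / (1 - r)
        total = lifetime_cost(series, curve, annual_discount=0.03, discount_all=True)
        assert total == pytest.approx(expected, abs=1e-6)

    def test_grid_mismatch_rejected(self):
        curve = ext_curve([1.0, 0.9], [0.5])
        series = CostSeries(np.arange(4), np.ones(4), np.full(4, OBSERVED, object))
        with pytest.raises(ValueError, match="grids"):
            lifetime_cost(series, curve)

    def test_discounting_only_extrapolated_months(self):
        curve = ext_curve([1.0, 0.9, 0.8], [0.7, 0.6])
        src = np.array([OBSERVED] * 3 + [EXTRAPOLATED] * 2, object)
        series = CostSeries(np.arange(5), 100.0 * np.ones(5), src)
        d = discount_factors(series, 0.03)
        np.testing.assert_allclose(d[:3], 1.0)
        np.testing.assert_allclose(d[3:], 1.03 ** (-np.arange(2) / 12))
        undisc = lifetime_cost(series, curve, annual_discount=0.0)
        disc = lifetime_cost(series, curve, annual_discount=0.03)
        assert disc < undisc

    def test_monotone_in_cost_and_survival(self):
        months = np.arange(40)
        S_lo = np.exp(-0.05 * months)
        S_hi = np.exp(-0.02 * months)
        c_lo = obs_series(50.0 * np.ones(40))
        c_hi = obs_series(80.0 * np.ones(40))
        lo_curve = SurvivalCurve(months, S_lo, np.full(40, np.nan))
        hi_curve = SurvivalCurve(months, S_hi, np.full(40, np.nan))
        assert lifetime_cost(c_hi, hi_curve) > lifetime_cost(c_lo, hi_curve)
        assert lifetime_cost(c_lo, hi_curve) > lifetime_cost(c_lo, lo_curve)


class TestCostPerLifeYear:
    def test_simple_quotient_and_zero(self):
        assert cost_per_life_year(50_000.0, 10.0) == pytest.approx(5000.0)
        assert cost_per_life_year(0.0, 4.2) == 0.0

    def test_inverse_identity(self):
        q = cost_per_life_year(123_456.78, 7.9)
        assert q * 7.9 == pytest.approx(123_456.78, abs=1e-9)

    def test_nonpositive_le_rejected(self):
        with pytest.raises(ValueError):
            cost_per_life_year(1.0, 0.0)


class TestConservation:
    def test_observed_mean_cost_times_survivors_equals_raw_spend(self, gompertz_table):
        cfg = ScenarioConfig(
            n_patients=200, excess_delta=0.02, followup_truncation_months=48, seed=23
        )
        cohort, _ = make_cohort(cfg, gompertz_table)
        nominal = make_costs(cohort, cfg, rng=24)
        cpi = make_cpi(cfg).set_index("year")["index"]
        usd = cpi_adjust(nominal, cpi, base_year=cfg.cpi_base_year, fx=cfg.fx_twd_per_usd)
        series = mean_monthly_cost(usd, cohort)
        f = cohort["followup_months"].to_numpy()
        survivors = np.array([(f >= m + 1).sum() for m in series.months])
        assert (series.c * survivors).sum() == pytest.approx(
            usd["cost"].sum(), rel=1e-9
        )
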