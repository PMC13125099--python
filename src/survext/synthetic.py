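"""Synthetic registry-style data with brute-force-computable ground truth.

Generates every input the pipeline consumes — a Gompertz life table, an index
cohort carrying a known excess hazard over the life-table hazard, monthly
cost histories with a terminal surge, a CPI index, and incidence scenarios —
together with the exact ("true") life expectancy, loss of LE, and CIR implied
by the generating hazards, computed by deterministic summation.  The truth
report is the recovery oracle against which the estimation pipeline is
validated.

Index lifetimes are simulated on a monthly grid: the referent monthly hazard
is h = -ln(1-q)/12 (constant within each age-year), the excess is either an
additive constant per month or a proportional hazard multiplier, and death in
month j (1-based) occurs with probability 1 - exp(-h_j).  Follow-up is
administratively truncated at a fixed horizon, mirroring registry follow-up
to a closing date.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import AGE_GROUPS
from .lifetables import LifeTable

__all__ = [
    "ScenarioConfig",
    "make_life_table",
    "make_cpi",
    "make_cohort",
    "make_costs",
    "make_incidence",
    "true_life_expectancy",
]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Baseline mortality is Gompertz: annual hazard A * exp(B * age), with a
    male multiplier on A.  The defaults emulate an adult registry cohort
    (men about twice as numerous as women, diagnosis ages centred in the
    sixties, 1998-2016 diagnoses followed at most ``followup_truncation_months``
    months) with realistic monthly spending and a terminal cost surge.
    """

    n_patients: int = 2000
    seed: int = 0

    # mortality model
    gompertz_a: float = 2.5e-5          # annual hazard at age 0
    gompertz_b: float = 0.10            # log-hazard slope per year of age
    male_hazard_multiplier: float = 1.6
    age_max: int = 110
    table_years: tuple = (1998, 2017)

    # cohort
    age_dx_mean: float = 62.0
    age_dx_sd: float = 11.0
    age_dx_range: tuple = (20, 79)
    male_fraction: float = 2.0 / 3.0
    dx_years: tuple = (1998, 2016)
    followup_truncation_months: int = 120

    # excess hazard of the diagnosed cohort over the referent hazard
    excess_model: str = "additive"      # "additive" | "proportional"
    excess_delta: float = 0.01          # added monthly hazard (additive model)
    hazard_ratio: float = 1.0           # multiplier (proportional model)

    # monthly costs (2017 USD before nominal inflation)
    cost_base_mean: float = 450.0       # mean of the lognormal baseline
    cost_base_sigma: float = 1.0        # lognormal sigma
    surge_multiplier: float = 5.0
    surge_months: int = 3

    # price level
    cpi_base_year: int = 2017
    cpi_annual_inflation: float = 0.01
    fx_twd_per_usd: float = 30.44

    # optional treatment arms: (name, excess_delta, cost_multiplier, fraction)
    arms: tuple = ()

    def __post_init__(self):
        if self.followup_truncation_months < 24:
            raise ValueError("followup_truncation_months must be >= 24")
        if self.excess_model not in ("additive", "proportional"):
            raise ValueError("excess_model must be 'additive' or 'proportional'")
        for name, val in (
            ("gompertz_a", self.gompertz_a),
            ("cost_base_mean", self.cost_base_mean),
            ("cost_base_sigma", self.cost_base_sigma),
            ("surge_multiplier", self.surge_multiplier),
            ("fx_twd_per_usd", self.fx_twd_per_usd),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gompertz_b < 0:
            raise ValueError("gompertz_b must be >= 0")
        if self.arms and abs(sum(a[3] for a in self.arms) - 1.0) > 1e-9:
            raise ValueError("arm fractions must sum to 1")


def make_life_table(config: ScenarioConfig) -> LifeTable:
    """Gompertz life table, per sex, closed at ``age_max``.

    q(age) = 1 - exp(-A_sex * exp(B * age)); identical across calendar years
    (no secular improvement).
    """
    ages = np.arange(config.age_max + 1)
    years = np.arange(config.table_years[0], config.table_years[1] + 1)
    q_rows = []
    for mult in (1.0, config.male_hazard_multiplier):  # F first, M second
        hazard = config.gompertz_a * mult * np.exp(config.gompertz_b * ages)
        q_rows.append(np.clip(-np.expm1(-hazard), 0.0, 1.0))
    q = np.stack(q_rows)[:, None, :].repeat(len(years), axis=1)
    return LifeTable(q=q, sexes=("F", "M"), years=years, age_max=config.age_max)


def make_cpi(config: ScenarioConfig, last_year: int | None = None) -> pd.DataFrame:
    """CPI index table (base year = 100) covering every year costs can touch."""
    if last_year is None:
        last_year = config.dx_years[1] + config.followup_truncation_months // 12 + 1
    years = np.arange(config.dx_years[0], last_year + 1)
    index = 100.0 * (1 + config.cpi_annual_inflation) ** (years - config.cpi_base_year)
    return pd.DataFrame({"year": years, "index": index})


def _monthly_death_probs(
    table: LifeTable,
    sex_idx: int,
    age0: int,
    year0: int,
    delta: float = 0.0,
    hazard_ratio: float = 1.0,
    n_months: int | None = None,
) -> np.ndarray:
    """P(die in month j | alive), j = 1..n_months, under referent + excess hazard."""
    if n_months is None:
        n_months = 12 * (table.age_max - min(age0, table.age_max) + 1)
    k = (np.arange(n_months)) // 12
    h = table.monthly_hazard(sex_idx, year0 + k, age0 + k)
    h = h * hazard_ratio + delta
    return -np.expm1(-h)


def true_life_expectancy(
    table: LifeTable,
    sex,
    age0: int,
    year0: int,
    delta: float = 0.0,
    hazard_ratio: float = 1.0,
) -> float:
    """Exact LE (years) under the discrete monthly scheme, by brute-force product.

    S(m) = prod_{j<=m} (1 - p_j) down to the closed-table horizon; LE is the
    trapezoidal area under S divided by 12, matching the estimator's rule.
    """
    p = _monthly_death_probs(
        table, int(table.sex_index(sex)), int(age0), int(year0), delta, hazard_ratio
    )
    S = np.concatenate([[1.0], np.cumprod(1.0 - p)])
    return float(np.trapezoid(S, dx=1.0)) / 12.0


def _truth_for(cohort: pd.DataFrame, table: LifeTable, config: ScenarioConfig) -> dict:
    """Mean true index/referent LE over a set of patients (cached per stratum key)."""
    deltas, ratios = _excess_by_patient(cohort, config)
    keys = list(
        zip(cohort["sex"], cohort["age_dx"].astype(int),
            (table.years[0] + cohort["dx_month"].astype(int) // 12), deltas, ratios)
    )
    cache: dict = {}
    le_idx = np.empty(len(keys))
    le_ref = np.empty(len(keys))
    for i, (sex, age, year, d, r) in enumerate(keys):
        if (sex, age, year, d, r) not in cache:
            cache[(sex, age, year, d, r)] = (
                true_life_expectancy(table, sex, age, year, d, r),
                true_life_expectancy(table, sex, age, year, 0.0, 1.0),
            )
        le_idx[i], le_ref[i] = cache[(sex, age, year, d, r)]
    return {
        "true_le_index_years": float(le_idx.mean()),
        "true_le_ref_years": float(le_ref.mean()),
        "true_loss_le_years": float(le_ref.mean() - le_idx.mean()),
        "n": int(len(keys)),
    }


def _excess_by_patient(cohort: pd.DataFrame, config: ScenarioConfig):
    """Per-patient (delta, hazard_ratio) arrays, honouring treatment arms."""
    n = len(cohort)
    if config.excess_model == "additive":
        deltas = np.full(n, config.excess_delta)
        ratios = np.ones(n)
    else:
        deltas = np.zeros(n)
        ratios = np.full(n, config.hazard_ratio)
    if config.arms and "arm" in cohort.columns:
        arm_delta = {a[0]: a[1] for a in config.arms}
        for name, d in arm_delta.items():
            mask = (cohort["arm"] == name).to_numpy()
            if config.excess_model == "additive":
                deltas[mask] = d
            else:
                ratios[mask] = d
    return deltas, ratios


def make_cohort(
    config: ScenarioConfig,
    table: LifeTable,
    rng: np.random.Generator | int | None = None,
):
    """Simulate an index cohort and report the exact LE truth alongside it.

    Returns ``(cohort, truth)`` where ``truth`` carries the brute-force true
    LE, referent LE, and loss of LE overall and per (sex, arm) stratum —
    the recovery oracle for the extrapolation pipeline.
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n_patients
    if n < 1:
        raise ValueError("n_patients must be >= 1")

    sex = np.where(rng.random(n) < config.male_fraction, "M", "F")
    lo, hi = config.age_dx_range
    age = np.clip(
        np.round(rng.normal(config.age_dx_mean, config.age_dx_sd, n)), lo, hi
    ).astype(int)
    dx_year = rng.integers(config.dx_years[0], config.dx_years[1] + 1, n)
    dx_month = (dx_year - table.years[0]) * 12 + rng.integers(0, 12, n)

    arm = np.full(n, "all", dtype=object)
    if config.arms:
        fractions = np.array([a[3] for a in config.arms])
        arm = np.asarray([a[0] for a in config.arms], dtype=object)[
            rng.choice(len(config.arms), size=n, p=fractions)
        ]

    cohort = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_dx": age,
            "dx_month": dx_month,
            "followup_months": 0,
            "died": 0,
            "arm": arm,
        }
    )
    deltas, ratios = _excess_by_patient(cohort, config)

    T = config.followup_truncation_months
    sex_idx = table.sex_index(sex)
    alive = np.ones(n, dtype=bool)
    death_month = np.zeros(n, dtype=int)
    for j in range(1, T + 1):
        k = (j - 1) // 12
        q = table.annual_q(sex_idx, dx_year + k, age + k)
        with np.errstate(divide="ignore"):
            h = -np.log1p(-q) / 12.0
        p = -np.expm1(-(h * ratios + deltas))
        dying = alive & (rng.random(n) < p)
        death_month[dying] = j
        alive &= ~dying
    cohort["followup_months"] = np.where(alive, T, death_month)
    cohort["died"] = (~alive).astype(int)

    truth = {"overall": _truth_for(cohort, table, config), "by_stratum": {}}
    strata = cohort.groupby(["sex", "arm"], observed=True)
    for key, grp in strata:
        if len(grp) == 0:
            truth.setdefault("warnings", []).append(f"empty stratum {key}")
            continue
        truth["by_stratum"]["/".join(map(str, key))] = _truth_for(grp, table, config)
    return cohort, truth


def make_costs(
    cohort: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Monthly nominal-TWD cost rows for every survived patient-month.

    Baseline costs are lognormal in 2017 USD (mean ``cost_base_mean``);
    decedents' final ``surge_months`` months are multiplied by
    ``surge_multiplier``; per-arm cost multipliers apply throughout.  The USD
    amounts are re-inflated to nominal TWD at each row's calendar-year price
    level, so that CPI adjustment recovers the 2017-USD scale.
    """
    rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    f = cohort["followup_months"].to_numpy(dtype=int)
    died = cohort["died"].to_numpy(dtype=int).astype(bool)
    total = int(f.sum())
    pm_patient = np.repeat(np.arange(len(f)), f)
    pm_month = np.arange(total) - np.repeat(np.cumsum(f) - f, f)

    mu = np.log(config.cost_base_mean) - config.cost_base_sigma**2 / 2.0
    usd = rng.lognormal(mu, config.cost_base_sigma, total)
    k = np.where(died[pm_patient], f[pm_patient] - 1 - pm_month, -1)
    usd[(k >= 0) & (k < config.surge_months)] *= config.surge_multiplier
    if config.arms and "arm" in cohort.columns:
        mult = cohort["arm"].map({a[0]: a[2] for a in config.arms}).to_numpy(dtype=float)
        usd *= mult[pm_patient]

    dx_month = cohort["dx_month"].to_numpy(dtype=int)
    # dx_month is counted from January of the first life-table year
    year = config.table_years[0] + (dx_month[pm_patient] + pm_month) // 12
    cpi = make_cpi(config).set_index("year")["index"]
    nominal = usd * config.fx_twd_per_usd * (cpi[year].to_numpy() / cpi[config.cpi_base_year])
    return pd.DataFrame(
        {
            "id": cohort["id"].to_numpy()[pm_patient],
            "month": pm_month,
            "cost": nominal,
            "year": year,
        }
    )


DEFAULT_TARGET_RATES = {
    # per person-year, per age group; men roughly twice women
    "M": (3e-5, 1.2e-4, 2.5e-4, 4.0e-4),
    "F": (1.5e-5, 6e-5, 1.2e-4, 2.0e-4),
}


def make_incidence(
    config: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
    target_rates: dict | None = None,
    periods: tuple = ((1999, 2001), (2002, 2004), (2005, 2007), (2008, 2010),
                      (2011, 2013), (2014, 2016)),
    person_years_per_group: float = 2.0e6,
    trend_multiplier: float = 2.0,
):
    """Poisson incidence scenario with known true CIR per sex and period.

    Age-specific rates grow linearly across periods from the target rates to
    ``trend_multiplier`` times them; case counts are Poisson around
    rate x person-years.  Returns ``(table, truth)`` where truth maps
    (sex, period) to the exact CIR of the generating rates.
    """
    rng = np.random.default_rng(config.seed + 2 if rng is None else rng)
    target_rates = target_rates or DEFAULT_TARGET_RATES
    rows, truth = [], {}
    n_periods = len(periods)
    from .incidence import cumulative_incidence  # local to avoid cycle at import

    for p_i, (start, end) in enumerate(periods):
        scale = 1.0 + (trend_multiplier - 1.0) * (p_i / max(n_periods - 1, 1))
        n_years = end - start + 1
        for sex, base in target_rates.items():
            rates = np.asarray(base) * scale
            for g_i, group in enumerate(AGE_GROUPS):
                py = person_years_per_group * n_years
                rows.append(
                    {
                        "sex": sex,
                        "age_group": group,
                        "period_start": start,
                        "period_end": end,
                        "cases": int(rng.poisson(rates[g_i] * py)),
                        "person_years": py,
                    }
                )
            truth[(sex, f"{start}-{end}")] = cumulative_incidence(rates)
    return pd.DataFrame(rows), truth


def scenario_to_dict(config: ScenarioConfig) -> dict:
    return dataclasses.asdict(config)
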