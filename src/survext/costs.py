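"""Mean monthly cost function, terminal-cost weighting, and lifetime cost.

Monthly healthcare spending is summed over patients and divided by the number
of surviving cases each month.  For extrapolated months the mean cost is a
survival-hazard-weighted average of terminal costs (the elevated spending in
the months immediately before death, located by a change-point scan) and the
stable background cost.  Lifetime cost is the sum of mean cost x survival,
with extrapolated months discounted at an annual rate (default 3%).

Cost months follow the package-wide grid convention: a patient with
``followup_months = f`` is a surviving case during months 0..f-1; the death
month of a decedent has index f-1.  Cost rows must therefore satisfy
``month < followup_months``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import EXTRAPOLATED, OBSERVED, SurvivalCurve, validate_cohort

REQUIRED_COST_COLUMNS = ("id", "month", "cost")


@dataclass
class CostSeries:
    """Mean cost per surviving patient-month (2017 USD) on the monthly grid."""

    months: np.ndarray
    c: np.ndarray
    source: np.ndarray

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        self.c = np.asarray(self.c, dtype=float)
        self.source = np.asarray(self.source, dtype=object)
        if np.any(self.c < 0):
            raise ValueError("mean costs must be >= 0")
        if len(self.months) and (self.months[0] != 0 or np.any(np.diff(self.months) != 1)):
            raise ValueError("months must be the consecutive grid 0,1,2,...")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": self.months, "c": self.c, "source": self.source})


@dataclass
class TerminalProfile:
    """End-of-life cost profile from a change-point scan over decedent months.

    ``c_term[k]`` is the mean cost k months before death (k = 0 is the death
    month) for k < L; ``c_stable`` is the mean cost of all patient-months
    outside any terminal window.
    """

    L: int
    c_term: np.ndarray
    c_stable: float

    def __post_init__(self):
        self.c_term = np.asarray(self.c_term, dtype=float)
        if self.L < 1 or len(self.c_term) != self.L:
            raise ValueError("c_term must hold L >= 1 values")
        if np.any(self.c_term < 0) or self.c_stable < 0:
            raise ValueError("costs must be >= 0")


def validate_costs(costs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COST_COLUMNS if c not in costs.columns]
    if missing:
        raise ValueError(f"cost table is missing required columns: {missing}")
    if (np.asarray(costs["cost"], dtype=float) < 0).any():
        raise ValueError("costs must be >= 0")
    if (np.asarray(costs["month"], dtype=int) < 0).any():
        raise ValueError("cost months must be >= 0")
    return costs


def load_costs(path) -> pd.DataFrame:
    """Read a cost CSV with columns id, month, cost[, year]."""
    return validate_costs(pd.read_csv(path, float_precision="round_trip"))


def load_cpi(path) -> pd.Series:
    """Read a CPI CSV (columns year, index) into a year-indexed series."""
    frame = pd.read_csv(path)
    for col in ("year", "index"):
        if col not in frame.columns:
            raise ValueError(f"CPI table is missing column {col!r}")
    return frame.set_index("year")["index"]


def cpi_adjust(
    raw: pd.DataFrame,
    cpi,
    base_year: int = 2017,
    fx: float = 30.44,
) -> pd.DataFrame:
    """Deflate nominal costs to base-year prices and convert to USD.

    cost_adj = cost * (cpi[base_year] / cpi[year]) / fx.  Requires a ``year``
    column on the cost table and CPI coverage of every year touched.
    """
    validate_costs(raw)
    if "year" not in raw.columns:
        raise ValueError("cpi_adjust requires a 'year' column on the cost table")
    if fx <= 0:
        raise ValueError("fx must be > 0")
    cpi = pd.Series(cpi)
    years = raw["year"].unique()
    missing = [int(y) for y in years if y not in cpi.index]
    if base_year not in cpi.index:
        raise ValueError(f"CPI table does not cover the base year {base_year}")
    if missing:
        raise ValueError(f"CPI table does not cover years {sorted(missing)}")
    factor = (cpi[base_year] / cpi[raw["year"]].to_numpy()) / fx
    out = raw.copy()
    out["cost"] = raw["cost"].to_numpy(dtype=float) * factor
    return out


def _survivors_by_month(cohort: pd.DataFrame) -> np.ndarray:
    """Number of surviving cases in each month m = 0..max(f)-1 (#{f >= m+1})."""
    f = np.asarray(cohort["followup_months"], dtype=int)
    T = int(f.max())
    counts = np.bincount(f, minlength=T + 1)
    alive = len(f) - np.cumsum(counts)  # index m: #{f > m} = #{f >= m+1}
    return alive[:T]


def mean_monthly_cost(costs: pd.DataFrame, cohort: pd.DataFrame) -> CostSeries:
    """Observed mean cost per surviving case each month since diagnosis.

    Patients alive in a month with no claim contribute 0 to the numerator and
    1 to the denominator.  Cost rows that do not join to a cohort patient, or
    that fall at/after the patient's exit month, raise.
    """
    validate_costs(costs)
    validate_cohort(cohort)
    f = pd.Series(
        np.asarray(cohort["followup_months"], dtype=int),
        index=cohort["id"].to_numpy(),
    )
    ids = costs["id"].to_numpy()
    unknown = ~pd.Index(ids).isin(f.index)
    if unknown.any():
        raise ValueError(
            f"orphan cost rows: ids {sorted(set(ids[unknown]))[:5]} not in cohort"
        )
    month = costs["month"].to_numpy(dtype=int)
    if (month >= f[ids].to_numpy()).any():
        raise ValueError("cost rows recorded at/after the patient's exit month")
    alive = _survivors_by_month(cohort)
    T = len(alive)
    total = np.bincount(month, weights=costs["cost"].to_numpy(dtype=float), minlength=T)
    c = np.divide(total[:T], alive, out=np.zeros(T), where=alive > 0)
    return CostSeries(
        months=np.arange(T), c=c, source=np.full(T, OBSERVED, dtype=object)
    )


def _patient_month_costs(costs: pd.DataFrame, cohort: pd.DataFrame):
    """Zero-filled per-patient-month cost array plus months-before-death index.

    Returns (cost, k) where k[j] = months before death for decedent months
    (k = 0 is the death month) and -1 for months of censored patients.
    """
    f = np.asarray(cohort["followup_months"], dtype=int)
    died = np.asarray(cohort["died"], dtype=int).astype(bool)
    starts = np.cumsum(f) - f
    total = int(f.sum())
    pm_patient = np.repeat(np.arange(len(f)), f)
    pm_month = np.arange(total) - np.repeat(starts, f)
    cost = np.zeros(total)
    code = pd.Series(np.arange(len(f)), index=cohort["id"].to_numpy())
    idx = starts[code[costs["id"].to_numpy()].to_numpy()] + costs["month"].to_numpy(dtype=int)
    np.add.at(cost, idx, costs["cost"].to_numpy(dtype=float))
    k = np.where(
        died[pm_patient], f[pm_patient] - 1 - pm_month, -1
    )
    return cost, k


def terminal_profile(
    costs: pd.DataFrame,
    cohort: pd.DataFrame,
    max_L: int = 12,
) -> TerminalProfile:
    """Locate the month at which costs begin to rise before death.

    Aligns decedents' patient-months backwards from death and scans terminal
    window lengths L = 1..max_L for the single change point that maximizes the
    absolute difference between the terminal and stable mean costs (smallest L
    wins ties).
    """
    validate_costs(costs)
    validate_cohort(cohort)
    died = np.asarray(cohort["died"], dtype=int).astype(bool)
    if not died.any():
        raise ValueError("terminal_profile requires at least one decedent")
    cost, k = _patient_month_costs(costs, cohort)
    k_max = int(k.max())
    if k_max < 0:  # pragma: no cover - decedents always have a death month
        raise ValueError("no decedent patient-months found")
    dec = k >= 0
    sum_by_k = np.bincount(k[dec], weights=cost[dec], minlength=k_max + 1)
    cnt_by_k = np.bincount(k[dec], minlength=k_max + 1)
    total_sum, total_cnt = cost.sum(), len(cost)

    best = None
    for L in range(1, min(max_L, k_max + 1) + 1):
        term_sum, term_cnt = sum_by_k[:L].sum(), cnt_by_k[:L].sum()
        stab_cnt = total_cnt - term_cnt
        if term_cnt == 0 or stab_cnt == 0:
            continue
        diff = abs(term_sum / term_cnt - (total_sum - term_sum) / stab_cnt)
        if best is None or diff > best[0] + 1e-12:
            best = (diff, L)
    if best is None:
        raise ValueError("no admissible terminal window length")
    L = best[1]
    with np.errstate(invalid="ignore"):
        c_term = np.divide(
            sum_by_k[:L], cnt_by_k[:L], out=np.zeros(L), where=cnt_by_k[:L] > 0
        )
    term_cnt = cnt_by_k[:L].sum()
    stab_sum = total_sum - sum_by_k[:L].sum()
    c_stable = stab_sum / (total_cnt - term_cnt)
    return TerminalProfile(L=L, c_term=c_term, c_stable=float(c_stable))


def extrapolate_costs(
    observed: CostSeries,
    profile: TerminalProfile,
    curve: SurvivalCurve,
) -> CostSeries:
    """Extend the mean cost function over the extrapolated survival months.

    For each extrapolated month t, p_k(t) = P(a patient alive at t dies in
    month t+k) is read off the completed survival curve for k = 0..L-1, and
    the mean cost is the weighted average
    c(t) = sum_k p_k(t) c_term[k] + (1 - sum_k p_k(t)) c_stable.
    The series is truncated where the curve is no longer strictly positive.
    """
    T0 = int(observed.months[-1]) + 1 if len(observed.months) else 0
    M = curve.last_month
    if M <= T0 - 1:
        raise ValueError("survival curve does not extend beyond the observed costs")
    S = np.concatenate([curve.S, np.zeros(profile.L + 1)])
    months, chat = [], []
    for t in range(T0, M + 1):
        if S[t] <= 0:
            break
        p = (S[t: t + profile.L] - S[t + 1: t + profile.L + 1]) / S[t]
        w_term = float(p @ profile.c_term)
        months.append(t)
        chat.append(w_term + (1.0 - float(p.sum())) * profile.c_stable)
    return CostSeries(
        months=np.concatenate([observed.months, np.asarray(months, dtype=int)]),
        c=np.concatenate([observed.c, np.asarray(chat)]),
        source=np.concatenate(
            [observed.source, np.full(len(months), EXTRAPOLATED, dtype=object)]
        ),
    )


def discount_factors(
    series: CostSeries,
    annual_discount: float,
    discount_from: int | None = None,
    discount_all: bool = False,
) -> np.ndarray:
    """Per-month discount factors: 1 over observed months, (1+r)^(-(t-t0)/12) after.

    ``discount_from`` defaults to the first extrapolated month of the series;
    with ``discount_all`` every month is discounted from month 0 (anchor at
    diagnosis).
    """
    if annual_discount < 0:
        raise ValueError("annual_discount must be >= 0")
    t = series.months.astype(float)
    if discount_all:
        return (1 + annual_discount) ** (-t / 12.0)
    if discount_from is None:
        ext = series.months[series.source == EXTRAPOLATED]
        if len(ext) == 0:
            return np.ones_like(t)
        discount_from = int(ext[0])
    d = np.ones_like(t)
    late = series.months >= discount_from
    d[late] = (1 + annual_discount) ** (-(t[late] - discount_from) / 12.0)
    return d


def lifetime_cost(
    series: CostSeries,
    curve: SurvivalCurve,
    annual_discount: float = 0.03,
    discount_from: int | None = None,
    discount_all: bool = False,
) -> float:
    """Discounted lifetime cost: sum_t c(t) * S(t) * d(t) in 2017 USD.

    The cost series and survival curve must share the monthly grid (the
    series may stop earlier, e.g. where survival hits 0).
    """
    n = len(series.months)
    if n > len(curve.months) or np.any(series.months != curve.months[:n]):
        raise ValueError("cost series and survival curve grids do not match")
    d = discount_factors(series, annual_discount, discount_from, discount_all)
    return float(np.sum(series.c * curve.S[:n] * d))


def discounted_life_years(
    curve: SurvivalCurve,
    annual_discount: float = 0.03,
    discount_from: int | None = None,
) -> float:
    """Area under S(t) * d(t) in years, discounting extrapolated months."""
    ext = curve.months[curve.source == EXTRAPOLATED]
    if discount_from is None:
        discount_from = int(ext[0]) if len(ext) else curve.last_month + 1
    t = curve.months.astype(float)
    d = np.ones_like(t)
    late = curve.months >= discount_from
    d[late] = (1 + annual_discount) ** (-(t[late] - discount_from) / 12.0)
    return float(np.trapezoid(curve.S * d, dx=1.0)) / 12.0


def cost_per_life_year(total_cost: float, le_years: float) -> float:
    """Lifetime cost divided by life expectancy (USD per life-year)."""
    if le_years <= 0:
        raise ValueError("life expectancy must be > 0")
    return total_cost / le_years
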