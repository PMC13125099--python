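"""Kaplan-Meier estimation on a monthly grid and restricted-mean life expectancy.

All survival machinery in this package works on a common monthly grid:
month index ``m`` denotes the interval [m, m+1) after diagnosis, S(m) is the
probability of being alive at the *start* of month m, and an event recorded
at time ``t`` (deaths before censorings within the same month) drops the
curve at grid point ``t``.  A patient record with ``followup_months = f`` and
``died = 1`` therefore died during month index f-1 and contributes a death at
time f; censored patients were observed alive through month f-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OBSERVED = "observed"
EXTRAPOLATED = "extrapolated"

#: Columns every cohort table must carry; ``arm`` is optional.
REQUIRED_COHORT_COLUMNS = ("id", "sex", "age_dx", "dx_month", "followup_months", "died")


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Raises
    ------
    ValueError
        On missing columns, empty table, duplicate ids, negative follow-up,
        or an event indicator outside {0, 1}.
    """
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    if len(cohort) == 0:
        raise ValueError("cohort table is empty")
    if cohort["id"].duplicated().any():
        raise ValueError("cohort table has duplicate patient ids")
    f = np.asarray(cohort["followup_months"])
    if (f < 0).any():
        raise ValueError("followup_months must be >= 0")
    if not np.isin(np.asarray(cohort["died"]), (0, 1)).all():
        raise ValueError("died must be 0 or 1")
    return cohort


def load_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV (columns id,sex,age_dx,dx_month,followup_months,died[,arm])."""
    return validate_cohort(pd.read_csv(path, float_precision="round_trip"))


@dataclass
class SurvivalCurve:
    """Monthly survival curve: S, at-risk counts, and an observed/extrapolated flag.

    ``months`` is the consecutive grid 0..M.  ``n_risk[m]`` is the number of
    subjects at risk entering month m (NaN over extrapolated months).
    """

    months: np.ndarray
    S: np.ndarray
    n_risk: np.ndarray
    source: np.ndarray = field(default=None)

    def __post_init__(self):
        self.months = np.asarray(self.months, dtype=int)
        self.S = np.asarray(self.S, dtype=float)
        self.n_risk = np.asarray(self.n_risk, dtype=float)
        if self.source is None:
            self.source = np.full(self.months.shape, OBSERVED, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        if not (len(self.months) == len(self.S) == len(self.n_risk) == len(self.source)):
            raise ValueError("months, S, n_risk, source must have equal length")
        if len(self.months) == 0:
            raise ValueError("empty survival curve")
        if self.months[0] != 0 or np.any(np.diff(self.months) != 1):
            raise ValueError("months must be the consecutive grid 0,1,2,...")
        if abs(self.S[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must equal 1")
        if np.any(self.S < -1e-12) or np.any(self.S > 1 + 1e-12):
            raise ValueError("S must lie in [0, 1]")
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("S must be non-increasing")

    @property
    def last_month(self) -> int:
        return int(self.months[-1])

    @property
    def last_observed_month(self) -> int:
        obs = self.months[self.source == OBSERVED]
        if len(obs) == 0:
            raise ValueError("curve has no observed months")
        return int(obs[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months, "S": self.S, "n_risk": self.n_risk, "source": self.source}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SurvivalCurve":
        return cls(
            months=frame["month"].to_numpy(),
            S=frame["S"].to_numpy(),
            n_risk=frame["n_risk"].to_numpy(),
            source=frame["source"].to_numpy(),
        )


def curve_from_event_times(times: np.ndarray, n: int) -> SurvivalCurve:
    """Empirical survivor curve for ``n`` subjects all followed to death.

    ``times`` are integer event times >= 1 on the monthly grid (a subject
    surviving s whole months has event time s+1).  Equivalent to KM with no
    censoring.
    """
    times = np.asarray(times, dtype=int)
    if len(times) != n or n == 0:
        raise ValueError("times must hold one event per subject")
    if times.min() < 1:
        raise ValueError("event times must be >= 1")
    T = int(times.max())
    deaths = np.bincount(times, minlength=T + 1)
    # subjects with event time > m are alive at the start of month m
    alive_after = n - np.cumsum(deaths)          # index t: #{times > t}
    S = alive_after / n
    S = np.concatenate([[1.0], S[1:T + 1]])
    at_risk = n - np.concatenate([[0], np.cumsum(deaths)[:-1]])  # #{times >= t}
    n_risk = at_risk[: T + 1].astype(float)
    n_risk[0] = n
    return SurvivalCurve(months=np.arange(T + 1), S=S, n_risk=n_risk)


def km_estimate(cohort: pd.DataFrame) -> SurvivalCurve:
    """Product-limit survival estimate of a cohort on the monthly grid.

    Within a month, deaths are processed before censorings (both are in the
    risk set for that month's deaths; censored subjects then leave).  A death
    recorded with followup_months = 0 is treated as a death during the first
    month (event time 1) so that S(0) = 1 always holds.
    """
    validate_cohort(cohort)
    f = np.asarray(cohort["followup_months"], dtype=int)
    died = np.asarray(cohort["died"], dtype=int).astype(bool)
    death_times = np.maximum(f[died], 1)
    censor_times = f[~died]
    n = len(f)
    T = int(max(death_times.max() if len(death_times) else 0,
                censor_times.max() if len(censor_times) else 0, 1))
    d = np.bincount(death_times, minlength=T + 1)
    c = np.bincount(censor_times, minlength=T + 1)
    exits = d + c
    # at risk entering month t = everyone whose event/censor time is >= t
    n_risk = n - np.concatenate([[0], np.cumsum(exits)[:-1]])
    n_risk = n_risk[: T + 1].astype(float)
    n_risk[0] = n
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(n_risk[1:] > 0, 1.0 - d[1: T + 1] / n_risk[1:], 1.0)
    S = np.concatenate([[1.0], np.cumprod(factors)])
    return SurvivalCurve(months=np.arange(T + 1), S=S, n_risk=n_risk)


def greenwood_sum(curve: SurvivalCurve) -> np.ndarray:
    """Cumulative Greenwood sum per month: Var(log S(t)) ~ sum d/(n(n-d)).

    Death and at-risk counts are reconstructed from the curve's S steps and
    n_risk.  Months without usable at-risk information (NaN or 0) contribute
    nothing, so a curve with no n_risk data yields all zeros.
    """
    S, n = curve.S, curve.n_risk
    G = np.zeros(len(S))
    for t in range(1, len(S)):
        G[t] = G[t - 1]
        if S[t - 1] > 0 and np.isfinite(n[t]) and n[t] > 0:
            d = (1.0 - S[t] / S[t - 1]) * n[t]
            denom = n[t] * (n[t] - d)
            if denom > 0:
                G[t] += d / denom
    return G


def restricted_mean(curve: SurvivalCurve, horizon: int | None = None) -> float:
    """Area under the survival curve over [0, horizon] months, in years.

    Trapezoidal rule on the monthly grid, divided by 12.  ``horizon`` defaults
    to the last month of the curve and may not exceed it.
    """
    if horizon is None:
        horizon = curve.last_month
    if horizon > curve.last_month:
        raise ValueError(
            f"horizon {horizon} beyond curve end {curve.last_month}"
        )
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    return float(np.trapezoid(curve.S[: horizon + 1], dx=1.0)) / 12.0
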