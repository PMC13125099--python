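"""National life tables and Monte Carlo simulation of matched referents.

A life table holds annual death probabilities q(sex, calendar year, age).
Referents matched to index patients on age, sex, and calendar year are
simulated year by year from these probabilities; the month of death within
the death year is uniform (the standard uniform-distribution-of-deaths
assumption).  Lookups outside the covered years/ages clamp to the nearest
covered value, and q at the highest covered age is treated as 1 (closed
table), so every simulated lifetime terminates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import SurvivalCurve, curve_from_event_times, validate_cohort


@dataclass
class LifeTable:
    """Annual death probabilities on a full (sex, year, age) grid.

    ``q`` has shape (n_sexes, n_years, age_max + 1); ``q[..., age_max]`` is
    forced to 1 at construction (closed table).
    """

    q: np.ndarray
    sexes: tuple
    years: np.ndarray
    age_max: int

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.q.shape != (len(self.sexes), len(self.years), self.age_max + 1):
            raise ValueError("q array shape does not match sexes/years/age_max")
        if np.any(self.q < 0) or np.any(self.q > 1):
            raise ValueError("all q must lie in [0, 1]")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        self.q = self.q.copy()
        self.q[..., self.age_max] = 1.0  # closed table

    @property
    def n_entries(self) -> int:
        return self.q.size

    def sex_index(self, sex) -> np.ndarray:
        """Map sex labels to internal indices (vectorized)."""
        lookup = {s: i for i, s in enumerate(self.sexes)}
        arr = np.asarray(sex)
        if arr.ndim == 0:
            if arr.item() not in lookup:
                raise KeyError(f"sex {arr.item()!r} not in table (has {self.sexes})")
            return np.asarray(lookup[arr.item()])
        try:
            return np.array([lookup[s] for s in arr])
        except KeyError as e:
            raise KeyError(f"sex {e} not in table (has {self.sexes})") from None

    def annual_q(self, sex_idx, year, age) -> np.ndarray:
        """q with clamping: years and ages outside coverage use the nearest entry."""
        yi = np.clip(np.asarray(year, dtype=int) - self.years[0], 0, len(self.years) - 1)
        ai = np.clip(np.asarray(age, dtype=int), 0, self.age_max)
        return self.q[np.asarray(sex_idx, dtype=int), yi, ai]

    def monthly_hazard(self, sex_idx, year, age) -> np.ndarray:
        """Constant-within-year monthly hazard rate, -ln(1-q)/12 (inf where q=1)."""
        q = self.annual_q(sex_idx, year, age)
        with np.errstate(divide="ignore"):
            return -np.log1p(-q) / 12.0

    def to_frame(self) -> pd.DataFrame:
        sex_col, year_col, age_col = np.meshgrid(
            np.arange(len(self.sexes)), self.years, np.arange(self.age_max + 1),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "sex": np.asarray(self.sexes)[sex_col.ravel()],
                "year": year_col.ravel(),
                "age": age_col.ravel(),
                "q": self.q.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class Referent:
    """One simulated life-table referent matched to an index patient."""

    matched_to: object
    survival_months: int

    def __post_init__(self):
        if self.survival_months < 0:
            raise ValueError("survival_months must be >= 0")


def life_table_from_frame(frame: pd.DataFrame) -> LifeTable:
    required = ("sex", "year", "age", "q")
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"life table is missing required columns: {missing}")
    if frame.duplicated(subset=["sex", "year", "age"]).any():
        raise ValueError("life table has duplicate (sex, year, age) keys")
    q = frame["q"].to_numpy(dtype=float)
    if np.any(q < 0) or np.any(q > 1) or np.any(~np.isfinite(q)):
        raise ValueError("life table has q outside [0, 1]")
    sexes = tuple(sorted(frame["sex"].unique()))
    years = np.arange(frame["year"].min(), frame["year"].max() + 1)
    age_max = int(frame["age"].max())
    arr = np.full((len(sexes), len(years), age_max + 1), np.nan)
    si = frame["sex"].map({s: i for i, s in enumerate(sexes)}).to_numpy()
    yi = frame["year"].to_numpy(dtype=int) - years[0]
    ai = frame["age"].to_numpy(dtype=int)
    arr[si, yi, ai] = q
    if np.isnan(arr).any():
        raise ValueError("life table grid is incomplete (missing sex/year/age cells)")
    return LifeTable(q=arr, sexes=sexes, years=years, age_max=age_max)


def load_life_table(path) -> LifeTable:
    """Read a life-table CSV with columns sex, year, age, q."""
    return life_table_from_frame(pd.read_csv(path, float_precision="round_trip"))


def _simulate_death_months(
    table: LifeTable,
    sex_idx: np.ndarray,
    years0: np.ndarray,
    ages0: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Whole months survived for a batch of referents (annual scheme).

    Year of death is drawn sequentially from the clamped annual q; the month
    within the death year is uniform on {0..11}.
    """
    n = len(ages0)
    alive = np.ones(n, dtype=bool)
    death_year = np.zeros(n, dtype=int)
    # closed table guarantees death by the time age_max is reached
    max_steps = int(table.age_max - min(int(ages0.min()), table.age_max)) + 1
    for k in range(max_steps + 1):
        q = table.annual_q(sex_idx, years0 + k, ages0 + k)
        dying = alive & (rng.random(n) < q)
        death_year[dying] = k
        alive &= ~dying
        if not alive.any():
            break
    if alive.any():  # pragma: no cover - closed-table rule forbids this
        raise AssertionError("closed life table failed to terminate a lifetime")
    return 12 * death_year + rng.integers(0, 12, n)


def simulate_referent(
    age_at_index: float,
    sex,
    calendar_year: int,
    table: LifeTable,
    rng: np.random.Generator,
    matched_to=None,
) -> Referent:
    """Simulate one age-, sex-, and calendar-year-matched referent."""
    if age_at_index < 0:
        raise ValueError("age_at_index must be >= 0")
    months = _simulate_death_months(
        table,
        np.asarray([table.sex_index(sex)]),
        np.asarray([calendar_year], dtype=int),
        np.asarray([int(age_at_index)]),
        rng,
    )
    return Referent(matched_to=matched_to, survival_months=int(months[0]))


def referent_survival_curve(
    cohort: pd.DataFrame,
    table: LifeTable,
    n_per_patient: int = 100,
    rng: np.random.Generator | int | None = None,
) -> SurvivalCurve:
    """Pooled survival curve of simulated referents, one batch per patient.

    Each index patient contributes ``n_per_patient`` referents matched on age
    at diagnosis, sex, and diagnosis calendar year.  Referents are followed to
    death (no censoring), so the pooled Kaplan-Meier curve is the empirical
    survivor function and reaches 0.
    """
    validate_cohort(cohort)
    if n_per_patient < 1:
        raise ValueError("n_per_patient must be >= 1")
    rng = np.random.default_rng(rng)
    sex_idx = np.repeat(table.sex_index(cohort["sex"].to_numpy()), n_per_patient)
    ages0 = np.repeat(
        np.floor(cohort["age_dx"].to_numpy(dtype=float)).astype(int), n_per_patient
    )
    dx_month = cohort["dx_month"].to_numpy(dtype=int)
    years0 = np.repeat(table.years[0] + dx_month // 12, n_per_patient)
    months = _simulate_death_months(table, sex_idx, years0, ages0, rng)
    return curve_from_event_times(months + 1, len(months))
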