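"""Rolling restricted-cubic-spline extrapolation of the logit survival ratio.

The method extends a cohort's observed Kaplan-Meier curve to lifetime:

1. Build the pooled survival curve of age-, sex-, and calendar-year-matched
   life-table referents (see :mod:`survext.lifetables`).
2. Form the survival ratio W(t) = S_index(t) / S_ref(t) over the observed
   months, clip it into (eps, 1-eps), and take the logit.
3. Fit a restricted (natural) cubic spline of logit W on the month index over
   a sliding window equal in length to the observed follow-up, predict logit W
   one month ahead, convert back via S_index = expit(logit W) * S_ref, then
   drop the earliest window month and append the predicted one.  Refit and
   repeat until the index survival falls below a stop threshold (default 0.01)
   or a hard cap is reached.

Two numerical safeguards address the logit's singularity at W = 1, where
pure sampling noise maps to unbounded logit swings that the spline would
otherwise extrapolate as a trend: (a) W is capped at a constant noise floor
1 - max(epsilon_upper, z * SE(W_T)) with the ratio's standard error taken at
the end of follow-up (a ratio statistically indistinguishable from 1 is
treated as 1-within-noise), and (b) the spline is fitted by weighted least
squares with delta-method inverse-variance weights
w(t) = (1 - W)^2 / [G_index(t) + G_ref(t)], G the cumulative Greenwood sums,
which downweights both the noisy near-1 months and the steep, information
poor early months.

Life expectancy (LE) is the area under the completed survival curve; loss of
LE is the referent LE minus the index LE.  Standard errors come from a
nonparametric patient-level bootstrap with the referent curve held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .lifetables import LifeTable, referent_survival_curve
from .survival import (
    EXTRAPOLATED,
    OBSERVED,
    SurvivalCurve,
    greenwood_sum,
    km_estimate,
    restricted_mean,
)


class ExtrapolationError(RuntimeError):
    """Raised when the rolling extrapolation cannot proceed."""


@dataclass
class ExtrapolationConfig:
    """Tuning parameters of the rolling extrapolation.

    stop_threshold
        Extrapolation stops once index survival falls below this (default 0.01).
    n_knots
        Knots of the restricted cubic spline (default 6, at conventional
        percentiles of the window months).
    epsilon
        Lower clip bound for the survival ratio before the logit.
    epsilon_upper
        Minimum upper clip: W is capped at 1 - max(epsilon_upper,
        noise_floor_z * SE(W)) with SE evaluated at the end of follow-up.
        Ratios at or above 1 are pure small-sample noise, and capping them at
        their own sampling-noise floor keeps the logit series on the scale of
        its noise instead of injecting spikes the spline would extrapolate as
        a trend.
    noise_floor_z
        Multiple of SE(W_T) used for the cap above; 0 disables the adaptive
        part of the floor.
    variance_weighting
        Fit the spline by inverse-variance weighted least squares
        (delta-method weights from the Greenwood variances of both curves);
        falls back to unweighted when at-risk counts are unavailable.
    n_referents_per_patient
        Monte Carlo referents simulated per index patient.
    hard_cap_months
        Maximum number of extrapolated months; exceeding it sets converged=False.
    min_observed_months
        Minimum observed follow-up required before extrapolating.
    """

    stop_threshold: float = 0.01
    n_knots: int = 6
    epsilon: float = 1e-6
    epsilon_upper: float = 0.005
    noise_floor_z: float = 1.0
    variance_weighting: bool = True
    n_boot: int = 100
    n_referents_per_patient: int = 100
    hard_cap_months: int = 1200
    min_observed_months: int = 24
    seed: int | None = None


@dataclass
class RatioSeries:
    """Survival ratio W = S_index/S_ref on the shared monthly grid, with logit."""

    months: np.ndarray
    W: np.ndarray
    logitW: np.ndarray


@dataclass
class ExtrapolationResult:
    """Completed curve plus LE, loss of LE, and (optional) bootstrap SEMs, in years."""

    curve: SurvivalCurve
    LE_index: float
    LE_ref: float
    loss_LE: float
    converged: bool
    sem_LE: float = float("nan")
    sem_loss: float = float("nan")
    n_boot: int = 0
    n_boot_failed: int = 0

    def summary(self) -> dict:
        return {
            "LE_index_years": self.LE_index,
            "LE_ref_years": self.LE_ref,
            "loss_LE_years": self.loss_LE,
            "sem_LE_years": self.sem_LE,
            "sem_loss_years": self.sem_loss,
            "n_boot": self.n_boot,
            "converged": self.converged,
        }


def survival_ratio(
    index: SurvivalCurve,
    ref: SurvivalCurve,
    epsilon: float = 1e-6,
    epsilon_upper: float | None = None,
    drop_first_month: bool = True,
) -> RatioSeries:
    """Clipped survival ratio and its logit over the observed months.

    Month 0 (where both curves equal 1 by construction) is dropped by default.
    Noisy small-cohort ratios above 1 are clipped, not rejected; the upper
    clip (default = epsilon) may be set wider than the lower one so that
    near-1 ratios stay on the scale of their sampling noise.
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if epsilon_upper is None:
        epsilon_upper = epsilon
    if not 0 < epsilon_upper < 0.5:
        raise ValueError("epsilon_upper must lie in (0, 0.5)")
    T = index.last_observed_month
    if ref.last_month < T:
        raise ValueError("reference curve does not cover the observed window")
    start = 1 if drop_first_month else 0
    months = np.arange(start, T + 1)
    s_ref = ref.S[months]
    if np.any(s_ref <= 0):
        raise ExtrapolationError(
            "reference survival reached 0 inside the observed window; "
            "simulate more referents or extend the life table"
        )
    W = np.clip(index.S[months] / s_ref, epsilon, 1 - epsilon_upper)
    return RatioSeries(months=months, W=W, logitW=logit(W))


# Conventional percentile placements for restricted cubic spline knots.
_KNOT_PERCENTILES = {
    3: (10, 50, 90),
    4: (5, 35, 65, 95),
    5: (5, 27.5, 50, 72.5, 95),
    6: (5, 23, 41, 59, 77, 95),
    7: (2.5, 18.33, 34.17, 50, 65.83, 81.67, 97.5),
}


def default_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    pct = _KNOT_PERCENTILES.get(n_knots, tuple(np.linspace(5, 95, n_knots)))
    knots = np.percentile(np.asarray(x, dtype=float), pct)
    if len(np.unique(knots)) < n_knots:
        raise ValueError("degenerate design: knots are not distinct")
    return knots


def rcs_design(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix of the restricted cubic spline: [1, x, C_1..C_{k-2}].

    Truncated-power construction normalized by (t_k - t_1)^2; the resulting
    function space is cubic between the boundary knots and linear outside
    them, and contains all linear functions.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    t1, tk1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2
    cols = [np.ones_like(x), x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            np.clip(x - tj, 0, None) ** 3
            - np.clip(x - tk1, 0, None) ** 3 * (tk - tj) / (tk - tk1)
            + np.clip(x - tk, 0, None) ** 3 * (tk1 - tj) / (tk - tk1)
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclass
class RcsFit:
    """Least-squares restricted-cubic-spline fit over the month index."""

    knots: np.ndarray
    coef: np.ndarray

    def predict(self, x) -> np.ndarray:
        scalar = np.ndim(x) == 0
        out = rcs_design(np.atleast_1d(x), self.knots) @ self.coef
        return float(out[0]) if scalar else out


def fit_rcs(
    months: np.ndarray,
    y: np.ndarray,
    n_knots: int = 6,
    knots: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> RcsFit:
    """Fit y on a restricted cubic spline of the month index by least squares.

    ``weights`` (optional) turns the fit into weighted least squares; with no
    weights this is the plain normal-equations solution on the natural-spline
    basis.
    """
    months = np.asarray(months, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_knots < 3:
        raise ValueError("n_knots must be >= 3")
    if len(months) < n_knots + 2:
        raise ValueError(f"need at least {n_knots + 2} points for {n_knots} knots")
    if len(np.unique(months)) < 2:
        raise ValueError("degenerate design: all months identical")
    if knots is None:
        knots = default_knots(months, n_knots)
    X = rcs_design(months, knots)
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return RcsFit(knots=np.asarray(knots, dtype=float), coef=coef)


def fit_ratio_spline(series: RatioSeries, n_knots: int = 6) -> RcsFit:
    """Convenience wrapper: fit the spline to a RatioSeries."""
    return fit_rcs(series.months, series.logitW, n_knots=n_knots)


def rolling_extrapolate(
    index: SurvivalCurve,
    ref_curve_full: SurvivalCurve,
    config: ExtrapolationConfig | None = None,
) -> ExtrapolationResult:
    """Extend the index curve to lifetime by the rolling spline algorithm.

    The sliding window holds (month, logit W) pairs; its length equals the
    observed follow-up (minus the dropped first month).  Each step refits the
    spline, predicts logit W one month ahead, converts to survival against the
    referent curve, then rolls the window forward one month.  Stops when index
    survival falls below ``stop_threshold`` (converged) or after
    ``hard_cap_months`` extrapolated months (not converged).
    """
    cfg = config or ExtrapolationConfig()
    T_obs = index.last_observed_month
    if T_obs < cfg.min_observed_months:
        raise ValueError(
            f"observed follow-up ({T_obs} months) is below the minimum "
            f"({cfg.min_observed_months}) required for extrapolation"
        )
    # raw ratio over months 1..T_obs, then the constant noise-floor cap
    months = np.arange(1, T_obs + 1)
    s_ref_obs = ref_curve_full.S[months] if ref_curve_full.last_month >= T_obs else None
    if s_ref_obs is None:
        raise ValueError("reference curve does not cover the observed window")
    if np.any(s_ref_obs <= 0):
        raise ExtrapolationError(
            "reference survival reached 0 inside the observed window; "
            "simulate more referents or extend the life table"
        )
    w_raw = index.S[months] / s_ref_obs
    G = greenwood_sum(index)[months] + greenwood_sum(ref_curve_full)[months]
    se_wT = float(w_raw[-1] * np.sqrt(G[-1]))
    floor = 1.0 - max(cfg.epsilon_upper, cfg.noise_floor_z * se_wT)
    W = np.clip(w_raw, cfg.epsilon, floor)
    win_m = months.astype(float)
    win_y = logit(W)
    if cfg.variance_weighting and G[-1] > 0:
        win_w = (1.0 - W) ** 2 / np.maximum(G, 1e-12)
    else:
        win_w = np.ones_like(W)
    w_append = win_w[-1]
    lo, hi = logit(cfg.epsilon), logit(floor)

    ref_S = ref_curve_full.S
    ref_last = ref_curve_full.last_month
    s_cur = float(index.S[T_obs])
    ext_months: list[int] = []
    ext_S: list[float] = []
    converged = s_cur < cfg.stop_threshold  # possible if follow-up is near-complete
    month = T_obs
    while not converged and len(ext_months) < cfg.hard_cap_months:
        month += 1
        if month > ref_last or ref_S[month] <= 0:
            raise ExtrapolationError(
                f"reference survival exhausted at month {month} while index "
                f"survival is {s_cur:.4f} >= stop threshold "
                f"{cfg.stop_threshold}; extend the life table or simulate "
                "more referents"
            )
        fit = fit_rcs(win_m, win_y, n_knots=cfg.n_knots, weights=win_w)
        pred = float(np.clip(fit.predict(float(month)), lo, hi))
        s_next = min(float(expit(pred)) * float(ref_S[month]), s_cur)
        ext_months.append(month)
        ext_S.append(s_next)
        win_m = np.append(win_m[1:], float(month))
        win_y = np.append(win_y[1:], pred)
        win_w = np.append(win_w[1:], w_append)
        s_cur = s_next
        if s_cur < cfg.stop_threshold:
            converged = True

    n_obs = T_obs + 1
    months = np.concatenate([index.months[:n_obs], np.asarray(ext_months, dtype=int)])
    S = np.concatenate([index.S[:n_obs], np.asarray(ext_S, dtype=float)])
    n_risk = np.concatenate(
        [index.n_risk[:n_obs], np.full(len(ext_months), np.nan)]
    )
    source = np.concatenate(
        [np.full(n_obs, OBSERVED, dtype=object),
         np.full(len(ext_months), EXTRAPOLATED, dtype=object)]
    )
    curve = SurvivalCurve(months=months, S=S, n_risk=n_risk, source=source)
    le_index = restricted_mean(curve)
    le_ref = restricted_mean(ref_curve_full)
    return ExtrapolationResult(
        curve=curve,
        LE_index=le_index,
        LE_ref=le_ref,
        loss_LE=le_ref - le_index,
        converged=converged,
    )


def bootstrap_sem(
    cohort: pd.DataFrame,
    table: LifeTable,
    config: ExtrapolationConfig | None = None,
    rng: np.random.Generator | int | None = None,
    extra_metric=None,
) -> ExtrapolationResult:
    """Point estimate plus bootstrap SEMs of LE and loss of LE.

    Nonparametric bootstrap over patients; each replicate reruns KM estimation
    and the rolling extrapolation against the *fixed* referent curve of the
    full cohort.  Replicates that fail to converge are dropped and counted;
    more than 20% failures raises.  ``extra_metric(boot_cohort, result)`` may
    compute an additional per-replicate statistic (e.g. lifetime cost); its
    replicate values are returned on the result as ``extra_values``.
    """
    cfg = config or ExtrapolationConfig()
    if cfg.n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    ref_curve = referent_survival_curve(
        cohort, table, n_per_patient=cfg.n_referents_per_patient, rng=rng
    )
    point = rolling_extrapolate(km_estimate(cohort), ref_curve, cfg)
    if extra_metric is not None:
        point_extra = extra_metric(cohort.assign(orig_id=cohort["id"]), point)

    n = len(cohort)
    reps_le, reps_loss, reps_extra = [], [], []
    failed = 0
    for _ in range(cfg.n_boot):
        take = rng.integers(0, n, n)
        boot = cohort.iloc[take].reset_index(drop=True)
        # resampled patients get fresh ids; the original id is kept so that
        # per-replicate metrics (e.g. lifetime cost) can rejoin auxiliary rows
        boot = boot.assign(orig_id=boot["id"].to_numpy(), id=np.arange(n))
        try:
            res = rolling_extrapolate(km_estimate(boot), ref_curve, cfg)
        except (ExtrapolationError, ValueError):
            failed += 1
            continue
        reps_le.append(res.LE_index)
        reps_loss.append(res.loss_LE)
        if extra_metric is not None:
            reps_extra.append(extra_metric(boot, res))
    if failed > 0.2 * cfg.n_boot:
        raise ExtrapolationError(
            f"{failed}/{cfg.n_boot} bootstrap replicates failed to converge"
        )
    result = replace(
        point,
        sem_LE=float(np.std(reps_le, ddof=1)),
        sem_loss=float(np.std(reps_loss, ddof=1)),
        n_boot=cfg.n_boot - failed,
        n_boot_failed=failed,
    )
    if extra_metric is not None:
        result.extra_point = point_extra
        result.extra_values = np.asarray(reps_extra, dtype=float)
    return result
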