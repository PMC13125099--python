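"""Orchestration: stratified LE / loss-of-LE / lifetime-cost analysis and CIR trends.

`run_le_analysis` reproduces the registry analysis flow per stratum
(sex x age group, and/or treatment arm): Kaplan-Meier on the index cohort,
Monte Carlo referents from the life table, rolling spline extrapolation,
patient-level bootstrap SEMs, and — when cost data are supplied — the mean
monthly cost function, terminal-cost weighting, and discounted lifetime cost
with both cost-per-life-year variants.  Output is a summary table with one
row per stratum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .costs import (
    cost_per_life_year,
    cpi_adjust,
    discounted_life_years,
    extrapolate_costs,
    lifetime_cost,
    mean_monthly_cost,
    terminal_profile,
)
from .extrapolation import ExtrapolationConfig, ExtrapolationError, bootstrap_sem
from .incidence import cir_table
from .lifetables import LifeTable
from .survival import validate_cohort

logger = logging.getLogger("survext")

LE_TABLE_COLUMNS = [
    "stratum", "n", "deaths", "LE", "sem_LE", "loss_LE", "sem_loss",
    "lifetime_cost", "sem_cost", "cost_per_life_year",
    "cost_per_discounted_life_year", "converged",
]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    age_breaks: tuple = (50, 65, 80)      # <50, 50-64, 65-79
    stratify_by_sex: bool = True
    stratify_by_arm: bool = False
    min_stratum_size: int = 50
    annual_discount: float = 0.03
    cpi_base_year: int = 2017
    fx_twd_per_usd: float = 30.44
    max_terminal_months: int = 12
    extrapolation: ExtrapolationConfig = field(default_factory=ExtrapolationConfig)
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def assign_age_group(ages, breaks=(50, 65, 80)) -> np.ndarray:
    """Label ages by left-closed bins ending at each break: <50, 50-64, 65-79."""
    ages = np.asarray(ages)
    edges = list(breaks)
    labels = [f"<{edges[0]}"] + [
        f"{lo}-{hi - 1}" for lo, hi in zip(edges[:-1], edges[1:])
    ]
    idx = np.searchsorted(edges, ages, side="right")
    if np.any(idx >= len(edges)):
        raise ValueError("cohort has ages beyond the last age break")
    return np.asarray(labels, dtype=object)[idx]


def _strata(cohort: pd.DataFrame, config: RunConfig):
    keys = []
    frame = cohort.copy()
    if config.stratify_by_sex:
        frame["age_group"] = assign_age_group(frame["age_dx"], config.age_breaks)
        keys = ["sex", "age_group"]
    if config.stratify_by_arm:
        keys = keys + ["arm"] if keys else ["arm"]
    if not keys:
        yield "all", frame
        return
    for key, grp in frame.groupby(keys, observed=True, sort=True):
        name = "/".join(map(str, key if isinstance(key, tuple) else (key,)))
        yield name, grp


def run_le_analysis(
    cohort: pd.DataFrame,
    life_table: LifeTable,
    config: RunConfig | None = None,
    costs: pd.DataFrame | None = None,
    cpi=None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-stratum LE, loss of LE, lifetime cost, and cost per life-year.

    Strata smaller than ``min_stratum_size`` are skipped with a logged
    warning.  When ``costs`` is given it must be a nominal cost table with a
    ``year`` column (CPI-adjusted internally if ``cpi`` is supplied, else
    assumed to be in base-year USD already).
    """
    cfg = config or RunConfig()
    validate_cohort(cohort)
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if costs is not None and cpi is not None:
        costs = cpi_adjust(costs, cpi, base_year=cfg.cpi_base_year, fx=cfg.fx_twd_per_usd)

    rows = []
    for name, grp in _strata(cohort, cfg):
        if len(grp) < cfg.min_stratum_size:
            logger.warning(
                "stratum %s skipped: %d patients < minimum %d",
                name, len(grp), cfg.min_stratum_size,
            )
            continue
        grp = grp.reset_index(drop=True)
        stratum_costs = None
        if costs is not None:
            stratum_costs = costs[costs["id"].isin(grp["id"])]

        try:
            if stratum_costs is not None:
                extra = _make_cost_metric(stratum_costs, cfg)
            else:
                extra = None
            res = bootstrap_sem(
                grp, life_table, cfg.extrapolation, rng=rng, extra_metric=extra
            )
        except (ExtrapolationError, ValueError) as err:
            logger.warning("stratum %s failed: %s", name, err)
            continue

        row = {
            "stratum": name,
            "n": len(grp),
            "deaths": int(grp["died"].sum()),
            "LE": res.LE_index,
            "sem_LE": res.sem_LE,
            "loss_LE": res.loss_LE,
            "sem_loss": res.sem_loss,
            "lifetime_cost": np.nan,
            "sem_cost": np.nan,
            "cost_per_life_year": np.nan,
            "cost_per_discounted_life_year": np.nan,
            "converged": res.converged,
        }
        if stratum_costs is not None:
            row["lifetime_cost"] = res.extra_point
            row["sem_cost"] = float(np.std(res.extra_values, ddof=1))
            row["cost_per_life_year"] = cost_per_life_year(res.extra_point, res.LE_index)
            dly = discounted_life_years(res.curve, cfg.annual_discount)
            row["cost_per_discounted_life_year"] = cost_per_life_year(
                res.extra_point, dly
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=LE_TABLE_COLUMNS)


def _make_cost_metric(stratum_costs: pd.DataFrame, cfg: RunConfig):
    """Per-replicate lifetime-cost metric sharing the patient bootstrap.

    The bootstrap relabels resampled patients with fresh ids 0..n-1; cost
    rows are rebuilt for the resampled patients by joining on the original
    id kept in the replicate's row order.
    """
    by_id = dict(tuple(stratum_costs.groupby("id", sort=False)))
    empty = stratum_costs.iloc[0:0]

    def metric(boot_cohort: pd.DataFrame, result) -> float:
        pieces = []
        for new_id, old_id in zip(boot_cohort["id"], boot_cohort["orig_id"]):
            rows = by_id.get(old_id)
            if rows is None:
                continue
            pieces.append(rows.assign(id=new_id))
        boot_costs = pd.concat(pieces, ignore_index=True) if pieces else empty
        observed = mean_monthly_cost(boot_costs, boot_cohort)
        profile = terminal_profile(
            boot_costs, boot_cohort, max_L=cfg.max_terminal_months
        )
        full = extrapolate_costs(observed, profile, result.curve)
        return lifetime_cost(full, result.curve, annual_discount=cfg.annual_discount)

    return metric


def run_cir_analysis(incidence: pd.DataFrame, config: RunConfig | None = None) -> pd.DataFrame:
    """CIR trend table per sex and calendar period."""
    return cir_table(incidence)


def run_metadata(config: RunConfig) -> dict:
    """Provenance record: config hash, seed, and package version."""
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "survext_version": __version__,
    }
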