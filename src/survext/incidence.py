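"""Age- and sex-specific incidence rates and the cumulative incidence rate.

The cumulative incidence rate over ages 20-79,

    CIR_20-79 = 1 - exp(-sum_i IR_i * dt_i),

converts age-group-specific incidence rates IR_i (new cases per person-year,
pooled over 2-3 consecutive calendar years) into the probability of
developing the disease between ages 20 and 79.  The default age groups are
20-49, 50-59, 60-69, 70-79 with widths (30, 10, 10, 10) years.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_GROUPS = ("20-49", "50-59", "60-69", "70-79")
DEFAULT_WIDTHS = (30.0, 10.0, 10.0, 10.0)

REQUIRED_INCIDENCE_COLUMNS = (
    "sex", "age_group", "period_start", "period_end", "cases", "person_years"
)


def validate_incidence(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_INCIDENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"incidence table is missing required columns: {missing}")
    if (np.asarray(frame["cases"], dtype=float) < 0).any():
        raise ValueError("case counts must be >= 0")
    if (np.asarray(frame["person_years"], dtype=float) <= 0).any():
        raise ValueError("person_years must be > 0")
    unknown = set(frame["age_group"]) - set(AGE_GROUPS)
    if unknown:
        raise ValueError(f"unknown age groups {sorted(unknown)}; expected {AGE_GROUPS}")
    return frame


def load_incidence(path) -> pd.DataFrame:
    return validate_incidence(pd.read_csv(path, float_precision="round_trip"))


def age_specific_ir(cases, person_years):
    """Incidence rate per person-year: cases / person-years at risk."""
    cases = np.asarray(cases, dtype=float)
    person_years = np.asarray(person_years, dtype=float)
    if np.any(person_years <= 0):
        raise ValueError("person_years must be > 0")
    if np.any(cases < 0):
        raise ValueError("cases must be >= 0")
    out = cases / person_years
    return float(out) if out.ndim == 0 else out


def cumulative_incidence(rates, widths=DEFAULT_WIDTHS) -> float:
    """CIR = 1 - exp(-sum_i IR_i * dt_i), a probability in [0, 1)."""
    rates = np.asarray(rates, dtype=float)
    widths = np.asarray(widths, dtype=float)
    if rates.shape != widths.shape:
        raise ValueError("rates and widths must align")
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if np.any(widths <= 0):
        raise ValueError("widths must be > 0")
    return float(-np.expm1(-np.dot(rates, widths)))


def cir_table(
    frame: pd.DataFrame,
    widths=DEFAULT_WIDTHS,
    age_groups=AGE_GROUPS,
) -> pd.DataFrame:
    """Per sex x period CIR series (for trend plots over calendar time).

    Each (sex, period) cell must provide all age groups; a missing group
    raises an error naming the gap.
    """
    validate_incidence(frame)
    widths = dict(zip(age_groups, widths))
    rows = []
    for (sex, start, end), grp in frame.groupby(["sex", "period_start", "period_end"]):
        grp = grp.set_index("age_group")
        missing = [g for g in age_groups if g not in grp.index]
        if missing:
            raise ValueError(
                f"sex={sex} period={start}-{end} is missing age groups {missing}"
            )
        rates = [
            age_specific_ir(grp.loc[g, "cases"], grp.loc[g, "person_years"])
            for g in age_groups
        ]
        rows.append(
            {
                "sex": sex,
                "period": f"{start}-{end}",
                "CIR": cumulative_incidence(rates, [widths[g] for g in age_groups]),
            }
        )
    return pd.DataFrame(rows).sort_values(["sex", "period"]).reset_index(drop=True)
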