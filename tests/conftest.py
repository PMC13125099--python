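import numpy as np
import pandas as pd
import pytest

from survext import LifeTable, ScenarioConfig, make_life_table


@pytest.fixture(scope="session")
def gompertz_table() -> LifeTable:
    """Default Gompertz life table used across tests."""
    return make_life_table(ScenarioConfig())


@pytest.fixture()
def flat_table_factory():
    """LifeTable with constant annual q at every age (closed at age_max)."""

    def make(q: float, age_max: int = 110, years=(1998, 2017), sexes=("F", "M")):
        arr = np.full((len(sexes), years[1] - years[0] + 1, age_max + 1), q)
        return LifeTable(
            q=arr, sexes=sexes, years=np.arange(years[0], years[1] + 1), age_max=age_max
        )

    return make


def build_cohort(followups, died, sex="M", age=60, dx_month=84, arm=None):
    """Small cohort table from parallel followup/died lists."""
    n = len(followups)
    frame = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": [sex] * n if isinstance(sex, str) else sex,
            "age_dx": [age] * n if np.isscalar(age) else age,
            "dx_month": [dx_month] * n if np.isscalar(dx_month) else dx_month,
            "followup_months": followups,
            "died": died,
        }
    )
    if arm is not None:
        frame["arm"] = arm
    return frame
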