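import numpy as np
import pandas as pd
import pytest

from recalldecay import (
    ModelSpec,
    PersonRecord,
    PersonTimeTable,
    RecallDecayModel,
    SimConfig,
    build_person_time,
    generate_cohort,
)
from recalldecay.decay import DecayCurve

#: Fitted log-quadratic decay coefficients by socioeconomic tertile
#: (linear, quadratic), and the corresponding published derived values.
TERTILE_COEFFS = {
    "lower": (-0.527, 0.036),
    "middle": (-0.215, 0.003),
    "upper": (-0.200, -0.004),
}


def make_person(i=0, household="h0", injury_day=None, cause=None, **covs):
    defaults = dict(
        sex="female",
        age_group="16-44",
        education="none",
        location="urban",
        ses_tertile="middle",
    )
    defaults.update(covs)
    return PersonRecord(
        person_id=f"p{i}",
        household_id=household,
        injury_days_before_interview=injury_day,
        injury_cause=cause if injury_day is not None else None,
        **defaults,
    )


@pytest.fixture
def single_cell_table():
    """One cell: 2 person-years exposure, 2 events, one household."""
    df = pd.DataFrame(
        {
            "sex": ["female"],
            "age_group": ["16-44"],
            "education": ["none"],
            "location": ["urban"],
            "ses_tertile": ["middle"],
            "household_id": ["h0"],
            "month": [1],
            "person_years": [2.0],
            "events": [2],
        }
    )
    return PersonTimeTable(df)


@pytest.fixture
def toy_household_table():
    """3 households x 4 monthly cells with assorted counts, for quadrature checks."""
    rows = []
    counts = {
        ("h0", 1): (0.5, 2), ("h0", 2): (0.5, 0), ("h0", 3): (0.4, 1), ("h0", 4): (0.4, 0),
        ("h1", 1): (0.6, 1), ("h1", 2): (0.6, 3), ("h1", 3): (0.5, 0), ("h1", 4): (0.5, 1),
        ("h2", 1): (0.3, 0), ("h2", 2): (0.3, 0), ("h2", 3): (0.3, 2), ("h2", 4): (0.2, 0),
    }
    hh_covs = {
        "h0": ("female", "middle"),
        "h1": ("male", "lower"),
        "h2": ("female", "upper"),
    }
    for (hh, month), (py, ev) in counts.items():
        sex, ses = hh_covs[hh]
        rows.append(
            dict(
                sex=sex, age_group="16-44", education="none",
                location="urban", ses_tertile=ses,
                household_id=hh, month=month, person_years=py, events=ev,
            )
        )
    return PersonTimeTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def lower_decay_cohort():
    """Moderate single-stratum cohort thinned by the fast (lower-tertile) curve."""
    cfg = SimConfig(
        n_households=250,
        baseline_rate=0.323,
        decay=DecayCurve(TERTILE_COEFFS["lower"]),
        seed=42,
    )
    records = generate_cohort(cfg)
    return cfg, records, build_person_time(records)
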