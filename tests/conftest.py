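from __future__ import annotations

from datetime import datetime, timedelta

import pandas as pd
import pytest

from ewscompare.cohort import Admission

BASE = datetime(2016, 3, 1, 9, 0)


def make_obs_row(admission_id, observed_at, **over):
    row = {
        "admission_id": admission_id,
        "observed_at": observed_at,
        "heart_rate": 70.0,
        "systolic_bp": 120.0,
        "respiratory_rate": 16.0,
        "temperature": 37.0,
        "spo2": 98.0,
        "on_oxygen": 0,
        "avpu": "A",
        "gcs": float("nan"),
    }
    row.update(over)
    return row


def make_admission(admission_id, *, age=70, los_hours=72, status="alive", **over):
    kwargs = dict(
        admission_id=admission_id,
        hospital_id="JR",
        admitted_at=BASE,
        discharged_at=BASE + timedelta(hours=los_hours),
        age_years=age,
        discharge_status=status,
    )
    kwargs.update(over)
    return Admission(**kwargs)


@pytest.fixture
def normal_vitals():
    """Keyword arguments for a complete observation with all-zero bands."""
    return dict(
        heart_rate=70,
        systolic_bp=120,
        respiratory_rate=16,
        temperature=37.0,
        spo2=98,
        on_oxygen=False,
        consciousness="A",
    )


@pytest.fixture
def flowchart_fixture():
    """12 admissions engineered to hit every exclusion stage.

    2 under-age, 1 with no complete observation set, 3 same-day live
    discharges, 2 with no vitals in the final 24 h, 4 retained.
    Expected tally: (12, 2, 1, 3, 2, 4).
    """
    adms, obs = [], []

    def add_obs(aid, hours_after_admit, **over):
        obs.append(make_obs_row(aid, BASE + timedelta(hours=hours_after_admit), **over))

    # under-age (complete vitals, long stay)
    for aid in ("U1", "U2"):
        adms.append(make_admission(aid, age=15))
        add_obs(aid, 1)
        add_obs(aid, 60)
    # adult, only incomplete observations (missing temperature)
    adms.append(make_admission("I1"))
    add_obs("I1", 1, temperature=float("nan"))
    add_obs("I1", 60, temperature=float("nan"))
    # same-day live discharges (admitted 09:00, discharged 21:00 same day)
    for aid in ("S1", "S2", "S3"):
        adms.append(make_admission(aid, los_hours=12))
        add_obs(aid, 1)
        add_obs(aid, 10)
    # stayed 3 days, last observation 48 h before discharge
    for aid in ("E1", "E2"):
        adms.append(make_admission(aid, los_hours=72))
        add_obs(aid, 1)
        add_obs(aid, 20)
    # retained: complete vitals through to discharge
    for aid in ("K1", "K2", "K3", "K4"):
        adms.append(make_admission(aid, los_hours=72))
        add_obs(aid, 1)
        add_obs(aid, 60)

    return adms, pd.DataFrame(obs)
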