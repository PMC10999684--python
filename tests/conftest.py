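import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pdcshift import ScmParams, generate_cohort
from pdcshift.adherence import ObservationWindow, PrescriptionRecord


def brute_force_days_covered(records, window):
    """Independent day-by-day pill-stock simulation (test oracle).

    Walks every calendar day from the earliest dispense date to the window
    end, adding tablets on dispense days and consuming the daily regimen
    whenever stock suffices; counts covered days inside the window only.
    """
    adds = {}
    tpd = float(records[0].tablets_per_day)
    for r in records:
        if r.dispense_date <= window.end_date:
            adds[r.dispense_date] = adds.get(r.dispense_date, 0) + r.tablets
    if not adds:
        return 0
    day = min(min(adds), window.start_date)
    stock, covered = 0.0, 0
    while day <= window.end_date:
        stock += adds.get(day, 0)
        if stock >= tpd - 1e-9:
            stock -= tpd
            if day >= window.start_date:
                covered += 1
        day += dt.timedelta(days=1)
    return covered


def random_refill_history(rng, patient_id="p1"):
    """A randomized single-patient refill history plus a window."""
    start = dt.date(2019, 1, 1) + dt.timedelta(days=int(rng.integers(0, 200)))
    length = int(rng.integers(30, 500))
    window = ObservationWindow(start, start + dt.timedelta(days=length - 1))
    tpd = float(rng.choice([1.0, 2.0, 3.0]))
    n_rec = int(rng.integers(1, 12))
    records = [
        PrescriptionRecord(
            patient_id=patient_id,
            dispense_date=start + dt.timedelta(days=int(rng.integers(-60, length))),
            boxes=int(rng.integers(1, 4)),
            tablets_per_box=int(rng.choice([28, 30, 60])),
            tablets_per_day=tpd,
        )
        for _ in range(n_rec)
    ]
    return records, window


@pytest.fixture(scope="session")
def small_cohort():
    """A modest fully-observed synthetic cohort shared across tests."""
    return generate_cohort(ScmParams(n=1500, seed=2024, miss_rates={}))


@pytest.fixture(scope="session")
def default_params():
    return ScmParams(n=1500, seed=2024)
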