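from datetime import date, timedelta

import numpy as np
import pytest

from stscan.io import CaseRecord, Dataset, LocationTable, StudyPeriod


def make_locations(n=4, seed=0, pop=None):
    rng = np.random.default_rng(seed)
    ids = [f"L{i:02d}" for i in range(n)]
    lats = rng.uniform(51.5, 52.0, n)
    lons = rng.uniform(-9.0, -8.5, n)
    pops = pop if pop is not None else rng.integers(50, 500, n)
    return LocationTable(ids, lats, lons, pops)


def make_dataset(counts, locations, start=date(2015, 1, 1)):
    """Build a dataset from an explicit (n_locations, n_days) count array."""
    counts = np.asarray(counts)
    period = StudyPeriod(start, start + timedelta(days=counts.shape[1] - 1))
    cases = []
    k = 0
    for li in range(counts.shape[0]):
        for ui in range(counts.shape[1]):
            for _ in range(int(counts[li, ui])):
                k += 1
                cases.append(
                    CaseRecord(
                        case_id=f"c{k}",
                        location_id=locations.ids[li],
                        event_date=period.unit_start(ui),
                    )
                )
    return Dataset(cases=cases, locations=locations, period=period)


@pytest.fixture
def two_location_table():
    return LocationTable(["A", "B"], [51.8, 51.9], [-8.5, -8.6], [100, 300])
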