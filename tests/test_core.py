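import math
from datetime import date, timedelta

import numpy as np
import pytest

from stscan.core import (
    ClusterResult,
    ScanParams,
    build_zones,
    enumerate_cylinders,
    expected_counts,
    great_circle_km,
    poisson_llr,
    relative_risk,
    scan,
)
from stscan.io import DataError, LocationTable, StudyPeriod

from conftest import make_dataset, make_locations


class TestDistance:
    def test_identity_and_symmetry(self):
        assert great_circle_km(51.9, -8.5, 51.9, -8.5) == 0.0
        d1 = great_circle_km(51.8985, -8.4756, 53.3498, -6.2603)
        d2 = great_circle_km(53.3498, -6.2603, 51.8985, -8.4756)
        assert d1 == d2

    def test_cork_to_dublin(self):
        # haversine closed form on the 6371 km sphere
        assert great_circle_km(51.8985, -8.4756, 53.3498, -6.2603) == pytest.approx(220.0, abs=0.5)

    def test_range_validation(self):
        with pytest.raises(DataError):
            great_circle_km(91.0, 0.0, 0.0, 0.0)


class TestExpectedCounts:
    def test_cell_value_and_conservation(self, two_location_table):
        period = StudyPeriod(date(2015, 1, 1), date(2015, 1, 10))
        surface = expected_counts(two_location_table, period, N=8)
        # N * (100/400) * (1/10)
        assert surface.mu[0, 3] == pytest.approx(0.2)
        assert surface.mu.sum() == pytest.approx(8.0, abs=1e-12)

    def test_zero_population_location_gets_zero_mu(self):
        table = LocationTable(["A", "B"], [51.8, 51.9], [-8.5, -8.6], [0, 300])
        surface = expected_counts(table, StudyPeriod(date(2015, 1, 1), date(2015, 1, 5)), N=10)
        assert np.all(surface.mu[0] == 0)
        assert surface.mu.sum() == pytest.approx(10.0)


class TestLikelihoodRatio:
    def test_null_boundary_is_zero(self):
        assert poisson_llr(5, 5.0, 100) == 0.0
        assert poisson_llr(3, 4.0, 100) == 0.0  # deficit: one-sided scan

    def test_all_cases_inside_is_finite(self):
        # 0*log(0) convention: only the inside term remains
        assert poisson_llr(10, 2.0, 10) == pytest.approx(10 * math.log(5), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DataError):
            poisson_llr(3, 0.0, 10)
        with pytest.raises(DataError):
            poisson_llr(11, 1.0, 10)

    def test_relative_risk_identities(self):
        assert relative_risk(5, 5.0, 100) == pytest.approx(1.0)
        assert relative_risk(10, 2.0, 10) == math.inf
        assert relative_risk(3, 0.103, 388) == pytest.approx(
            (3 / 0.103) / (385 / (388 - 0.103)), rel=1e-12
        )


class TestCylinderEnumeration:
    def test_single_location_interval_counts(self):
        table = LocationTable(["A"], [51.8], [-8.5], [100])
        period = StudyPeriod(date(2015, 1, 1), date(2015, 1, 3))
        retro = enumerate_cylinders(table, period, ScanParams(mode="retrospective"))
        assert len(retro) == 6  # 3 + 2 + 1 intervals
        prosp = enumerate_cylinders(table, period, ScanParams(mode="prospective"))
        assert len(prosp) == 3
        assert all(c.t_end == date(2015, 1, 3) for c in prosp)

    def test_population_cap_excludes_pairs(self):
        table = LocationTable(["A", "B"], [51.8, 51.9], [-8.5, -8.6], [200, 200])
        zones = build_zones(table, max_pop_fraction=0.5)
        assert all(len(z.member_indices) == 1 for z in zones)

    def test_t_max_limits_window_length(self):
        table = LocationTable(["A"], [51.8], [-8.5], [100])
        period = StudyPeriod(date(2015, 1, 1), date(2015, 1, 20))
        cylinders = enumerate_cylinders(table, period, ScanParams(t_max_days=5))
        assert max((c.t_end - c.t_start).days for c in cylinders) == 4


# ---------------------------------------------------------------------------
# independent brute-force oracle


def brute_force_best(dataset, params):
    """Re-count cases cylinder by cylinder; independent of the scan path."""
    N = dataset.N
    total_pop = dataset.locations.total_population
    total_days = dataset.period.n_days
    best = None
    for cyl in enumerate_cylinders(dataset.locations, dataset.period, params):
        members = set(cyl.member_location_ids)
        O = sum(
            1
            for c in dataset.cases
            if c.location_id in members and cyl.t_start <= c.event_date <= cyl.t_end
        )
        pop = sum(
            dataset.locations.populations[dataset.locations.index(m)] for m in members
        )
        days = (cyl.t_end - cyl.t_start).days + 1
        E = N * (pop / total_pop) * (days / total_days)
        if O <= E or O < params.min_cases or E <= 0:
            continue
        llr = O * math.log(O / E)
        if N - O > 0:
            llr += (N - O) * math.log((N - O) / (N - E))
        if best is None or llr > best[0] + 1e-12:
            best = (llr, {(O, round(E, 12))})
        elif abs(llr - best[0]) <= 1e-12:
            best[1].add((O, round(E, 12)))
    return best


class TestScan:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        params = ScanParams(t_max_days=30)
        for trial in range(15):
            n_loc = int(rng.integers(2, 7))
            n_days = int(rng.integers(3, 13))
            locations = make_locations(n=n_loc, seed=trial)
            counts = rng.poisson(0.25, size=(n_loc, n_days))
            if counts.sum() == 0:
                counts[0, 0] = 2
            dataset = make_dataset(counts, locations)
            oracle = brute_force_best(dataset, params)
            results = scan(dataset, params)
            if oracle is None:
                assert results == []
            else:
                mlc = results[0]
                assert mlc.llr == pytest.approx(oracle[0], abs=1e-9)
                assert (mlc.observed, round(mlc.expected, 12)) in oracle[1]

    def test_planted_burst_is_most_likely(self):
        locations = make_locations(n=5, seed=3)
        counts = np.zeros((5, 20), dtype=int)
        counts[2, 7:10] = [3, 4, 3]  # a one-location burst
        counts[0, 1] = 1
        counts[4, 15] = 1
        dataset = make_dataset(counts, locations)
        mlc = scan(dataset, ScanParams())[0]
        assert locations.ids[2] in mlc.cylinder.member_location_ids
        assert mlc.cylinder.t_start <= date(2015, 1, 8)
        assert mlc.cylinder.t_end >= date(2015, 1, 10)

    def test_min_cases_filter(self):
        locations = make_locations(n=3, seed=1)
        counts = np.zeros((3, 5), dtype=int)
        counts[1, 2] = 1
        dataset = make_dataset(counts, locations)
        assert scan(dataset, ScanParams(min_cases=2)) == []

    def test_empty_dataset_is_empty_result(self, two_location_table):
        dataset = make_dataset(np.zeros((2, 5), dtype=int), two_location_table)
        assert scan(dataset, ScanParams()) == []

    def test_reported_clusters_are_location_disjoint(self):
        rng = np.random.default_rng(7)
        locations = make_locations(n=8, seed=8)
        counts = rng.poisson(0.5, size=(8, 30))
        dataset = make_dataset(counts, locations)
        results = scan(dataset, ScanParams())
        seen = set()
        for r in results:
            members = set(r.cylinder.member_location_ids)
            assert not members & seen
            seen |= members

    def test_adding_case_inside_mlc_never_decreases_llr(self):
        rng = np.random.default_rng(11)
        locations = make_locations(n=5, seed=5)
        counts = rng.poisson(0.4, size=(5, 15))
        counts[2, 5] += 3
        dataset = make_dataset(counts, locations)
        params = ScanParams()
        mlc = scan(dataset, params)[0]
        li = locations.index(mlc.cylinder.centre_location_id)
        ui = (mlc.cylinder.t_start - dataset.period.start_date).days
        counts2 = counts.copy()
        counts2[li, ui] += 1
        mlc2 = scan(make_dataset(counts2, locations), params)[0]
        assert mlc2.llr >= mlc.llr - 1e-12

    def test_prospective_equals_filtered_retrospective(self):
        rng = np.random.default_rng(13)
        locations = make_locations(n=5, seed=9)
        counts = rng.poisson(0.6, size=(5, 12))
        counts[3, -1] += 2  # something active at the end
        dataset = make_dataset(counts, locations)
        end = dataset.period.end_date
        prosp = scan(dataset, ScanParams(mode="prospective"))
        retro_params = ScanParams(mode="retrospective")
        oracle = brute_force_best_prospective_filter(dataset, retro_params, end)
        if prosp:
            assert prosp[0].llr == pytest.approx(oracle, abs=1e-9)
        else:
            assert oracle is None

    def test_full_region_has_zero_llr(self, two_location_table):
        counts = np.ones((2, 4), dtype=int)
        dataset = make_dataset(counts, two_location_table)
        # with the cap at 1 the whole region is a window: O = N there, LLR 0
        results = scan(dataset, ScanParams(max_pop_fraction=1.0, t_max_days=30))
        assert all(r.observed < dataset.N or r.llr == 0 for r in results)


def brute_force_best_prospective_filter(dataset, params, end_date):
    """Best LLR among retrospective cylinders ending on the final date."""
    best = brute_force_best(
        dataset, ScanParams(mode="prospective", t_max_days=params.t_max_days)
    )
    return None if best is None else best[0]


class TestDeterminism:
    def test_scan_output_is_deterministic(self):
        rng = np.random.default_rng(21)
        locations = make_locations(n=6, seed=2)
        counts = rng.poisson(0.5, size=(6, 20))
        dataset = make_dataset(counts, locations)
        r1 = scan(dataset, ScanParams())
        r2 = scan(dataset, ScanParams())
        assert [(c.cylinder, c.observed, c.llr) for c in r1] == [
            (c.cylinder, c.observed, c.llr) for c in r2
        ]
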