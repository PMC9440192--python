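"""Cylindrical space-time scan statistic under the discrete Poisson model.

A candidate cluster is a *cylinder*: a circular spatial base (a centre
location plus its k nearest neighbours, for every k the population cap
allows) extruded over a time interval of at most ``t_max_days`` days.  In
retrospective mode the interval may sit anywhere in the study period; in
prospective mode it must end on the final day, so only clusters still
"active" at the analysis date are considered.

Each cylinder is scored by the Poisson log-likelihood ratio, conditional on
the observed grand total N::

    LLR = O ln(O/E) + (N - O) ln((N - O)/(N - E))   if O > E, else 0

where O is the observed and E the expected count inside the cylinder.
Expectations are proportional to population x interval length (spatially
heterogeneous, temporally homogeneous null).  Scanning is one-sided for
elevated rates, as appropriate for excess-incidence surveillance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Iterator, Sequence

import numpy as np

from .io import DataError, Dataset, LocationTable, StudyPeriod

__all__ = [
    "ScanParams",
    "Cylinder",
    "ClusterResult",
    "ExpectedSurface",
    "great_circle_km",
    "expected_counts",
    "poisson_llr",
    "relative_risk",
    "enumerate_cylinders",
    "scan",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class ScanParams:
    """Tuning parameters of the scan.

    Defaults follow common surveillance practice for sparse, non-infectious
    event data: a 30-day maximum temporal window at one-day aggregation,
    spatial windows capped at half the population at risk, a minimum of two
    cases per reported cluster, and 999 Monte-Carlo replications with a
    0.05 significance threshold.
    """

    mode: str = "retrospective"
    t_max_days: int = 30
    aggregation_days: int = 1
    max_pop_fraction: float = 0.5
    min_cases: int = 2
    n_replications: int = 999
    alpha: float = 0.05
    distance_metric: str = "great_circle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("retrospective", "prospective"):
            raise DataError(f"unknown scan mode {self.mode!r}")
        if self.distance_metric not in ("great_circle", "euclidean"):
            raise DataError(f"unknown distance metric {self.distance_metric!r}")
        if self.aggregation_days < 1:
            raise DataError("aggregation_days must be >= 1")
        if self.t_max_days < self.aggregation_days:
            raise DataError("t_max_days must be >= aggregation_days")
        if not (0 < self.max_pop_fraction <= 1):
            raise DataError("max_pop_fraction must be in (0, 1]")
        if self.min_cases < 1:
            raise DataError("min_cases must be >= 1")
        if self.n_replications < 0:
            raise DataError("n_replications must be >= 0")
        if not (0 < self.alpha < 1):
            raise DataError("alpha must be in (0, 1)")

    @property
    def max_units(self) -> int:
        """Maximum temporal window length in aggregated units."""
        return max(1, self.t_max_days // self.aggregation_days)


@dataclass(frozen=True)
class Cylinder:
    """A candidate space-time window."""

    centre_location_id: str
    radius_km: float
    member_location_ids: tuple[str, ...]
    t_start: date
    t_end: date

    @property
    def duration_days(self) -> int:
        """Table convention: end minus start, so a same-day window is 0."""
        return (self.t_end - self.t_start).days


@dataclass
class ClusterResult:
    """A scored (and possibly significance-tested) cluster."""

    cylinder: Cylinder
    observed: int
    expected: float
    llr: float
    relative_risk: float
    p_value: float | None = None
    significant: bool | None = None
    rank: int | None = None

    @property
    def duration_days(self) -> int:
        return self.cylinder.duration_days


@dataclass(frozen=True)
class ExpectedSurface:
    """Null expected counts per (location, time-unit) cell, conditioned on N.

    ``mu`` has shape (n_locations, n_units) and sums to N exactly.
    """

    mu: np.ndarray
    N: int
    locations: LocationTable
    period: StudyPeriod


# ---------------------------------------------------------------------------
# elementary statistics


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise DataError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise DataError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _distance_matrix(locations: LocationTable, metric: str) -> np.ndarray:
    lat = np.radians(locations.latitudes)[:, None]
    lon = np.radians(locations.longitudes)[:, None]
    if metric == "euclidean":
        return np.hypot(
            locations.latitudes[:, None] - locations.latitudes[None, :],
            locations.longitudes[:, None] - locations.longitudes[None, :],
        )
    dphi = lat - lat.T
    dlmb = lon - lon.T
    a = np.sin(dphi / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(a)))


def expected_counts(locations: LocationTable, period: StudyPeriod, N: int) -> ExpectedSurface:
    """Null expectation mu(loc, unit) = N * pop_share(loc) * day_share(unit)."""
    if N < 0:
        raise DataError("N must be >= 0")
    pop = locations.populations.astype(float)
    total = pop.sum()
    if total <= 0:
        raise DataError("zero total population")
    days = period.unit_days().astype(float)
    mu = N * np.outer(pop / total, days / days.sum())
    return ExpectedSurface(mu=mu, N=N, locations=locations, period=period)


def _llr_vec(O, E, N: int) -> np.ndarray:
    """Vectorized one-sided Poisson LLR with the 0*log(0) := 0 convention."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    rem = N - O
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(O > 0, O * np.log(np.where(O > 0, O, 1.0) / E), 0.0)
        outside = np.where(
            rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0) / (N - E)), 0.0
        )
    return np.where(O > E, inside + outside, 0.0)


def poisson_llr(O: int, E: float, N: int) -> float:
    """One-sided Poisson scan log-likelihood ratio for a single window."""
    if not 0 <= O <= N:
        raise DataError(f"O={O} outside [0, N={N}]")
    if not 0 < E < N:
        raise DataError(f"E={E} outside (0, N={N})")
    return float(_llr_vec(O, E, N))


def relative_risk(O: int, E: float, N: int) -> float:
    """Rate ratio inside vs outside the window; +inf when all cases inside."""
    if not 0 <= O <= N:
        raise DataError(f"O={O} outside [0, N={N}]")
    if not 0 < E < N:
        raise DataError(f"E={E} outside (0, N={N})")
    if O == N:
        return math.inf
    return (O / E) / ((N - O) / (N - E))


# ---------------------------------------------------------------------------
# cylinder geometry


@dataclass(frozen=True)
class Zone:
    """A circular spatial base: a centre and its nearest-neighbour closure."""

    centre_index: int
    radius_km: float
    member_indices: tuple[int, ...]
    pop_fraction: float


def build_zones(
    locations: LocationTable,
    max_pop_fraction: float = 0.5,
    distance_metric: str = "great_circle",
) -> list[Zone]:
    """All distinct nested nearest-neighbour zones under the population cap.

    For every centre, neighbours are added in order of (distance, id); each
    prefix whose population stays within ``max_pop_fraction`` of the total
    is a zone.  The singleton {centre} zone is always kept, even when the
    centre alone exceeds the cap — otherwise a location holding more than
    the cap's share of the population (e.g. a single-location geometry,
    where only temporal windows can score) could never be scanned at all.
    Duplicate member sets arising from different centres are emitted once,
    keeping the representative with the smallest (radius, centre id) for
    deterministic tie-breaking downstream.
    """
    D = _distance_matrix(locations, distance_metric)
    pop = locations.populations.astype(float)
    cap = max_pop_fraction * pop.sum()
    ids = locations.ids
    best: dict[frozenset[int], Zone] = {}
    for c in range(len(locations)):
        order = sorted(range(len(locations)), key=lambda j: (D[c, j], ids[j]))
        members: list[int] = []
        cum = 0.0
        for j in order:
            if members and cum + pop[j] > cap:
                break
            cum += pop[j]
            members.append(j)
            key = frozenset(members)
            zone = Zone(
                centre_index=c,
                radius_km=float(D[c, j]),
                member_indices=tuple(members),
                pop_fraction=cum / pop.sum(),
            )
            prev = best.get(key)
            if prev is None or (zone.radius_km, ids[c]) < (prev.radius_km, ids[prev.centre_index]):
                best[key] = zone
    return sorted(best.values(), key=lambda z: (ids[z.centre_index], z.radius_km, z.member_indices))


def _temporal_windows(n_units: int, max_units: int, prospective: bool) -> Iterator[tuple[int, int]]:
    """(start_unit, end_unit) inclusive pairs for the scanning mode."""
    if prospective:
        e = n_units - 1
        for length in range(1, min(max_units, n_units) + 1):
            yield e - length + 1, e
    else:
        for length in range(1, min(max_units, n_units) + 1):
            for s in range(n_units - length + 1):
                yield s, s + length - 1


def enumerate_cylinders(
    locations: LocationTable, period: StudyPeriod, params: ScanParams
) -> list[Cylinder]:
    """Materialize every candidate cylinder (intended for small problems;
    :func:`scan` evaluates the same set without building objects)."""
    zones = build_zones(locations, params.max_pop_fraction, params.distance_metric)
    out = []
    for z in zones:
        member_ids = tuple(locations.ids[i] for i in z.member_indices)
        centre_id = locations.ids[z.centre_index]
        for s, e in _temporal_windows(period.n_units, params.max_units, params.mode == "prospective"):
            out.append(
                Cylinder(
                    centre_location_id=centre_id,
                    radius_km=z.radius_km,
                    member_location_ids=member_ids,
                    t_start=period.unit_start(s),
                    t_end=period.unit_end(e),
                )
            )
    return out


# ---------------------------------------------------------------------------
# the scan


def _candidate_arrays(
    counts: np.ndarray,
    zones: Sequence[Zone],
    period: StudyPeriod,
    params: ScanParams,
    N: int,
):
    """Yield per-(zone, window-length) vectors of (O, E, llr, start_units)."""
    n_units = period.n_units
    day_len = period.unit_days().astype(float)
    DD = np.concatenate([[0.0], np.cumsum(day_len)])
    total_days = DD[-1]
    prospective = params.mode == "prospective"
    max_len = min(params.max_units, n_units)
    for zi, z in enumerate(zones):
        series = counts[list(z.member_indices), :].sum(axis=0)
        P = np.concatenate([[0], np.cumsum(series)])
        for length in range(1, max_len + 1):
            if prospective:
                starts = np.array([n_units - length], dtype=int)
            else:
                starts = np.arange(n_units - length + 1)
            O = P[starts + length] - P[starts]
            interval_days = DD[starts + length] - DD[starts]
            E = N * z.pop_fraction * interval_days / total_days
            llr = _llr_vec(O, E, N)
            yield zi, length, starts, O, E, llr


def scan(dataset: Dataset, params: ScanParams) -> list[ClusterResult]:
    """Rank non-overlapping clusters by LLR (p-values attached separately).

    Returns the most-likely cluster first, then secondary clusters in
    decreasing LLR whose member-location sets are disjoint from every
    better-ranked cluster.  Only windows with at least ``min_cases``
    observed cases and a strictly positive LLR are reported.  Ties are
    broken by (smaller radius, earlier start, centre id).
    """
    counts = dataset.count_matrix()
    N = int(counts.sum())
    if N == 0:
        return []
    if params.aggregation_days != dataset.period.aggregation_days:
        period = StudyPeriod(
            dataset.period.start_date, dataset.period.end_date, params.aggregation_days
        )
        dataset = Dataset(dataset.cases, dataset.locations, period)
        counts = dataset.count_matrix()
    zones = build_zones(dataset.locations, params.max_pop_fraction, params.distance_metric)
    period = dataset.period
    ids = dataset.locations.ids

    # All windows of a zone share one member set, so under the
    # no-geographic-overlap reporting rule only each zone's best window can
    # ever be reported: reduce to one candidate per zone on the fly.
    # Per-zone rows: (-llr, s, e, O, E); ties prefer earlier, shorter windows.
    best_per_zone: dict[int, tuple[float, int, int, int, float]] = {}
    for zi, length, starts, O, E, llr in _candidate_arrays(counts, zones, period, params, N):
        keep = (O >= params.min_cases) & (llr > 0) & (E > 0)
        if not keep.any():
            continue
        kk = np.flatnonzero(keep)
        k = kk[np.argmax(llr[kk])]
        row = (-float(llr[k]), int(starts[k]), int(starts[k]) + length - 1, int(O[k]), float(E[k]))
        if zi not in best_per_zone or row < best_per_zone[zi]:
            best_per_zone[zi] = row

    cand = [
        (
            -row[0], zones[zi].radius_km, period.unit_start(row[1]),
            ids[zones[zi].centre_index], zi, row[1], row[2], row[3], row[4],
        )
        for zi, row in best_per_zone.items()
    ]
    cand.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))

    results: list[ClusterResult] = []
    used: set[int] = set()
    for llr, radius, _, centre_id, zi, s, e, O, E in cand:
        members = zones[zi].member_indices
        if used.intersection(members):
            continue
        used.update(members)
        cyl = Cylinder(
            centre_location_id=centre_id,
            radius_km=radius,
            member_location_ids=tuple(ids[i] for i in members),
            t_start=period.unit_start(s),
            t_end=period.unit_end(e),
        )
        results.append(
            ClusterResult(
                cylinder=cyl,
                observed=O,
                expected=E,
                llr=llr,
                relative_risk=relative_risk(O, E, N) if E < N else 1.0,
                rank=len(results) + 1,
            )
        )
    return results
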