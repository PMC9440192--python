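"""Seeded synthetic datasets with the structure the scan statistic assumes.

Real small-area suicide surveillance data are access-restricted, so the
package ships a generator that emulates their statistical shape:

* small-area centroids scattered uniformly over a bounding box, with
  heterogeneous log-normal population counts (a handful of towns, many
  sparse rural areas);
* a baseline case process that is Poisson with rate proportional to
  population and homogeneous in time — exactly the scan's null model;
* optional planted cylindrical clusters that multiply the baseline rate by
  a relative risk inside a circle x time-interval window, for power and
  recovery studies.

Defaults emulate a decade of county-level data: 100 small areas in a
1-degree square and an expected 388 cases over 2008-2017.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Sequence

import numpy as np

from .core import ClusterResult, great_circle_km
from .io import CaseRecord, DataError, Dataset, LocationTable, StudyPeriod

__all__ = [
    "PlantedCluster",
    "SyntheticConfig",
    "generate",
    "resolve_planted_members",
    "OverlapMetrics",
    "plant_truth_overlap",
]

_GENDER_LEVELS = ("male", "female")
_GENDER_PROBS = (0.8, 0.2)
_METHOD_LEVELS = ("hanging", "drowning", "overdose", "other")
_METHOD_PROBS = (0.6, 0.12, 0.12, 0.16)


@dataclass(frozen=True)
class PlantedCluster:
    """Ground-truth excess-risk cylinder: rate x RR inside the window."""

    centre_lat: float
    centre_lon: float
    radius_km: float
    t_start: date
    t_end: date
    relative_risk: float

    def __post_init__(self) -> None:
        if self.relative_risk < 1:
            raise DataError("planted relative_risk must be >= 1")
        if self.t_start > self.t_end:
            raise DataError("planted window start after end")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of one synthetic study dataset.

    ``expected_total_cases`` is the expected *baseline* total (planted
    clusters add excess cases on top); set ``fixed_n`` to condition on an
    exact total instead.  The seed is mandatory: every dataset must be
    reproducible.
    """

    seed: int
    n_locations: int = 100
    pop_median: float = 300.0
    pop_sigma: float = 1.0
    bbox: tuple[float, float, float, float] = (51.4, -9.5, 52.4, -8.5)  # lat0, lon0, lat1, lon1
    start_date: date = date(2008, 1, 1)
    end_date: date = date(2017, 12, 31)
    expected_total_cases: float = 388.0
    fixed_n: int | None = None
    planted_clusters: tuple[PlantedCluster, ...] = ()
    seasonal_amplitude: float = 0.0  # optional sinusoidal annual multiplier, off by default
    with_demographics: bool = True

    def __post_init__(self) -> None:
        lat0, lon0, lat1, lon1 = self.bbox
        if not (lat0 < lat1 and lon0 < lon1):
            raise DataError("degenerate bounding box")
        if self.start_date > self.end_date:
            raise DataError("empty study period")
        if self.n_locations < 1:
            raise DataError("need at least one location")
        for pc in self.planted_clusters:
            if pc.t_start < self.start_date or pc.t_end > self.end_date:
                raise DataError("planted window outside study period")


def _locations(cfg: SyntheticConfig, rng: np.random.Generator) -> LocationTable:
    lat0, lon0, lat1, lon1 = cfg.bbox
    lats = rng.uniform(lat0, lat1, cfg.n_locations)
    lons = rng.uniform(lon0, lon1, cfg.n_locations)
    pops = np.maximum(
        1, np.round(rng.lognormal(np.log(cfg.pop_median), cfg.pop_sigma, cfg.n_locations))
    ).astype(int)
    width = len(str(cfg.n_locations))
    ids = [f"SA{i + 1:0{width}d}" for i in range(cfg.n_locations)]
    return LocationTable(ids, lats, lons, pops)


def resolve_planted_members(
    locations: LocationTable, planted: PlantedCluster
) -> tuple[str, ...]:
    """Location ids inside the planted circle (its realized spatial truth)."""
    members = [
        locations.ids[i]
        for i in range(len(locations))
        if great_circle_km(
            planted.centre_lat, planted.centre_lon,
            locations.latitudes[i], locations.longitudes[i],
        )
        <= planted.radius_km
    ]
    return tuple(members)


def _rate_matrix(cfg: SyntheticConfig, locations: LocationTable, period: StudyPeriod) -> np.ndarray:
    pop = locations.populations.astype(float)
    n_units = period.n_units
    base = np.outer(pop / pop.sum(), np.full(n_units, 1.0 / n_units))
    if cfg.seasonal_amplitude:
        doy = np.array(
            [(period.unit_start(u).timetuple().tm_yday) for u in range(n_units)], dtype=float
        )
        season = 1.0 + cfg.seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
        base = base * season[None, :]
        base /= base.sum()
    rate = cfg.expected_total_cases * base
    for pc in cfg.planted_clusters:
        member_idx = [locations.index(m) for m in resolve_planted_members(locations, pc)]
        u0, u1 = period.unit_index(pc.t_start), period.unit_index(pc.t_end)
        if member_idx:
            rate[np.ix_(member_idx, range(u0, u1 + 1))] *= pc.relative_risk
    return rate


def generate(cfg: SyntheticConfig) -> Dataset:
    """Draw one synthetic dataset; fully reproducible from the seed."""
    rng = np.random.default_rng(cfg.seed)
    locations = _locations(cfg, rng)
    period = StudyPeriod(cfg.start_date, cfg.end_date, aggregation_days=1)
    rate = _rate_matrix(cfg, locations, period)
    if cfg.fixed_n is not None:
        probs = rate.ravel() / rate.sum()
        counts = rng.multinomial(cfg.fixed_n, probs).reshape(rate.shape)
    else:
        counts = rng.poisson(rate)
    cases: list[CaseRecord] = []
    seq = 0
    for li, ui in zip(*np.nonzero(counts)):
        for _ in range(counts[li, ui]):
            seq += 1
            event = period.unit_start(int(ui))
            gender = age = method = None
            if cfg.with_demographics:
                gender = str(rng.choice(_GENDER_LEVELS, p=_GENDER_PROBS))
                age = float(int(np.clip(rng.normal(40, 15), 15, 90)))
                method = str(rng.choice(_METHOD_LEVELS, p=_METHOD_PROBS))
            cases.append(
                CaseRecord(
                    case_id=f"C{seq:06d}",
                    location_id=locations.ids[li],
                    event_date=event,
                    gender=gender,
                    age_years=age,
                    method=method,
                )
            )
    return Dataset(cases=cases, locations=locations, period=period)


@dataclass(frozen=True)
class OverlapMetrics:
    """Agreement between a detected cluster and a planted truth window."""

    spatial_jaccard: float
    temporal_overlap: float


def plant_truth_overlap(
    detected: ClusterResult,
    truth: PlantedCluster,
    locations: LocationTable,
    truth_members: Sequence[str] | None = None,
) -> OverlapMetrics:
    """Spatial Jaccard of member-location sets and temporal
    intersection-over-union of the (inclusive) day intervals."""
    truth_set = set(
        truth_members if truth_members is not None else resolve_planted_members(locations, truth)
    )
    det_set = set(detected.cylinder.member_location_ids)
    union = det_set | truth_set
    spatial = len(det_set & truth_set) / len(union) if union else 0.0

    a0, a1 = detected.cylinder.t_start, detected.cylinder.t_end
    b0, b1 = truth.t_start, truth.t_end
    inter = (min(a1, b1) - max(a0, b0)).days + 1
    uni = (max(a1, b1) - min(a0, b0)).days + 1
    temporal = max(0, inter) / uni if uni > 0 else 0.0
    return OverlapMetrics(spatial_jaccard=spatial, temporal_overlap=temporal)
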