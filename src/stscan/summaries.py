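"""Dashboard data products: demographic breakdowns and GeoJSON cluster maps.

These functions produce the tables and geometries a surveillance dashboard
renders — percentage breakdowns by gender, age group and method of death,
and an RFC 7946 GeoJSON document with one feature per detected cluster —
without doing any rendering themselves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import ClusterResult, EARTH_RADIUS_KM
from .io import CaseRecord, DataError, LocationTable

__all__ = [
    "BreakdownTable",
    "demographic_breakdown",
    "export_clusters_geojson",
    "write_clusters_geojson",
]

DIMENSIONS = ("gender", "age_group", "method")
DEFAULT_AGE_BINS = (0, 10, 20, 30, 40, 50, 60, 70, 80, 90)


@dataclass
class BreakdownTable:
    """Category counts and percentages for one demographic dimension.

    Percentages are over cases with a non-missing value; missing cases are
    counted separately and never silently dropped.
    """

    dimension: str
    table: pd.DataFrame  # columns: category, count, percentage
    n_missing: int
    n_total: int

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.loc[len(out)] = ["(missing)", self.n_missing, float("nan")]
        out.to_csv(path, index=False)


def _age_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi - 1}"


def demographic_breakdown(
    cases: Iterable[CaseRecord],
    dimension: str,
    age_bins: Sequence[int] | None = None,
) -> BreakdownTable:
    """Counts and percentages per category of ``dimension``.

    Ages are taken from ``age_years`` or computed at the event date from
    ``birth_date``.  Age bins are half-open, low-inclusive: with bins
    ``[0, 20, 40]`` an age of 39.99 falls in 20-39 and the last bin (40+)
    is unbounded.
    """
    if dimension not in DIMENSIONS:
        raise DataError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    cases = list(cases)
    values: list[str] = []
    n_missing = 0
    if dimension == "age_group":
        bins = list(age_bins if age_bins is not None else DEFAULT_AGE_BINS)
        if any(b1 <= b0 for b0, b1 in zip(bins, bins[1:])):
            raise DataError("age_bins must be strictly increasing")
        edges = bins + [None]
        for c in cases:
            age = c.age_at_event()
            if age is None or age < bins[0]:
                n_missing += 1
                continue
            k = int(np.searchsorted(bins, age, side="right")) - 1
            values.append(_age_label(bins[k], edges[k + 1]))
        categories = [_age_label(lo, hi) for lo, hi in zip(bins, edges[1:])]
    else:
        for c in cases:
            v = getattr(c, dimension)
            if v is None:
                n_missing += 1
            else:
                values.append(str(v))
        categories = sorted(set(values))

    counts = pd.Series(values, dtype=object).value_counts()
    n_valid = int(counts.sum())
    rows = []
    for cat in categories:
        n = int(counts.get(cat, 0))
        if dimension != "age_group" and n == 0:
            continue
        pct = 100.0 * n / n_valid if n_valid else float("nan")
        rows.append({"category": cat, "count": n, "percentage": pct})
    table = pd.DataFrame(rows, columns=["category", "count", "percentage"])
    return BreakdownTable(
        dimension=dimension, table=table, n_missing=n_missing, n_total=len(cases)
    )


def _circle_ring(lat: float, lon: float, radius_km: float, n_segments: int = 64) -> list[list[float]]:
    """Closed counterclockwise ring approximating a geodesic circle."""
    deg_per_km_lat = 180.0 / (math.pi * EARTH_RADIUS_KM)
    deg_per_km_lon = deg_per_km_lat / max(1e-9, math.cos(math.radians(lat)))
    ring = []
    for k in range(n_segments):
        theta = 2 * math.pi * k / n_segments
        ring.append(
            [
                round(lon + radius_km * math.cos(theta) * deg_per_km_lon, 9),
                round(lat + radius_km * math.sin(theta) * deg_per_km_lat, 9),
            ]
        )
    ring.append(list(ring[0]))
    return ring


def export_clusters_geojson(
    results: Iterable[ClusterResult], locations: LocationTable
) -> dict:
    """RFC 7946 FeatureCollection: one feature per cluster, WGS84
    [lon, lat] order.  Single-location (radius 0) clusters become Points;
    others become 64-segment polygons around the centre."""
    features = []
    for c in results:
        idx = locations.index(c.cylinder.centre_location_id)
        lat = float(locations.latitudes[idx])
        lon = float(locations.longitudes[idx])
        if c.cylinder.radius_km <= 0:
            geometry = {"type": "Point", "coordinates": [lon, lat]}
        else:
            geometry = {
                "type": "Polygon",
                "coordinates": [_circle_ring(lat, lon, c.cylinder.radius_km)],
            }
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {
                    "cluster_id": c.rank,
                    "centre_location_id": c.cylinder.centre_location_id,
                    "radius_km": c.cylinder.radius_km,
                    "member_location_ids": list(c.cylinder.member_location_ids),
                    "start_date": c.cylinder.t_start.isoformat(),
                    "end_date": c.cylinder.t_end.isoformat(),
                    "duration_days": c.duration_days,
                    "observed": c.observed,
                    "expected": c.expected,
                    "test_statistic": c.llr,
                    # strict JSON has no Infinity literal; an all-cases-inside
                    # cluster gets a null RR with a separate flag
                    "relative_risk": None if math.isinf(c.relative_risk) else c.relative_risk,
                    "all_cases_inside": math.isinf(c.relative_risk),
                    "p_value": c.p_value,
                    "significant": c.significant,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_clusters_geojson(path, results: Iterable[ClusterResult], locations: LocationTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(export_clusters_geojson(results, locations), fh, indent=1, sort_keys=True)
        fh.write("\n")
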