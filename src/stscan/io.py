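"""Reading, writing and validation of case, coordinates and population files.

Two on-disk dialects are supported:

* ``satscan`` — the whitespace/comma-delimited layout used by the SaTScan
  family of tools: a case file of ``<location_id> <count> <date>`` rows, a
  coordinates file of ``<location_id> <lat> <lon>`` rows and a population
  file of ``<location_id> <year> <population>`` rows (the year is validated
  but otherwise ignored: a single census snapshot is applied uniformly over
  the study period).
* ``csv`` — headered, comma-separated UTF-8 with one row per case and
  optional demographic columns.

Dates are accepted in ISO-8601 (``2011-09-15``) and slash form
(``2011/09/15``, also ``2011/9/5``).
"""

from __future__ import annotations

import csv as _csv
import os
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "CaseRecord",
    "LocationTable",
    "StudyPeriod",
    "Dataset",
    "parse_date",
    "read_case_file",
    "read_location_table",
    "write_dataset",
]

GENDERS = ("male", "female", "other/unknown")

_GENDER_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "o": "other/unknown",
    "other": "other/unknown",
    "unknown": "other/unknown",
    "other/unknown": "other/unknown",
}


class DataError(ValueError):
    """Raised for malformed or inconsistent input data.

    Carries per-line diagnostics in :attr:`problems` (list of
    ``(line_number, message)`` pairs) when the error arises from file
    parsing.
    """

    def __init__(self, message: str, problems: Sequence[tuple[int, str]] = ()):
        detail = message
        if problems:
            detail += "\n" + "\n".join(f"  line {ln}: {msg}" for ln, msg in problems)
        super().__init__(detail)
        self.problems = list(problems)


def parse_date(text: str) -> date:
    """Parse ``YYYY-MM-DD`` or ``YYYY/MM/DD`` (month/day may be unpadded)."""
    s = text.strip()
    for sep in ("-", "/"):
        parts = s.split(sep)
        if len(parts) == 3:
            try:
                y, m, d = (int(p) for p in parts)
                return date(y, m, d)
            except ValueError as exc:
                raise DataError(f"unparseable date {text!r}: {exc}") from None
    raise DataError(f"unparseable date {text!r}: expected YYYY-MM-DD or YYYY/MM/DD")


@dataclass(frozen=True)
class CaseRecord:
    """One suspected-suicide event assigned to a small-area location."""

    case_id: str
    location_id: str
    event_date: date
    gender: str | None = None
    age_years: float | None = None
    birth_date: date | None = None
    method: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.age_years is not None and self.age_years < 0:
            raise DataError(f"case {self.case_id}: negative age {self.age_years}")
        if self.gender is not None and self.gender not in GENDERS:
            norm = _GENDER_ALIASES.get(str(self.gender).strip().lower())
            if norm is None:
                raise DataError(f"case {self.case_id}: unknown gender {self.gender!r}")
            object.__setattr__(self, "gender", norm)

    def age_at_event(self) -> float | None:
        """Age in whole years at the event date (from ``age_years`` or
        ``birth_date``, in that order of preference)."""
        if self.age_years is not None:
            return self.age_years
        if self.birth_date is None:
            return None
        e, b = self.event_date, self.birth_date
        return e.year - b.year - ((e.month, e.day) < (b.month, b.day))


class LocationTable:
    """Small-area centroids with census population denominators.

    Locations are stored sorted by id; lookups by id are O(1).
    """

    def __init__(
        self,
        ids: Sequence[str],
        latitudes: Sequence[float],
        longitudes: Sequence[float],
        populations: Sequence[int],
    ):
        order = np.argsort(np.asarray(ids, dtype=object))
        self.ids: list[str] = [str(ids[i]) for i in order]
        self.latitudes = np.asarray(latitudes, dtype=float)[order]
        self.longitudes = np.asarray(longitudes, dtype=float)[order]
        self.populations = np.asarray(populations)[order].astype(np.int64)
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise DataError(f"duplicate location ids: {dupes}")
        if np.any(self.latitudes < -90) or np.any(self.latitudes > 90):
            raise DataError("latitude outside [-90, 90]")
        if np.any(self.longitudes < -180) or np.any(self.longitudes > 180):
            raise DataError("longitude outside [-180, 180]")
        if np.any(self.populations < 0):
            raise DataError("negative population count")
        if self.total_population <= 0:
            raise DataError("total population must be positive")
        self._index = {loc: i for i, loc in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, location_id: str) -> bool:
        return location_id in self._index

    def index(self, location_id: str) -> int:
        try:
            return self._index[location_id]
        except KeyError:
            raise DataError(f"unknown location id {location_id!r}") from None

    @property
    def total_population(self) -> int:
        return int(self.populations.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "location_id": self.ids,
                "latitude": self.latitudes,
                "longitude": self.longitudes,
                "population": self.populations,
            }
        )


@dataclass(frozen=True)
class StudyPeriod:
    """Inclusive calendar study window with a time-aggregation length.

    The period is partitioned into units of ``aggregation_days`` days; the
    final unit may be shorter when the period length is not a multiple of
    the aggregation.
    """

    start_date: date
    end_date: date
    aggregation_days: int = 1

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise DataError(
                f"study period start {self.start_date} after end {self.end_date}"
            )
        if self.aggregation_days < 1:
            raise DataError("aggregation_days must be >= 1")

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def n_units(self) -> int:
        return -(-self.n_days // self.aggregation_days)

    def unit_index(self, d: date) -> int:
        if d < self.start_date or d > self.end_date:
            raise DataError(f"date {d} outside study period")
        return (d - self.start_date).days // self.aggregation_days

    def unit_days(self) -> np.ndarray:
        """Length in days of every aggregated unit (last may be truncated)."""
        out = np.full(self.n_units, self.aggregation_days, dtype=np.int64)
        out[-1] = self.n_days - self.aggregation_days * (self.n_units - 1)
        return out

    def unit_start(self, u: int) -> date:
        return self.start_date + timedelta(days=u * self.aggregation_days)

    def unit_end(self, u: int) -> date:
        return min(
            self.start_date + timedelta(days=(u + 1) * self.aggregation_days - 1),
            self.end_date,
        )


@dataclass
class Dataset:
    """A coherent study dataset: cases + locations + period."""

    cases: list[CaseRecord]
    locations: LocationTable
    period: StudyPeriod

    def __post_init__(self) -> None:
        self.validate()

    @property
    def N(self) -> int:
        return len(self.cases)

    def validate(self) -> None:
        problems: list[tuple[int, str]] = []
        for i, c in enumerate(self.cases):
            if c.location_id not in self.locations:
                problems.append((i, f"case {c.case_id}: unknown location {c.location_id!r}"))
            if not (self.period.start_date <= c.event_date <= self.period.end_date):
                problems.append((i, f"case {c.case_id}: date {c.event_date} outside study period"))
        if problems:
            raise DataError("invalid dataset", problems)

    def count_matrix(self) -> np.ndarray:
        """Integer case counts per (location, aggregated time unit)."""
        counts = np.zeros((len(self.locations), self.period.n_units), dtype=np.int64)
        for c in self.cases:
            counts[self.locations.index(c.location_id), self.period.unit_index(c.event_date)] += 1
        return counts

    def subset_through(self, analysis_date: date) -> "Dataset":
        """Cases observed up to and including ``analysis_date``, with the
        period truncated to end on that date (for surveillance replay)."""
        if not (self.period.start_date <= analysis_date <= self.period.end_date):
            raise DataError(f"analysis date {analysis_date} outside study period")
        return Dataset(
            cases=[c for c in self.cases if c.event_date <= analysis_date],
            locations=self.locations,
            period=StudyPeriod(
                self.period.start_date, analysis_date, self.period.aggregation_days
            ),
        )


# ---------------------------------------------------------------------------
# readers


def _tokenize(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_case_file(path: str | os.PathLike, dialect: str = "satscan") -> list[CaseRecord]:
    """Read a case file; one :class:`CaseRecord` per unit count.

    In the ``satscan`` dialect a row ``SA001 2 2011-09-15`` expands to two
    case records.  In the ``csv`` dialect each data row is one case and must
    carry unique ``case_id`` values when that column is present.
    """
    if dialect == "satscan":
        return _read_cases_satscan(path)
    if dialect == "csv":
        return _read_cases_csv(path)
    raise DataError(f"unknown case-file dialect {dialect!r}")


def _read_cases_satscan(path: str | os.PathLike) -> list[CaseRecord]:
    cases: list[CaseRecord] = []
    problems: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = _tokenize(line)
            if len(tokens) != 3:
                problems.append((ln, f"expected 3 fields, got {len(tokens)}"))
                continue
            loc, count_s, date_s = tokens
            try:
                count = int(count_s)
            except ValueError:
                problems.append((ln, f"non-integer count {count_s!r}"))
                continue
            if count < 0:
                problems.append((ln, f"negative count {count}"))
                continue
            try:
                d = parse_date(date_s)
            except DataError as exc:
                problems.append((ln, str(exc)))
                continue
            for k in range(count):
                cases.append(
                    CaseRecord(case_id=f"{loc}:{d.isoformat()}:{k}", location_id=loc, event_date=d)
                )
    if problems:
        raise DataError(f"malformed case file {os.fspath(path)}", problems)
    return cases


_CSV_LOCATION_NAMES = ("location_id", "location", "loc_id")
_CSV_DATE_NAMES = ("event_date", "date", "date_of_death")


def _read_cases_csv(path: str | os.PathLike) -> list[CaseRecord]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = _csv.DictReader(fh)
        if reader.fieldnames is None:
            raise DataError(f"empty csv case file {os.fspath(path)}")
        fields = [f.strip().lower() for f in reader.fieldnames]
        colmap = dict(zip(fields, reader.fieldnames))
        loc_col = next((colmap[n] for n in _CSV_LOCATION_NAMES if n in colmap), None)
        date_col = next((colmap[n] for n in _CSV_DATE_NAMES if n in colmap), None)
        if loc_col is None or date_col is None:
            raise DataError(
                "csv case file needs a location column "
                f"({'/'.join(_CSV_LOCATION_NAMES)}) and a date column "
                f"({'/'.join(_CSV_DATE_NAMES)}); found {reader.fieldnames}"
            )
        known = {loc_col, date_col}
        opt = {}
        for name in ("case_id", "gender", "age_years", "birth_date", "method"):
            if name in colmap:
                opt[name] = colmap[name]
                known.add(colmap[name])
        extra_cols = [c for c in reader.fieldnames if c not in known]

        cases: list[CaseRecord] = []
        problems: list[tuple[int, str]] = []
        seen_ids: set[str] = set()
        for ln, row in enumerate(reader, start=2):
            try:
                d = parse_date(row[date_col])
            except DataError as exc:
                problems.append((ln, str(exc)))
                continue
            case_id = (row.get(opt.get("case_id", ""), "") or "").strip() or f"row{ln}"
            if "case_id" in opt:
                if case_id in seen_ids:
                    problems.append((ln, f"duplicate case_id {case_id!r}"))
                    continue
                seen_ids.add(case_id)
            age: float | None = None
            if opt.get("age_years") and (row[opt["age_years"]] or "").strip():
                try:
                    age = float(row[opt["age_years"]])
                except ValueError:
                    problems.append((ln, f"non-numeric age {row[opt['age_years']]!r}"))
                    continue
            birth: date | None = None
            if opt.get("birth_date") and (row[opt["birth_date"]] or "").strip():
                try:
                    birth = parse_date(row[opt["birth_date"]])
                except DataError as exc:
                    problems.append((ln, str(exc)))
                    continue
            gender = (row.get(opt.get("gender", ""), "") or "").strip() or None
            method = (row.get(opt.get("method", ""), "") or "").strip() or None
            attributes = {c: row[c] for c in extra_cols if (row[c] or "").strip()}
            try:
                cases.append(
                    CaseRecord(
                        case_id=case_id,
                        location_id=str(row[loc_col]).strip(),
                        event_date=d,
                        gender=gender,
                        age_years=age,
                        birth_date=birth,
                        method=method,
                        attributes=attributes,
                    )
                )
            except DataError as exc:
                problems.append((ln, str(exc)))
    if problems:
        raise DataError(f"malformed case file {os.fspath(path)}", problems)
    return cases


def _looks_headered(path: str | os.PathLike) -> bool:
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                head = line.lower()
                return any(k in head for k in ("location", "lat", "population", "pop"))
    return False


def read_location_table(
    geo_path: str | os.PathLike, pop_path: str | os.PathLike
) -> LocationTable:
    """Join a coordinates file with a population file into a
    :class:`LocationTable`; the two key sets must match exactly."""
    geo = _read_keyed_file(geo_path, n_values=2, kind="coordinates")
    pop = _read_keyed_file(pop_path, n_values=2, kind="population")
    geo_keys, pop_keys = set(geo), set(pop)
    if geo_keys != pop_keys:
        missing_pop = sorted(geo_keys - pop_keys)
        missing_geo = sorted(pop_keys - geo_keys)
        parts = []
        if missing_pop:
            parts.append(f"missing from population file: {missing_pop}")
        if missing_geo:
            parts.append(f"missing from coordinates file: {missing_geo}")
        raise DataError("location key mismatch; " + "; ".join(parts))
    ids = sorted(geo)
    lats, lons, pops = [], [], []
    for loc in ids:
        lat_s, lon_s = geo[loc]
        try:
            lats.append(float(lat_s))
            lons.append(float(lon_s))
        except ValueError:
            raise DataError(f"non-numeric coordinate for {loc!r}") from None
        _, pop_s = pop[loc]
        try:
            p = float(pop_s)
        except ValueError:
            raise DataError(f"non-numeric population for {loc!r}") from None
        if p < 0:
            raise DataError(f"negative population for {loc!r}")
        pops.append(int(round(p)))
    return LocationTable(ids, lats, lons, pops)


def _read_keyed_file(path: str | os.PathLike, n_values: int, kind: str) -> dict[str, tuple]:
    """Read `<id> v1 v2` style rows (satscan layout or a headered CSV).

    For the population file the two values are (year, population); for the
    coordinates file they are (lat, lon).
    """
    out: dict[str, tuple] = {}
    problems: list[tuple[int, str]] = []
    headered = _looks_headered(path)
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if headered and ln == 1:
                continue
            tokens = _tokenize(line)
            if len(tokens) < 1 + n_values:
                problems.append((ln, f"expected {1 + n_values} fields, got {len(tokens)}"))
                continue
            key = tokens[0]
            if key in out:
                problems.append((ln, f"duplicate location id {key!r}"))
                continue
            out[key] = tuple(tokens[1 : 1 + n_values])
    if problems:
        raise DataError(f"malformed {kind} file {os.fspath(path)}", problems)
    return out


# ---------------------------------------------------------------------------
# writer


def write_dataset(
    dataset: Dataset, out_dir: str | os.PathLike, dialect: str = "satscan"
) -> dict[str, str]:
    """Write a dataset to ``out_dir``; round-tripping through the readers
    reproduces the per-location/day case counts and the location table
    exactly.  Returns the paths written, keyed by role."""
    os.makedirs(out_dir, exist_ok=True)
    out_dir = os.fspath(out_dir)
    geo_path = os.path.join(out_dir, "locations.geo")
    pop_path = os.path.join(out_dir, "locations.pop")
    loc = dataset.locations
    with open(geo_path, "w", encoding="utf-8") as fh:
        for i, lid in enumerate(loc.ids):
            fh.write(f"{lid} {loc.latitudes[i]:.6f} {loc.longitudes[i]:.6f}\n")
    census_year = dataset.period.start_date.year
    with open(pop_path, "w", encoding="utf-8") as fh:
        for i, lid in enumerate(loc.ids):
            fh.write(f"{lid} {census_year} {int(loc.populations[i])}\n")

    if dialect == "satscan":
        case_path = os.path.join(out_dir, "cases.cas")
        agg: dict[tuple[str, date], int] = {}
        for c in dataset.cases:
            agg[(c.location_id, c.event_date)] = agg.get((c.location_id, c.event_date), 0) + 1
        with open(case_path, "w", encoding="utf-8") as fh:
            for (lid, d), n in sorted(agg.items()):
                fh.write(f"{lid} {n} {d.isoformat()}\n")
    elif dialect == "csv":
        case_path = os.path.join(out_dir, "cases.csv")
        rows = []
        for c in sorted(dataset.cases, key=lambda c: (c.event_date, c.location_id, c.case_id)):
            rows.append(
                {
                    "case_id": c.case_id,
                    "location_id": c.location_id,
                    "event_date": c.event_date.isoformat(),
                    "gender": c.gender or "",
                    "age_years": "" if c.age_years is None else c.age_years,
                    "birth_date": "" if c.birth_date is None else c.birth_date.isoformat(),
                    "method": c.method or "",
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "case_id", "location_id", "event_date", "gender",
                "age_years", "birth_date", "method",
            ],
        ).to_csv(case_path, index=False)
    else:
        raise DataError(f"unknown dialect {dialect!r}")

    period_path = os.path.join(out_dir, "period.csv")
    with open(period_path, "w", encoding="utf-8") as fh:
        fh.write("start_date,end_date,aggregation_days\n")
        fh.write(
            f"{dataset.period.start_date.isoformat()},"
            f"{dataset.period.end_date.isoformat()},{dataset.period.aggregation_days}\n"
        )
    return {"cases": case_path, "geo": geo_path, "pop": pop_path, "period": period_path}


def read_dataset(paths: Mapping[str, str], dialect: str = "satscan") -> Dataset:
    """Inverse of :func:`write_dataset` given its returned path mapping."""
    cases = read_case_file(paths["cases"], dialect=dialect)
    locations = read_location_table(paths["geo"], paths["pop"])
    with open(paths["period"], encoding="utf-8") as fh:
        next(fh)
        start_s, end_s, agg_s = fh.readline().strip().split(",")
    period = StudyPeriod(parse_date(start_s), parse_date(end_s), int(agg_s))
    return Dataset(cases=cases, locations=locations, period=period)
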