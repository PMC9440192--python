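"""Periodic prospective surveillance replay and cluster timelines.

``prospective_replay`` re-runs the prospective scan on a schedule of
analysis dates, each time using only the cases observed up to that date —
emulating how a live surveillance system would have behaved over a
historical period.  The output is an alarm timeline: per analysis date,
the active clusters (cylinders ending on that date), their p-values, and
an alarm flag when any cluster is significant at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, timedelta
from typing import Iterable

import pandas as pd

from .core import ClusterResult, ScanParams
from .inference import ScanAnalysis, analyze
from .io import DataError, Dataset

__all__ = [
    "AnalysisSchedule",
    "AlarmEntry",
    "AlarmTimeline",
    "prospective_replay",
    "build_cluster_timeline",
]

_FREQUENCIES = ("daily", "weekly", "monthly", "yearly")


def _add_months(d: date, months: int) -> date:
    month_index = d.month - 1 + months
    year = d.year + month_index // 12
    month = month_index % 12 + 1
    # clamp to month length (e.g. Jan 31 + 1 month -> Feb 28)
    for day in range(d.day, 27, -1):
        try:
            return date(year, month, day)
        except ValueError:
            continue
    return date(year, month, min(d.day, 28))


@dataclass(frozen=True)
class AnalysisSchedule:
    """Dates at which the prospective scan is (re)run."""

    frequency: str
    first_analysis_date: date
    last_analysis_date: date

    def __post_init__(self) -> None:
        if self.frequency not in _FREQUENCIES:
            raise DataError(
                f"unknown frequency {self.frequency!r}; expected one of {_FREQUENCIES}"
            )
        if self.first_analysis_date > self.last_analysis_date:
            raise DataError("first_analysis_date after last_analysis_date")

    def dates(self) -> list[date]:
        out = []
        d = self.first_analysis_date
        while d <= self.last_analysis_date:
            out.append(d)
            if self.frequency == "daily":
                d = d + timedelta(days=1)
            elif self.frequency == "weekly":
                d = d + timedelta(days=7)
            elif self.frequency == "monthly":
                d = _add_months(d, 1)
            else:
                d = _add_months(d, 12)
        return out


@dataclass
class AlarmEntry:
    """Findings of one scheduled prospective analysis."""

    analysis_date: date
    clusters: list[ClusterResult]
    alarm: bool

    @property
    def most_likely(self) -> ClusterResult | None:
        return self.clusters[0] if self.clusters else None


@dataclass
class AlarmTimeline:
    entries: list[AlarmEntry]
    params: ScanParams

    @property
    def alarm_dates(self) -> list[date]:
        return [e.analysis_date for e in self.entries if e.alarm]

    def to_frame(self) -> pd.DataFrame:
        """One row per (analysis date, reported cluster); analyses with no
        clusters contribute a row with empty cluster fields so that every
        scheduled analysis is visible in the export."""
        rows = []
        for e in self.entries:
            if not e.clusters:
                rows.append(
                    {
                        "analysis_date": e.analysis_date.isoformat(),
                        "cluster_id": "",
                        "alarm": e.alarm,
                    }
                )
            for c in e.clusters:
                rows.append(
                    {
                        "analysis_date": e.analysis_date.isoformat(),
                        "cluster_id": c.rank,
                        "start_date": c.cylinder.t_start.isoformat(),
                        "end_date": c.cylinder.t_end.isoformat(),
                        "duration_days": c.duration_days,
                        "observed": c.observed,
                        "expected": c.expected,
                        "relative_risk": c.relative_risk,
                        "p_value": c.p_value,
                        "significant": c.significant,
                        "recurrence_interval": (
                            1.0 / c.p_value if c.p_value else float("nan")
                        ),
                        "alarm": e.alarm,
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def prospective_replay(
    dataset: Dataset, params: ScanParams, schedule: AnalysisSchedule
) -> AlarmTimeline:
    """Replay prospective scanning over the schedule.

    Causality is enforced by construction: the analysis at date d sees only
    cases dated <= d and a study period ending at d.  Each analysis uses a
    seed offset from the master seed by its index, so the replay is
    reproducible yet analyses draw independent replicate streams.
    """
    if not (
        dataset.period.start_date
        <= schedule.first_analysis_date
        <= schedule.last_analysis_date
        <= dataset.period.end_date
    ):
        raise DataError("schedule extends outside the dataset study period")
    dates = schedule.dates()
    if not dates:
        raise DataError("empty analysis schedule")
    entries = []
    for i, d in enumerate(dates):
        sub = dataset.subset_through(d)
        p = replace(params, mode="prospective", seed=(params.seed + i) % 2**31)
        analysis: ScanAnalysis = analyze(sub, p)
        alarm = any(c.significant for c in analysis.results)
        entries.append(AlarmEntry(analysis_date=d, clusters=analysis.results, alarm=alarm))
    return AlarmTimeline(entries=entries, params=params)


def build_cluster_timeline(results: Iterable[ClusterResult]) -> pd.DataFrame:
    """Chronological cluster timeline records for plotting or export."""
    rows = []
    for c in results:
        rows.append(
            {
                "cluster_id": c.rank,
                "start_date": c.cylinder.t_start,
                "end_date": c.cylinder.t_end,
                "duration_days": c.duration_days,
                "observed": c.observed,
                "expected": c.expected,
                "p_value": c.p_value,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "start_date", "end_date", "duration_days",
            "observed", "expected", "p_value",
        ],
    )
    return frame.sort_values(["start_date", "end_date"], kind="stable").reset_index(drop=True)
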