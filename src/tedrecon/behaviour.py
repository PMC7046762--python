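"""Individual whereabouts records: parsing, plausibility screening, 6-hour discretization.

A behaviour record is a subject's ordered sequence of hourly waypoints
(place, activity) over 11-25 March 2011 (JST), as collected by evacuation
questionnaires.  Records are screened for impossible movements and for gaps
that leave whole days unlocatable, then collapsed onto the 56-slot
six-hour-segment timeline that the dose model consumes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .concentration_db import (
    BLOCKS,
    N_SEGMENTS,
    WINDOW_END,
    WINDOW_START,
    ConcentrationTable,
    SegmentIndex,
    haversine_km,
)

AGE_GROUPS = ("1y", "5y", "10y", "adult")
ACTIVITIES = ("indoor", "outdoor", "travel", "unknown")

#: full questionnaire window (11 March is recorded but never dosed)
RECORD_START = dt.date(2011, 3, 11)
RECORD_END = dt.date(2011, 3, 25)

JST = dt.timezone(dt.timedelta(hours=9))


@dataclass(frozen=True)
class Waypoint:
    timestamp: dt.datetime  # naive, interpreted as JST wall clock
    lat: float | None
    lon: float | None
    activity: str = "indoor"

    @property
    def located(self) -> bool:
        return self.lat is not None and self.lon is not None


@dataclass
class BehaviourRecord:
    subject_id: str
    age_group: str
    municipality: str
    moves: list[Waypoint]

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")
        times = [w.timestamp for w in self.moves]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.subject_id}: waypoint timestamps not strictly increasing")
        for w in self.moves:
            if not RECORD_START <= w.timestamp.date() <= RECORD_END:
                raise ValueError(
                    f"{self.subject_id}: waypoint {w.timestamp} outside 11-25 March 2011"
                )


@dataclass(frozen=True)
class ExclusionReport:
    subject_id: str
    municipality: str
    status: str  # included | excluded
    reason: str  # incomplete_route | unrealistic_movement | out_of_window | none

    def __post_init__(self) -> None:
        if self.status == "excluded" and self.reason == "none":
            raise ValueError("excluded record must carry a reason")


@dataclass
class SegmentTimeline:
    """Location occupied in each of the 56 dosed six-hour segments."""

    subject_id: str
    age_group: str
    municipality: str
    positions: np.ndarray  # (56, 2) lat/lon
    landmark_ids: list[str | None] = field(default_factory=lambda: [None] * N_SEGMENTS)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (N_SEGMENTS, 2):
            raise ValueError(f"positions shape {self.positions.shape} != ({N_SEGMENTS}, 2)")
        if len(self.landmark_ids) != N_SEGMENTS:
            raise ValueError("landmark_ids must have 56 entries")


# ---------------------------------------------------------------------------
# hourly expansion

def _hour_range():
    """The 360 hourly slots of 11-25 March (336 of which are dosed)."""
    t = dt.datetime.combine(RECORD_START, dt.time(0))
    end = dt.datetime.combine(RECORD_END, dt.time(23))
    while t <= end:
        yield t
        t += dt.timedelta(hours=1)


def hourly_locations(rec: BehaviourRecord) -> dict[dt.datetime, tuple[float, float] | None]:
    """Location occupied in every hourly slot of the record window.

    A waypoint holds from its timestamp until the next waypoint.  Hours of a
    ``travel`` waypoint are split between origin (location of the travel
    waypoint itself) and destination (next waypoint): first half at the
    origin, second half — including the odd middle hour — at the destination.
    Unlocated hours inherit the last known location; leading unlocated hours
    take the first known one.  ``None`` marks hours with no location at all.
    """
    hours = list(_hour_range())
    loc: dict[dt.datetime, tuple[float, float] | None] = {h: None for h in hours}
    moves = rec.moves
    for k, wp in enumerate(moves):
        start = wp.timestamp.replace(minute=0, second=0, microsecond=0)
        if k + 1 < len(moves):
            stop = moves[k + 1].timestamp.replace(minute=0, second=0, microsecond=0)
        else:
            stop = hours[-1] + dt.timedelta(hours=1)
        span = [h for h in hours if start <= h < stop]
        if wp.activity == "travel" and k + 1 < len(moves) and moves[k + 1].located:
            dest = (moves[k + 1].lat, moves[k + 1].lon)
            origin = (wp.lat, wp.lon) if wp.located else None
            n_origin = len(span) // 2  # odd hour goes to the destination
            for j, h in enumerate(span):
                loc[h] = origin if j < n_origin else dest
        else:
            p = (wp.lat, wp.lon) if wp.located else None
            for h in span:
                loc[h] = p
    # fill unknowns from neighbours (last known, else next known)
    last = None
    for h in hours:
        if loc[h] is not None:
            last = loc[h]
        elif last is not None:
            loc[h] = last
    nxt = None
    for h in reversed(hours):
        if loc[h] is not None:
            nxt = loc[h]
        elif nxt is not None:
            loc[h] = nxt
    return loc


# ---------------------------------------------------------------------------
# screening

def validate_record(rec: BehaviourRecord, speed_limit: float = 80.0) -> ExclusionReport:
    """Screen one record; never raises on content.

    ``unrealistic_movement``: any pair of consecutive located waypoints whose
    implied sustained great-circle speed exceeds ``speed_limit`` (km/h).
    ``incomplete_route``: some calendar day of 12-25 March has no locatable
    whereabouts even after carrying locations forward.
    """
    located = [w for w in rec.moves if w.located]
    for a, b in zip(located, located[1:]):
        hours = (b.timestamp - a.timestamp).total_seconds() / 3600.0
        d = float(haversine_km(a.lat, a.lon, b.lat, b.lon))
        if d / hours > speed_limit:
            return ExclusionReport(rec.subject_id, rec.municipality, "excluded",
                                   "unrealistic_movement")
    if not located:
        return ExclusionReport(rec.subject_id, rec.municipality, "excluded", "incomplete_route")
    # a whole dosed day with no reported waypoint *and* no earlier location to
    # inherit cannot be placed anywhere
    days_with_data = {w.timestamp.date() for w in located}
    first_day = min(days_with_data)
    day = WINDOW_START
    while day <= WINDOW_END:
        if day not in days_with_data and day < first_day:
            return ExclusionReport(rec.subject_id, rec.municipality, "excluded",
                                   "incomplete_route")
        day += dt.timedelta(days=1)
    return ExclusionReport(rec.subject_id, rec.municipality, "included", "none")


def exclusion_table(reports: list[ExclusionReport]) -> pd.DataFrame:
    """Per-municipality bookkeeping: received / excluded / analysed counts."""
    df = pd.DataFrame(
        [(r.municipality, r.status, r.reason) for r in reports],
        columns=["municipality", "status", "reason"],
    )
    out = (
        df.groupby("municipality", sort=True)
        .agg(
            received=("status", "size"),
            excluded=("status", lambda s: int((s == "excluded").sum())),
        )
        .reset_index()
    )
    out["analysed"] = out["received"] - out["excluded"]
    return out


# ---------------------------------------------------------------------------
# discretization

def discretize(rec: BehaviourRecord) -> SegmentTimeline:
    """Collapse hourly whereabouts onto the 56 dosed six-hour slots.

    Each slot takes the location occupied for the most hours within it;
    ties go to the location occupied latest in the block.
    """
    loc = hourly_locations(rec)
    positions = np.empty((N_SEGMENTS, 2))
    for ordinal in range(1, N_SEGMENTS + 1):
        seg = SegmentIndex.from_ordinal(ordinal)
        start_hour = BLOCKS.index(seg.block) * 6
        block_locs = []
        for h in range(start_hour, start_hour + 6):
            t = dt.datetime.combine(seg.date, dt.time(h))
            block_locs.append(loc[t])
        if any(p is None for p in block_locs):
            raise ValueError(
                f"{rec.subject_id}: no locatable whereabouts in segment "
                f"{seg.date} {seg.block} (record should have been excluded)"
            )
        counts: dict[tuple[float, float], int] = {}
        last_seen: dict[tuple[float, float], int] = {}
        for j, p in enumerate(block_locs):
            counts[p] = counts.get(p, 0) + 1
            last_seen[p] = j
        best = max(counts, key=lambda p: (counts[p], last_seen[p]))
        positions[ordinal - 1] = best
    return SegmentTimeline(rec.subject_id, rec.age_group, rec.municipality, positions)


def assign_landmarks(tl: SegmentTimeline, table: ConcentrationTable) -> SegmentTimeline:
    """Attach the nearest landmark id to every slot (total assignment)."""
    ids = [table.nearest_landmark(lat, lon).id for lat, lon in tl.positions]
    return SegmentTimeline(tl.subject_id, tl.age_group, tl.municipality,
                           tl.positions.copy(), ids)


# ---------------------------------------------------------------------------
# CSV interchange

def read_behaviour_csv(path) -> list[BehaviourRecord]:
    """Read the behaviour CSV dialect.

    Columns: subject_id, age_group, municipality, timestamp (ISO-8601,
    +09:00 offset or naive JST), lat, lon, activity.  Empty lat/lon marks an
    unlocated waypoint.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"subject_id", "age_group", "municipality", "timestamp", "lat", "lon", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behaviour CSV missing columns {sorted(missing)}")
    records = []
    for sid, g in df.groupby("subject_id", sort=True):
        ts = pd.to_datetime(g["timestamp"])
        if ts.dt.tz is not None:
            ts = ts.dt.tz_convert(JST).dt.tz_localize(None)
        moves = [
            Waypoint(
                t.to_pydatetime(),
                None if pd.isna(lat) else float(lat),
                None if pd.isna(lon) else float(lon),
                act,
            )
            for t, lat, lon, act in zip(ts, g["lat"], g["lon"], g["activity"])
        ]
        records.append(
            BehaviourRecord(str(sid), g["age_group"].iloc[0], str(g["municipality"].iloc[0]),
                            moves)
        )
    return records


def write_behaviour_csv(records: list[BehaviourRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "age_group": r.age_group,
            "municipality": r.municipality,
            "timestamp": w.timestamp.isoformat() + "+09:00",
            "lat": w.lat,
            "lon": w.lon,
            "activity": w.activity,
        }
        for r in records
        for w in r.moves
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
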