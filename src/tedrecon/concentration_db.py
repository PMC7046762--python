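"""Spatiotemporal radioiodine concentration table at landmark x 6-hour-segment resolution.

The exposure model discretizes 12-25 March 2011 (JST) into 56 six-hour
segments (6-HS): AM1 [00:00,06:00), AM2 [06:00,12:00), PM1 [12:00,18:00),
PM2 [18:00,24:00) of each day.  Air concentrations of the three chemical
forms of iodine-131 (particulate, elemental vapour, methyl iodide) are
tabulated at fixed georeferenced landmarks; exposures are looked up at the
nearest landmark by great-circle distance.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BLOCKS = ("AM1", "AM2", "PM1", "PM2")
FORMS = ("particulate", "elemental", "methyl")

#: first and last dosed calendar dates (JST)
WINDOW_START = dt.date(2011, 3, 12)
WINDOW_END = dt.date(2011, 3, 25)
N_DAYS = (WINDOW_END - WINDOW_START).days + 1
N_SEGMENTS = N_DAYS * len(BLOCKS)  # 56

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True, order=True)
class SegmentIndex:
    """One 6-hour segment of the dosing window, e.g. 12 March AM1."""

    date: dt.date
    block: str

    def __post_init__(self) -> None:
        if self.block not in BLOCKS:
            raise ValueError(f"unknown block {self.block!r}; expected one of {BLOCKS}")
        if not WINDOW_START <= self.date <= WINDOW_END:
            raise ValueError(f"date {self.date} outside dosing window 12-25 March 2011")

    @property
    def ordinal(self) -> int:
        """1-based position in the 56-segment timeline."""
        return 4 * (self.date - WINDOW_START).days + BLOCKS.index(self.block) + 1

    @classmethod
    def from_ordinal(cls, ordinal: int) -> "SegmentIndex":
        if not 1 <= ordinal <= N_SEGMENTS:
            raise ValueError(f"ordinal {ordinal} outside 1..{N_SEGMENTS}")
        day, block = divmod(ordinal - 1, 4)
        return cls(WINDOW_START + dt.timedelta(days=day), BLOCKS[block])

    @classmethod
    def from_datetime(cls, t: dt.datetime) -> "SegmentIndex":
        """Segment containing a JST timestamp (segment boundaries half-open)."""
        return cls(t.date(), BLOCKS[t.hour // 6])


def all_segments() -> list[SegmentIndex]:
    return [SegmentIndex.from_ordinal(i) for i in range(1, N_SEGMENTS + 1)]


@dataclass(frozen=True)
class Landmark:
    id: str
    lat: float
    lon: float
    label: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6371 km.

    Accepts scalars or numpy arrays (broadcasting).
    """
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def hourly_to_segment_average(hourly) -> float:
    """Arithmetic mean of the 6 hourly concentrations of one segment.

    Segment averages are used instead of hourly values to damp the
    dispersion model's uncertainty in plume arrival time.
    """
    arr = np.asarray(hourly, dtype=float)
    if arr.shape != (6,):
        raise ValueError(f"expected exactly 6 hourly values, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("negative concentration in hourly values")
    return float(arr.mean())


class ConcentrationTable:
    """Complete landmark x segment x form table of Bq/m3 air concentrations.

    Internally a dense array of shape (n_landmarks, 56, 3); every cell must
    be present and non-negative at construction.
    """

    def __init__(self, landmarks: list[Landmark], values: np.ndarray):
        ids = [lm.id for lm in landmarks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate landmark ids")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(landmarks), N_SEGMENTS, len(FORMS)):
            raise ValueError(
                f"values shape {values.shape} != ({len(landmarks)}, {N_SEGMENTS}, {len(FORMS)})"
            )
        if np.any(~np.isfinite(values)):
            raise ValueError("non-finite concentration")
        if np.any(values < 0):
            raise ValueError("negative concentration")
        self.landmarks = list(landmarks)
        self.values = values
        self._index = {lm.id: k for k, lm in enumerate(self.landmarks)}
        self._lats = np.array([lm.lat for lm in self.landmarks])
        self._lons = np.array([lm.lon for lm in self.landmarks])

    def __len__(self) -> int:
        return len(self.landmarks)

    def landmark(self, landmark_id: str) -> Landmark:
        return self.landmarks[self._index[landmark_id]]

    def concentration(self, landmark_id: str, ordinal: int, form: str) -> float:
        return float(self.values[self._index[landmark_id], ordinal - 1, FORMS.index(form)])

    def segment_concentrations(self, landmark_id: str, ordinal: int) -> np.ndarray:
        """All three form concentrations of one landmark/segment, in FORMS order."""
        return self.values[self._index[landmark_id], ordinal - 1, :].copy()

    def nearest_landmark(self, lat: float, lon: float) -> Landmark:
        """Landmark minimizing haversine distance; ties go to the smallest id."""
        if not self.landmarks:
            raise ValueError("empty concentration table")
        d = haversine_km(lat, lon, self._lats, self._lons)
        best = np.flatnonzero(d == d.min())
        if len(best) > 1:
            best = sorted(best, key=lambda k: self.landmarks[k].id)
        return self.landmarks[int(best[0])]

    def to_frame(self, dialect: str = "long") -> pd.DataFrame:
        """Export as the long or wide CSV dialect."""
        rows = []
        for k, lm in enumerate(self.landmarks):
            for seg in all_segments():
                base = {
                    "landmark_id": lm.id,
                    "lat": lm.lat,
                    "lon": lm.lon,
                    "date": seg.date.isoformat(),
                    "block": seg.block,
                }
                if dialect == "long":
                    for f, form in enumerate(FORMS):
                        rows.append(
                            base | {"form": form, "conc_bq_m3": self.values[k, seg.ordinal - 1, f]}
                        )
                elif dialect == "wide":
                    rows.append(
                        base
                        | {
                            f"conc_{form}": self.values[k, seg.ordinal - 1, f]
                            for f, form in enumerate(FORMS)
                        }
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
        return pd.DataFrame(rows)

    def write_csv(self, path, dialect: str = "long") -> None:
        # %.17g round-trips float64 exactly
        self.to_frame(dialect).to_csv(path, index=False, float_format="%.17g")


def _table_from_long(df: pd.DataFrame) -> ConcentrationTable:
    required = {"landmark_id", "lat", "lon", "date", "block", "form", "conc_bq_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"long concentration CSV missing columns {sorted(missing)}")
    bad_form = set(df["form"]) - set(FORMS)
    if bad_form:
        raise ValueError(f"unknown chemical forms {sorted(bad_form)}")
    landmarks = []
    for lid, g in df.groupby("landmark_id", sort=True):
        lats, lons = g["lat"].unique(), g["lon"].unique()
        if len(lats) > 1 or len(lons) > 1:
            raise ValueError(f"landmark {lid} has inconsistent coordinates")
        landmarks.append(Landmark(str(lid), float(lats[0]), float(lons[0])))
    values = np.full((len(landmarks), N_SEGMENTS, len(FORMS)), np.nan)
    lm_index = {lm.id: k for k, lm in enumerate(landmarks)}
    dates = pd.to_datetime(df["date"]).dt.date
    for (lid, date, block, form), conc in zip(
        zip(df["landmark_id"].astype(str), dates, df["block"], df["form"]),
        df["conc_bq_m3"].astype(float),
    ):
        seg = SegmentIndex(date, block)
        values[lm_index[lid], seg.ordinal - 1, FORMS.index(form)] = conc
    _check_complete(landmarks, values)
    return ConcentrationTable(landmarks, values)


def _table_from_wide(df: pd.DataFrame) -> ConcentrationTable:
    required = {"landmark_id", "lat", "lon", "date", "block"} | {f"conc_{f}" for f in FORMS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"wide concentration CSV missing columns {sorted(missing)}")
    long_rows = df.melt(
        id_vars=["landmark_id", "lat", "lon", "date", "block"],
        value_vars=[f"conc_{f}" for f in FORMS],
        var_name="form",
        value_name="conc_bq_m3",
    )
    long_rows["form"] = long_rows["form"].str.removeprefix("conc_")
    return _table_from_long(long_rows)


def _check_complete(landmarks, values) -> None:
    gaps = np.argwhere(np.isnan(values))
    if len(gaps):
        k, s, f = gaps[0]
        seg = SegmentIndex.from_ordinal(int(s) + 1)
        raise ValueError(
            f"incomplete concentration table: landmark {landmarks[int(k)].id}, "
            f"segment {seg.date} {seg.block}, form {FORMS[int(f)]} missing "
            f"({len(gaps)} gaps in total)"
        )


def load_concentration_table(path, dialect: str | None = None,
                             hourly: bool = False) -> ConcentrationTable:
    """Load a concentration table CSV (long or wide dialect).

    With ``hourly=True`` the long dialect carries a ``timestamp`` column of
    hourly values instead of date/block, and each segment's value is the
    mean of its 6 hourly entries.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if hourly:
        df = _hourly_to_segments(df)
    if dialect is None:
        dialect = "wide" if "conc_particulate" in df.columns else "long"
    if dialect == "long":
        return _table_from_long(df)
    if dialect == "wide":
        return _table_from_wide(df)
    raise ValueError(f"unknown dialect {dialect!r}")


def _hourly_to_segments(df: pd.DataFrame) -> pd.DataFrame:
    required = {"landmark_id", "lat", "lon", "timestamp", "form", "conc_bq_m3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"hourly concentration CSV missing columns {sorted(missing)}")
    ts = pd.to_datetime(df["timestamp"])
    work = df.assign(date=ts.dt.date.astype(str), block=[BLOCKS[h // 6] for h in ts.dt.hour])
    grouped = (
        work.groupby(["landmark_id", "lat", "lon", "date", "block", "form"], sort=False)
        .agg(conc_bq_m3=("conc_bq_m3", "mean"), n_hours=("conc_bq_m3", "size"))
        .reset_index()
    )
    short = grouped[grouped["n_hours"] != 6]
    if len(short):
        r = short.iloc[0]
        raise ValueError(
            f"segment {r['date']} {r['block']} of landmark {r['landmark_id']} has "
            f"{r['n_hours']} hourly values, expected 6"
        )
    return grouped.drop(columns="n_hours")
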