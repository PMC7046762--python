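"""Synthetic concentration tables, behaviour cohorts, and tap-water series.

Every stage of the reconstruction is testable without restricted survey
data or the dispersion-model database: this module emits inputs in exactly
the pipeline's CSV dialects, built from plume episodes and evacuation
archetypes with known closed-form doses.

A plume episode deposits, in a few six-hour segments, a concentration
footprint with exponential decay along the transport bearing and a Gaussian
cross-track profile — the simplest shape reproducing the sharp spatial
gradients between nearby landmarks seen in dispersion-model output; it is
not a physical dispersion model.  Total concentration is split 50/20/30
into particulate/elemental/methyl forms, matching the source-term
assumption behind the dispersion database.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .behaviour import BehaviourRecord, Waypoint
from .concentration_db import (
    FORMS,
    N_SEGMENTS,
    ConcentrationTable,
    Landmark,
    SegmentIndex,
    haversine_km,
)
from .dosimetry import (
    SV_TO_MSV,
    CorrectionFactorModel,
    DoseCoefficientSet,
    TapWaterExposure,
    VentilationTable,
)

KM_PER_DEG = np.pi / 180.0 * 6371.0  # meridian km per degree latitude

DEFAULT_FORM_SPLIT = (0.5, 0.2, 0.3)  # particulate, elemental, methyl


@dataclass(frozen=True)
class PlumeEpisode:
    """One release episode confined to a few six-hour segments."""

    ordinals: tuple[int, ...]  # affected segments, 1..56
    source_lat: float
    source_lon: float
    bearing_deg: float  # transport direction, clockwise from north
    peak_bq_m3: float  # total over the three forms, at the source on-axis
    decay_km: float  # along-track e-folding length
    width_km: float  # cross-track Gaussian scale
    form_split: tuple[float, float, float] = DEFAULT_FORM_SPLIT

    def __post_init__(self) -> None:
        if self.peak_bq_m3 <= 0 or self.decay_km <= 0 or self.width_km <= 0:
            raise ValueError("peak, decay length and width must be positive")
        if abs(sum(self.form_split) - 1.0) > 1e-12:
            raise ValueError("form split must sum to 1")
        for o in self.ordinals:
            if not 1 <= o <= N_SEGMENTS:
                raise ValueError(f"ordinal {o} outside 1..{N_SEGMENTS}")

    def total_concentration(self, lat: float, lon: float) -> float:
        """Footprint value (all forms summed) at a point, 0 upwind of the source."""
        dn = (lat - self.source_lat) * KM_PER_DEG
        de = (lon - self.source_lon) * KM_PER_DEG * np.cos(np.radians(self.source_lat))
        theta = np.radians(self.bearing_deg)
        along = de * np.sin(theta) + dn * np.cos(theta)
        cross = de * np.cos(theta) - dn * np.sin(theta)
        if along < 0:
            return 0.0
        return float(
            self.peak_bq_m3 * np.exp(-along / self.decay_km) * np.exp(-((cross / self.width_km) ** 2))
        )

    def concentration(self, lat: float, lon: float, ordinal: int) -> np.ndarray:
        """Per-form concentrations at a point in one segment (zeros off-episode)."""
        if ordinal not in self.ordinals:
            return np.zeros(len(FORMS))
        return self.total_concentration(lat, lon) * np.asarray(self.form_split)


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon landmark grid; default 12 x 13 = 156 landmarks."""

    n_lat: int = 12
    n_lon: int = 13
    lat_min: float = 36.9
    lat_max: float = 37.9
    lon_min: float = 140.5
    lon_max: float = 141.1

    def landmarks(self) -> list[Landmark]:
        lats = np.linspace(self.lat_min, self.lat_max, self.n_lat)
        lons = np.linspace(self.lon_min, self.lon_max, self.n_lon)
        out = []
        k = 0
        for lat in lats:
            for lon in lons:
                k += 1
                out.append(Landmark(f"LM{k:03d}", float(lat), float(lon)))
        return out


def gen_concentration_table(
    episodes: list[PlumeEpisode],
    grid: GridSpec = GridSpec(),
    seed: int = 0,
) -> ConcentrationTable:
    """Deterministic landmark x segment x form table from plume footprints.

    ``seed`` is accepted for interface uniformity; the footprint itself is
    deterministic in the episode parameters.
    """
    landmarks = grid.landmarks()
    values = np.zeros((len(landmarks), N_SEGMENTS, len(FORMS)))
    for ep in episodes:
        for k, lm in enumerate(landmarks):
            total = ep.total_concentration(lm.lat, lm.lon)
            if total > 0:
                contribution = total * np.asarray(ep.form_split)
                for o in ep.ordinals:
                    values[k, o - 1, :] += contribution
    return ConcentrationTable(landmarks, values)


@dataclass(frozen=True)
class ScenarioArchetype:
    """A canonical evacuation trajectory shared by a block of subjects.

    Waypoints must start at 11 March 00:00 and sit on six-hour block
    boundaries so that each block has a single unambiguous location — that
    is what makes the archetype's dose available in closed form.
    """

    name: str
    schedule: tuple[tuple[dt.datetime, float, float], ...]
    count: int = 25
    age_group: str = "1y"
    municipality: str = "SYN"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not self.schedule:
            raise ValueError("empty schedule")
        t0 = self.schedule[0][0]
        if (t0.date(), t0.hour) != (dt.date(2011, 3, 11), 0):
            raise ValueError("schedule must start at 11 March 2011 00:00")
        for t, _, _ in self.schedule:
            if t.hour % 6 != 0 or t.minute or t.second:
                raise ValueError("waypoints must sit on six-hour block boundaries")

    def block_positions(self) -> np.ndarray:
        """(56, 2) lat/lon occupied in each dosed segment (closed form)."""
        out = np.empty((N_SEGMENTS, 2))
        for i in range(N_SEGMENTS):
            seg = SegmentIndex.from_ordinal(i + 1)
            start = dt.datetime.combine(seg.date, dt.time(("AM1", "AM2", "PM1", "PM2").index(seg.block) * 6))
            pos = self.schedule[0][1:]
            for t, lat, lon in self.schedule:
                if t <= start:
                    pos = (lat, lon)
            out[i] = pos
        return out


def _default_archetypes() -> list[ScenarioArchetype]:
    """Four archetypes mirroring the canonical evacuation patterns:

    shelter-in-place near the source, northbound into the first plume,
    southbound with repeat urban exposure, and early evacuation westward
    out of every footprint.
    """
    d = dt.datetime
    home = (37.42, 141.02)
    north = (37.70, 141.00)
    south = (37.05, 140.90)
    far_west = (37.45, 140.52)
    return [
        ScenarioArchetype(
            "shelter_in_place",
            ((d(2011, 3, 11, 0), *home),),
            count=30,
        ),
        ScenarioArchetype(
            "northbound_into_plume",
            (
                (d(2011, 3, 11, 0), *home),
                (d(2011, 3, 12, 12), *north),  # moves north as P1 passes
                (d(2011, 3, 14, 0), *far_west),
            ),
            count=25,
        ),
        ScenarioArchetype(
            "southern_repeat_exposure",
            (
                (d(2011, 3, 11, 0), *home),
                (d(2011, 3, 12, 6), *south),  # exposed to the southbound plumes
                (d(2011, 3, 17, 0), *far_west),
            ),
            count=25,
        ),
        ScenarioArchetype(
            "early_evacuee",
            (
                (d(2011, 3, 11, 0), *home),
                (d(2011, 3, 12, 0), *far_west),
            ),
            count=20,
        ),
    ]


def default_episodes() -> list[PlumeEpisode]:
    """Three plume episodes echoing the early northbound plume (12 March
    afternoon/evening), the southbound morning plume (15 March) and the
    north-westerly evening plume (15 March)."""
    src = (37.42, 141.03)
    return [
        PlumeEpisode((3, 4), *src, bearing_deg=0.0, peak_bq_m3=8000.0,
                     decay_km=40.0, width_km=8.0),
        PlumeEpisode((14,), *src, bearing_deg=185.0, peak_bq_m3=5000.0,
                     decay_km=60.0, width_km=10.0),
        PlumeEpisode((16,), *src, bearing_deg=315.0, peak_bq_m3=3000.0,
                     decay_km=50.0, width_km=7.0),
    ]


def gen_cohort(
    archetypes: list[ScenarioArchetype] | None = None,
    seed: int = 0,
    jitter_km: float = 0.5,
) -> tuple[list[BehaviourRecord], dict[str, str]]:
    """Behaviour records jittered around archetype trajectories.

    Each subject's waypoints get an independent isotropic lat/lon offset of
    scale ``jitter_km`` per waypoint.  Returns the records and a
    subject -> archetype-name map (the clustering ground truth).
    """
    if archetypes is None:
        archetypes = _default_archetypes()
    rng = np.random.default_rng(seed)
    records, membership = [], {}
    sid = 0
    for arch in archetypes:
        for _ in range(arch.count):
            sid += 1
            subject = f"S{sid:04d}"
            moves = []
            for t, lat, lon in arch.schedule:
                dlat = rng.normal(0.0, jitter_km) / KM_PER_DEG
                dlon = rng.normal(0.0, jitter_km) / (KM_PER_DEG * np.cos(np.radians(lat)))
                moves.append(Waypoint(t, lat + dlat, lon + dlon, "indoor"))
            records.append(BehaviourRecord(subject, arch.age_group, arch.municipality, moves))
            membership[subject] = arch.name
    return records, membership


def analytic_inhalation_doses(
    records: list[BehaviourRecord],
    episodes: list[PlumeEpisode],
    landmarks: list[Landmark],
    vent: VentilationTable,
    coeffs: DoseCoefficientSet,
    cf: CorrectionFactorModel,
) -> dict[str, float]:
    """Closed-form ground-truth iodine-131 inhalation doses (mSv, before SF).

    Independent of the pipeline path: per-block location is resolved
    directly from the waypoint schedule (which must sit on block
    boundaries), the nearest landmark by an explicit all-pairs scan, and
    the concentration from the plume footprint formula rather than a
    stored table.
    """
    doses = {}
    for rec in records:
        v4 = vent.volume(rec.age_group) / 4.0
        e = [coeffs.inhal(rec.age_group, form) for form in FORMS]
        total = 0.0
        for i in range(N_SEGMENTS):
            seg = SegmentIndex.from_ordinal(i + 1)
            start = dt.datetime.combine(
                seg.date, dt.time(("AM1", "AM2", "PM1", "PM2").index(seg.block) * 6)
            )
            pos = None
            for wp in rec.moves:
                if wp.timestamp <= start:
                    pos = (wp.lat, wp.lon)
            if pos is None:
                pos = (rec.moves[0].lat, rec.moves[0].lon)
            best, best_d = None, np.inf
            for lm in landmarks:  # brute-force nearest
                dist = float(haversine_km(pos[0], pos[1], lm.lat, lm.lon))
                if dist < best_d or (dist == best_d and lm.id < best.id):
                    best, best_d = lm, dist
            term = 0.0
            for f in range(len(FORMS)):
                c = 0.0
                for ep in episodes:
                    if i + 1 in ep.ordinals:
                        c += ep.total_concentration(best.lat, best.lon) * ep.form_split[f]
                term += c * e[f]
            total += v4 * term * cf.fc_central * cf.df_shelter_central * SV_TO_MSV
        doses[rec.subject_id] = total
    return doses


def gen_tapwater(
    peak_bq_l: float,
    half_life_days: float = 8.02,
    source_id: str = "TWPP-A",
    peak_day: int = 1,
    meals: np.ndarray | None = None,
    seed: int = 0,
) -> TapWaterExposure:
    """Exponentially decaying 14-day tap-water series (days 1..14 = 12-25 March).

    Zero before ``peak_day``, then ``peak * 2**(-(j - peak_day)/half_life)``.
    """
    if peak_bq_l < 0:
        raise ValueError("peak must be >= 0")
    days = np.arange(1, 15)
    c = np.where(days >= peak_day, peak_bq_l * 2.0 ** (-(days - peak_day) / half_life_days), 0.0)
    if meals is None:
        meals = np.full(14, 3)
    return TapWaterExposure(source_id, c, np.asarray(meals))
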