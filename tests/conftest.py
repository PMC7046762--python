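import datetime as dt

import numpy as np
import pytest

from tedrecon.behaviour import BehaviourRecord, Waypoint
from tedrecon.concentration_db import ConcentrationTable, Landmark, N_SEGMENTS
from tedrecon.dosimetry import (
    CorrectionFactorModel,
    DoseCoefficientSet,
    VentilationTable,
)


@pytest.fixture
def round_vent():
    """Round synthetic ventilation volumes (m3/day)."""
    return VentilationTable({"1y": 5.0, "5y": 8.0, "10y": 16.0, "adult": 20.0})


@pytest.fixture
def round_coeffs():
    """Round synthetic thyroid dose coefficients (Sv/Bq)."""
    inhal = {}
    for age, base in [("1y", 1e-6), ("5y", 5e-7), ("10y", 2.5e-7), ("adult", 1e-7)]:
        inhal[(age, "particulate")] = base
        inhal[(age, "elemental")] = 2 * base
        inhal[(age, "methyl")] = 1.5 * base
    ing = {"1y": 2e-6, "5y": 1e-6, "10y": 5e-7, "adult": 2e-7}
    return DoseCoefficientSet(inhal, ing)


@pytest.fixture
def cf():
    return CorrectionFactorModel()


def make_table(landmarks, fill=0.0):
    values = np.full((len(landmarks), N_SEGMENTS, 3), float(fill))
    return ConcentrationTable(landmarks, values)


@pytest.fixture
def two_landmark_table():
    """Two landmarks ~22 km apart, all concentrations zero."""
    return make_table([Landmark("A", 37.0, 141.0), Landmark("B", 37.2, 141.0)])


def stationary_record(subject_id="S1", lat=37.0, lon=141.0, age_group="1y",
                      municipality="M"):
    return BehaviourRecord(
        subject_id,
        age_group,
        municipality,
        [Waypoint(dt.datetime(2011, 3, 11, 0), lat, lon, "indoor")],
    )


@pytest.fixture
def stationary():
    return stationary_record()
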