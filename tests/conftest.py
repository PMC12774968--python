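from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from volecmr.capture_data import EncounterData, StudyDesign

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_design() -> StudyDesign:
    """Two sessions of two trapping days, 61 days apart."""
    return StudyDesign(
        session_labels=("S1", "S2"),
        session_start_dates=(date(2005, 9, 1), date(2005, 11, 1)),
        occasions_per_session=(2, 2),
        treatment_start_session=2,
    )


@pytest.fixture
def four_vole_data(tiny_design) -> EncounterData:
    """Hand-built 4-individual dataset used for hand-enumerated checks.

    A: caught day 1+2 of session 1 and day 1 of session 2 (control).
    B: caught day 2 of session 1 only (control).
    C: caught both days of session 2 (control).
    D: caught day 1 of session 1 only (treatment plot).
    """
    enc = np.array(
        [
            [1, 1, 1, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=np.int8,
    )
    mass = np.array(
        [
            [22.0, 24.0, ],
            [30.0, np.nan],
            [np.nan, 18.5],
            [25.5, np.nan],
        ]
    )
    return EncounterData(
        design=tiny_design,
        ids=["A", "B", "C", "D"],
        sex=np.array(["F", "M", "F", "M"]),
        location=np.array(["Barwik"] * 4, dtype="U32"),
        plot_role=np.array(["control", "control", "control", "treatment"], dtype="U16"),
        cohort=np.array(["c1"] * 4, dtype="U32"),
        encounters=enc,
        observed_mass=mass,
    )
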