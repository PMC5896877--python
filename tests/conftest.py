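import numpy as np
import pandas as pd
import pytest

from icmsmap import SimulationConfig, simulate_exp1, simulate_exp2
from icmsmap.types import SESSION_COLUMNS, SessionData


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=0)


@pytest.fixture(scope="session")
def exp1_sessions(default_config):
    """Full default amplitude-mapping simulation (96 electrodes, 8
    amplitudes x 3 reps, ~10% catch trials)."""
    return simulate_exp1(default_config)


@pytest.fixture(scope="session")
def exp2_sessions(default_config):
    """Default amplitude x frequency simulation (5 electrodes, 3 days)."""
    return simulate_exp2(default_config)


def make_sessions(rows):
    """Build SessionData from a list of partial row dicts, filling the
    remaining schema columns with sensible defaults."""
    filled = []
    for i, r in enumerate(rows):
        base = {
            "experiment": "exp1", "session_day": 1, "block": 1,
            "trial_index": i, "electrode_id": 1, "array": "medial",
            "row": 0, "col": 0, "amplitude_uA": 60.0, "frequency_hz": 150.0,
            "pulse_width_us": 200.0, "interphase_us": 53.0, "duration_s": 1.0,
            "is_catch": False, "detected": False, "modality": None,
            "descriptor": None, "region": None, "plane": None,
            "grid_cell": None, "intensity": None, "duration_category": None,
            "impedance_kohm": 50.0,
        }
        base.update(r)
        filled.append(base)
    return SessionData(pd.DataFrame(filled, columns=SESSION_COLUMNS))


@pytest.fixture
def make_session_rows():
    return make_sessions
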