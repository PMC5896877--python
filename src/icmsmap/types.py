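"""Core domain types and protocol constants for percept-mapping experiments.

The experiment stimulates single electrodes on two 7x7 microelectrode arrays
(48 physically-connected sites each) implanted in primary somatosensory
cortex, and records the subject's report for every trial: whether a sensation
was detected and, if so, its modality (cutaneous or proprioceptive), a
single-word descriptor, the receptive-field location on a body grid, a 1-10
intensity rating and a short/medium/long duration category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

# ---------------------------------------------------------------------------
# Protocol constants
# ---------------------------------------------------------------------------

#: Amplitudes (µA) used in the single-frequency mapping experiment.
EXP1_AMPLITUDES_UA = (20.0, 30.0, 40.0, 60.0, 70.0, 80.0, 90.0, 100.0)
#: Fixed pulse frequency (Hz) of the single-frequency mapping experiment.
EXP1_FREQUENCY_HZ = 150.0
#: Amplitudes (µA) of the amplitude x frequency mapping experiment.
EXP2_AMPLITUDES_UA = (20.0, 40.0, 60.0, 80.0, 100.0)
#: Pulse frequencies (Hz) of the amplitude x frequency mapping experiment.
EXP2_FREQUENCIES_HZ = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0)

PULSE_WIDTH_US = 200.0
INTERPHASE_US = 53.0
TRAIN_DURATION_S = 1.0
#: Safety ceiling on charge delivered in one pulse phase (nanocoulomb).
MAX_CHARGE_NC = 20.0

GRID_SIZE = 7
CONNECTED_PER_ARRAY = 48
ARRAYS = ("medial", "lateral")

CUTANEOUS = "cutaneous"
PROPRIOCEPTIVE = "proprioceptive"
MODALITIES = (CUTANEOUS, PROPRIOCEPTIVE)

REGIONS = ("upper_arm", "forearm", "hand")
PLANES = ("anterior", "posterior")
DURATION_CATEGORIES = ("short", "medium", "long")

#: Fixed descriptor -> modality map.  ``other`` is a catch-all consistent
#: with either modality.  Overridable through SimulationConfig.
DESCRIPTOR_MODALITY = {
    "squeeze": CUTANEOUS,
    "tap": CUTANEOUS,
    "vibration": CUTANEOUS,
    "blowing": CUTANEOUS,
    "pinch": CUTANEOUS,
    "press": CUTANEOUS,
    "goosebumps": CUTANEOUS,
    "right_movement": PROPRIOCEPTIVE,
    "forward_movement": PROPRIOCEPTIVE,
    "upward_movement": PROPRIOCEPTIVE,
    "other": None,
}


def descriptor_matches_modality(descriptor: str, modality: str,
                                mapping: Optional[dict] = None) -> bool:
    """True if *descriptor* is consistent with *modality* under *mapping*
    (``None``-mapped descriptors match any modality)."""
    mapping = DESCRIPTOR_MODALITY if mapping is None else mapping
    expected = mapping.get(descriptor, None)
    return expected is None or expected == modality


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimParams:
    """Electrical parameters of one biphasic, charge-balanced,
    cathodic-leading stimulus train."""

    amplitude_uA: float
    frequency_hz: float = EXP1_FREQUENCY_HZ
    pulse_width_us: float = PULSE_WIDTH_US
    interphase_us: float = INTERPHASE_US
    train_duration_s: float = TRAIN_DURATION_S


@dataclass(frozen=True)
class Trial:
    """One scheduled stimulation (or catch) with its position in the session.

    Catch trials present the full trial cueing but deliver no current; their
    electrode and stimulus fields are absent.
    """

    experiment: str  # "exp1" | "exp2"
    session_day: int
    block: int
    order_index: int
    electrode_id: Optional[int]
    stim: Optional[StimParams]
    is_catch: bool


@dataclass(frozen=True)
class Response:
    """The subject-report record attached to one trial."""

    detected: bool
    modality: Optional[str] = None      # cutaneous | proprioceptive
    descriptor: Optional[str] = None
    region: Optional[str] = None        # upper_arm | forearm | hand
    plane: Optional[str] = None         # anterior | posterior
    grid_cell: Optional[str] = None
    intensity: Optional[int] = None     # 1..10
    duration: Optional[str] = None      # short | medium | long

    def __post_init__(self):
        if not self.detected:
            if any(v is not None for v in (self.modality, self.descriptor,
                                           self.region, self.plane,
                                           self.grid_cell, self.intensity,
                                           self.duration)):
                raise ValidationError(
                    "undetected response must carry no report fields")
        else:
            if self.modality not in MODALITIES:
                raise ValidationError(
                    f"detected response needs a modality, got {self.modality!r}")
            if self.intensity is not None and not 1 <= int(self.intensity) <= 10:
                raise ValidationError(
                    f"intensity must be in 1..10, got {self.intensity}")
            if self.descriptor is not None and not descriptor_matches_modality(
                    self.descriptor, self.modality):
                raise ValidationError(
                    f"descriptor {self.descriptor!r} inconsistent with "
                    f"modality {self.modality!r}")


@dataclass
class ElectrodeProfile:
    """An electrode's geometry, impedance and generative response parameters.

    The generative fields parameterise the simulator: detection probability
    is linear in amplitude (``p_detect_base + detect_amp_slope * A``, clipped
    to [0, 1]) and, given detection, the probability that the percept is
    proprioceptive is ``logistic(modality_beta0 + modality_beta1 * A)``.
    ``region_weights`` are categorical weights over the six
    (region, plane) receptive-field cells.
    """

    electrode_id: int
    array: str                      # medial | lateral
    row: int
    col: int
    connected: bool
    impedance_kohm: float
    responsive: bool
    p_detect_base: float
    detect_amp_slope: float
    modality_beta0: float
    modality_beta1: float
    region_weights: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Session table
# ---------------------------------------------------------------------------

#: Fixed, ordered column set of the session CSV schema.
SESSION_COLUMNS = (
    "experiment", "session_day", "block", "trial_index",
    "electrode_id", "array", "row", "col",
    "amplitude_uA", "frequency_hz", "pulse_width_us", "interphase_us",
    "duration_s", "is_catch", "detected",
    "modality", "descriptor", "region", "plane", "grid_cell",
    "intensity", "duration_category", "impedance_kohm",
)

#: Column kinds used for parsing/formatting ("int" columns are nullable).
SESSION_COLUMN_KINDS = {
    "experiment": "str", "session_day": "int", "block": "int",
    "trial_index": "int", "electrode_id": "int", "array": "str",
    "row": "int", "col": "int", "amplitude_uA": "float",
    "frequency_hz": "float", "pulse_width_us": "float",
    "interphase_us": "float", "duration_s": "float",
    "is_catch": "bool", "detected": "bool", "modality": "str",
    "descriptor": "str", "region": "str", "plane": "str",
    "grid_cell": "str", "intensity": "int", "duration_category": "str",
    "impedance_kohm": "float",
}


def canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a session frame to canonical dtypes (nullable Int64 integers,
    float64 reals, plain bools, object strings with pd.NA for missing)."""
    out = pd.DataFrame(index=df.index)
    for col in SESSION_COLUMNS:
        kind = SESSION_COLUMN_KINDS[col]
        s = df[col] if col in df.columns else pd.Series(pd.NA, index=df.index)
        if kind == "int":
            out[col] = pd.array(pd.to_numeric(s, errors="coerce"),
                                dtype="Int64")
        elif kind == "float":
            out[col] = pd.to_numeric(s, errors="coerce").astype("float64")
        elif kind == "bool":
            out[col] = s.astype(bool)
        else:
            vals = s.astype("object").where(~pd.isna(s), pd.NA)
            vals = vals.where(vals != "", pd.NA)
            out[col] = vals
    return out


@dataclass
class SessionData:
    """A set of per-trial records (one row per trial, responses attached),
    with per-session electrode impedance snapshots embedded on stimulation
    rows."""

    table: pd.DataFrame

    def __post_init__(self):
        self.table = canonicalize_frame(self.table)

    # -- convenience views --------------------------------------------------

    @property
    def n_trials(self) -> int:
        return len(self.table)

    @property
    def non_catch(self) -> pd.DataFrame:
        return self.table[~self.table["is_catch"]]

    @property
    def catch(self) -> pd.DataFrame:
        return self.table[self.table["is_catch"]]

    @property
    def detected(self) -> pd.DataFrame:
        """Rows with a reported sensation (non-catch, detected)."""
        t = self.table
        return t[(~t["is_catch"]) & t["detected"]]

    def impedances(self) -> pd.DataFrame:
        """Per (session_day, electrode_id) impedance snapshot, from stim rows."""
        t = self.non_catch
        snap = (t[["session_day", "electrode_id", "impedance_kohm"]]
                .dropna(subset=["electrode_id"])
                .drop_duplicates(subset=["session_day", "electrode_id"]))
        return snap.reset_index(drop=True)

    def session_days(self):
        return sorted(self.table["session_day"].dropna().unique().tolist())

    def equals(self, other: "SessionData") -> bool:
        return self.table.equals(other.table)
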