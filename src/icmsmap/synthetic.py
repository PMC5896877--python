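"""Generative simulator for percept-mapping sessions.

The simulator replaces the study's raw per-trial spreadsheet with synthetic
sessions that carry the same statistical structure the analyses consume:

* roughly half of the stimulable electrodes ever elicit a sensation;
* detection probability rises weakly and linearly with amplitude;
* given detection, the probability that the percept is proprioceptive
  (rather than cutaneous) is logistic in amplitude, with no frequency term,
  so proprioceptive reports skew toward higher amplitudes;
* reported intensity (integers 1-10) is linear in amplitude with Gaussian
  noise before rounding/clipping (default slope 0.02 a.u./µA, mean ~2.4 at
  20 µA);
* duration categories are drawn with short >> medium >> long weights, with a
  small probability of an unrecorded duration;
* descriptors are drawn from a modality-consistent vocabulary;
* receptive fields are categorical over (region, plane) cells, with
  medial-array electrodes favouring the anterior upper arm and lateral-array
  electrodes the posterior forearm;
* catch trials never yield a detection (zero false positives by
  construction);
* electrode impedances are log-normal and independent of responsiveness.

Randomness flows from a single master seed spawning named, independent
streams (population / schedule / responses / impedance), so the entire
simulation is bit-reproducible for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import design
from .errors import ConfigurationError, ScheduleError
from .types import (ARRAYS, CONNECTED_PER_ARRAY, CUTANEOUS,
                    DESCRIPTOR_MODALITY, DURATION_CATEGORIES,
                    EXP2_AMPLITUDES_UA, EXP2_FREQUENCIES_HZ, GRID_SIZE,
                    PLANES, PROPRIOCEPTIVE, REGIONS, SESSION_COLUMNS,
                    ElectrodeProfile, Response, SessionData, StimParams,
                    Trial)

__all__ = [
    "SimulationConfig", "make_electrode_population", "simulate_response",
    "simulate_experiment", "simulate_exp1", "simulate_exp2",
]

# (region, plane) receptive-field cells
RF_CELLS = tuple((r, p) for r in REGIONS for p in PLANES)

# Array-level receptive-field weights over RF_CELLS: the medial array favours
# the anterior upper arm (modal share 0.46) and the lateral array the
# posterior forearm (modal share 0.51).
DEFAULT_REGION_WEIGHTS = {
    "medial": {
        ("upper_arm", "anterior"): 0.46, ("upper_arm", "posterior"): 0.20,
        ("forearm", "anterior"): 0.12, ("forearm", "posterior"): 0.14,
        ("hand", "anterior"): 0.04, ("hand", "posterior"): 0.04,
    },
    "lateral": {
        ("upper_arm", "anterior"): 0.10, ("upper_arm", "posterior"): 0.14,
        ("forearm", "anterior"): 0.15, ("forearm", "posterior"): 0.51,
        ("hand", "anterior"): 0.05, ("hand", "posterior"): 0.05,
    },
}

# Within-modality descriptor weights (proportional to observed shares of all
# responses; "other" absorbs the unlisted remainder of each modality).
DEFAULT_DESCRIPTOR_WEIGHTS = {
    CUTANEOUS: {
        "squeeze": 24.9, "tap": 17.3, "vibration": 8.1, "blowing": 6.6,
        "pinch": 5.5, "press": 5.0, "goosebumps": 3.1, "other": 8.8,
    },
    PROPRIOCEPTIVE: {
        "right_movement": 9.7, "forward_movement": 5.8,
        "upward_movement": 3.9, "other": 1.3,
    },
}


def _logistic(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


@dataclass
class SimulationConfig:
    """Generative defaults for a synthetic percept-mapping study.

    Intensity model: ``clip(round(intensity_intercept + intensity_slope * A
    + N(0, intensity_noise_sd)), 1, 10)``; the intercept 2.0 places the mean
    near 2.4 at 20 µA and 4.0 at 100 µA with the default slope.
    """

    seed: int = 0
    n_electrodes: int = 2 * CONNECTED_PER_ARRAY
    responsive_fraction: float = 0.48
    # detection: p = clip(p_detect_base + detect_amp_slope * A, 0, 1)
    p_detect_base: float = 0.52
    p_detect_sd: float = 0.15
    detect_amp_slope: float = 0.002
    # modality: P(proprioceptive | detected) = logistic(b0 + b1 * A)
    modality_beta0: float = -2.6
    modality_beta1: float = 0.02
    # intensity (a.u. on the 1-10 scale)
    intensity_intercept: float = 2.0
    intensity_slope: float = 0.02
    intensity_noise_sd: float = 1.8
    # duration categories short/medium/long, plus unrecorded durations
    duration_weights: tuple = (225 / 359, 122 / 359, 12 / 359)
    duration_missing_prob: float = 22 / 381
    descriptor_weights: dict = field(
        default_factory=lambda: {m: dict(w) for m, w in
                                 DEFAULT_DESCRIPTOR_WEIGHTS.items()})
    descriptor_modality: dict = field(
        default_factory=lambda: dict(DESCRIPTOR_MODALITY))
    region_weights: dict = field(
        default_factory=lambda: {a: dict(w) for a, w in
                                 DEFAULT_REGION_WEIGHTS.items()})
    # share of an electrode's responses concentrated on its modal RF cell
    rf_consistency: float = 0.7
    # impedances: log-normal, identical for responsive/non-responsive sites
    impedance_median_kohm: float = 50.0
    impedance_sigma: float = 0.3
    impedance_session_jitter: float = 0.05
    # Experiment-1 block design
    subset_size: int = 8
    reps_per_param: int = 3
    catch_fraction: float = 0.10

    def validate(self) -> None:
        if not 0 <= self.responsive_fraction <= 1:
            raise ConfigurationError("responsive_fraction must be in [0, 1]")
        if not 1 <= self.n_electrodes <= 2 * CONNECTED_PER_ARRAY:
            raise ConfigurationError(
                f"n_electrodes must be in [1, {2 * CONNECTED_PER_ARRAY}]")
        if len(self.duration_weights) != 3 or min(self.duration_weights) < 0:
            raise ConfigurationError("duration_weights must be 3 non-negative values")
        if abs(sum(self.duration_weights) - 1.0) > 1e-9:
            raise ConfigurationError("duration_weights must sum to 1")
        if not 0 <= self.duration_missing_prob < 1:
            raise ConfigurationError("duration_missing_prob must be in [0, 1)")
        if not 0 <= self.rf_consistency <= 1:
            raise ConfigurationError("rf_consistency must be in [0, 1]")
        if self.impedance_median_kohm <= 0:
            raise ConfigurationError("impedance_median_kohm must be positive")
        for arr, w in self.region_weights.items():
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"region_weights[{arr}] must sum to 1")


def rng_streams(seed: int) -> Dict[str, np.random.Generator]:
    """Named independent generators spawned from one master seed."""
    kids = np.random.SeedSequence(seed).spawn(4)
    names = ("population", "schedule", "responses", "impedance")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


# ---------------------------------------------------------------------------
# Electrode population
# ---------------------------------------------------------------------------


def make_electrode_population(config: SimulationConfig,
                              rng: Optional[np.random.Generator] = None
                              ) -> List[ElectrodeProfile]:
    """Generate the stimulable electrode population (default: two 7x7 arrays
    with 48 connected sites each).

    Exactly ``round(responsive_fraction * n)`` electrodes are responsive (the
    default reproduces 46 of 96).  Responsive electrodes get a baseline
    detection probability drawn around ``p_detect_base`` and per-electrode
    receptive-field weights that concentrate ``rf_consistency`` of the mass
    on a modal (region, plane) cell drawn from the array-level weights.
    """
    config.validate()
    rng = rng_streams(config.seed)["population"] if rng is None else rng

    profiles: List[ElectrodeProfile] = []
    eid = 0
    for array in ARRAYS:
        sites = [(r, c) for r in range(GRID_SIZE) for c in range(GRID_SIZE)]
        unconnected = int(rng.integers(len(sites)))
        cells = list(config.region_weights[array].keys())
        base_w = np.array([config.region_weights[array][c] for c in cells])
        for j, (r, c) in enumerate(sites):
            if j == unconnected:
                continue  # 48 of 49 sites per array are physically connected
            eid += 1
            if eid > config.n_electrodes:
                break
            modal = cells[int(rng.choice(len(cells), p=base_w))]
            w = {cell: (1 - config.rf_consistency) * bw
                 for cell, bw in zip(cells, base_w)}
            w[modal] = w[modal] + config.rf_consistency
            impedance = float(rng.lognormal(
                math.log(config.impedance_median_kohm), config.impedance_sigma))
            p_base = float(np.clip(
                rng.normal(config.p_detect_base, config.p_detect_sd),
                0.05, 0.90))
            profiles.append(ElectrodeProfile(
                electrode_id=eid, array=array, row=r, col=c, connected=True,
                impedance_kohm=impedance, responsive=True,
                p_detect_base=p_base,
                detect_amp_slope=config.detect_amp_slope,
                modality_beta0=config.modality_beta0,
                modality_beta1=config.modality_beta1,
                region_weights=w))

    n = len(profiles)
    n_resp = int(math.floor(config.responsive_fraction * n + 0.5))
    responsive_idx = set(rng.choice(n, size=n_resp, replace=False).tolist())
    for i, p in enumerate(profiles):
        if i not in responsive_idx:
            p.responsive = False
            p.p_detect_base = 0.0
            p.detect_amp_slope = 0.0
    return profiles


# ---------------------------------------------------------------------------
# Per-trial response generation
# ---------------------------------------------------------------------------

_NO_RESPONSE = Response(detected=False)


def simulate_response(profile: Optional[ElectrodeProfile],
                      stim: Optional[StimParams],
                      is_catch: bool,
                      rng: np.random.Generator,
                      config: SimulationConfig) -> Response:
    """Draw one subject report for a trial.

    Catch trials and non-responsive electrodes never produce a detection.
    Otherwise detection is Bernoulli with linear-in-amplitude probability;
    given detection the modality, descriptor, receptive field, intensity and
    duration are drawn as described in the module docstring.
    """
    if is_catch or profile is None or not profile.responsive:
        return _NO_RESPONSE
    a = stim.amplitude_uA
    p_detect = min(1.0, max(0.0, profile.p_detect_base
                            + profile.detect_amp_slope * a))
    if rng.random() >= p_detect:
        return _NO_RESPONSE

    p_prop = _logistic(profile.modality_beta0 + profile.modality_beta1 * a)
    modality = PROPRIOCEPTIVE if rng.random() < p_prop else CUTANEOUS

    weights = config.descriptor_weights[modality]
    names = sorted(weights)
    w = np.array([weights[k] for k in names], dtype=float)
    descriptor = names[int(rng.choice(len(names), p=w / w.sum()))]

    cells = sorted(profile.region_weights)
    cw = np.array([profile.region_weights[c] for c in cells], dtype=float)
    region, plane = cells[int(rng.choice(len(cells), p=cw / cw.sum()))]
    grid_cell = f"{region[:2].upper()}{plane[0].upper()}{int(rng.integers(1, 13))}"

    raw = (config.intensity_intercept + config.intensity_slope * a
           + rng.normal(0.0, config.intensity_noise_sd))
    intensity = int(np.clip(math.floor(raw + 0.5), 1, 10))

    if rng.random() < config.duration_missing_prob:
        duration = None
    else:
        duration = DURATION_CATEGORIES[int(rng.choice(
            3, p=np.asarray(config.duration_weights)))]

    return Response(detected=True, modality=modality, descriptor=descriptor,
                    region=region, plane=plane, grid_cell=grid_cell,
                    intensity=intensity, duration=duration)


# ---------------------------------------------------------------------------
# Whole-experiment simulation
# ---------------------------------------------------------------------------


def simulate_experiment(schedule: Sequence[Trial],
                        profiles: Sequence[ElectrodeProfile],
                        config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None,
                        impedance_rng: Optional[np.random.Generator] = None
                        ) -> SessionData:
    """Run a schedule through the generative model, one Response per Trial in
    order, attaching a per-session impedance snapshot to stimulation rows."""
    by_id = {p.electrode_id: p for p in profiles}
    unknown = sorted({t.electrode_id for t in schedule
                      if t.electrode_id is not None and t.electrode_id not in by_id})
    if unknown:
        raise ScheduleError(f"schedule references unknown electrode ids {unknown}")
    if rng is None or impedance_rng is None:
        streams = rng_streams(config.seed)
        rng = streams["responses"] if rng is None else rng
        impedance_rng = (streams["impedance"] if impedance_rng is None
                         else impedance_rng)

    days = sorted({t.session_day for t in schedule})
    snapshot: Dict[tuple, float] = {}
    for day in days:
        for p in sorted(profiles, key=lambda p: p.electrode_id):
            jitter = impedance_rng.lognormal(0.0, config.impedance_session_jitter)
            snapshot[(day, p.electrode_id)] = p.impedance_kohm * float(jitter)

    rows = []
    for t in schedule:
        prof = by_id.get(t.electrode_id) if t.electrode_id is not None else None
        resp = simulate_response(prof, t.stim, t.is_catch, rng, config)
        rows.append({
            "experiment": t.experiment, "session_day": t.session_day,
            "block": t.block, "trial_index": t.order_index,
            "electrode_id": t.electrode_id,
            "array": prof.array if prof else None,
            "row": prof.row if prof else None,
            "col": prof.col if prof else None,
            "amplitude_uA": t.stim.amplitude_uA if t.stim else None,
            "frequency_hz": t.stim.frequency_hz if t.stim else None,
            "pulse_width_us": t.stim.pulse_width_us if t.stim else None,
            "interphase_us": t.stim.interphase_us if t.stim else None,
            "duration_s": t.stim.train_duration_s if t.stim else None,
            "is_catch": t.is_catch, "detected": resp.detected,
            "modality": resp.modality, "descriptor": resp.descriptor,
            "region": resp.region, "plane": resp.plane,
            "grid_cell": resp.grid_cell, "intensity": resp.intensity,
            "duration_category": resp.duration,
            "impedance_kohm": (snapshot[(t.session_day, t.electrode_id)]
                               if t.electrode_id is not None else None),
        })
    df = pd.DataFrame(rows, columns=SESSION_COLUMNS) if rows else \
        pd.DataFrame(columns=SESSION_COLUMNS)
    return SessionData(df)


def simulate_exp1(config: Optional[SimulationConfig] = None) -> SessionData:
    """Population + full amplitude-mapping schedule + responses, from one seed."""
    config = SimulationConfig() if config is None else config
    config.validate()
    streams = rng_streams(config.seed)
    profiles = make_electrode_population(config, rng=streams["population"])
    schedule = design.build_exp1_schedule(
        profiles, subset_size=config.subset_size,
        reps_per_param=config.reps_per_param,
        catch_fraction=config.catch_fraction, rng=streams["schedule"])
    return simulate_experiment(schedule, profiles, config,
                               rng=streams["responses"],
                               impedance_rng=streams["impedance"])


def simulate_exp2(config: Optional[SimulationConfig] = None,
                  n_electrodes: int = 5,
                  days: int = 3,
                  reps_per_day: int = 2,
                  amplitudes: Sequence[float] = EXP2_AMPLITUDES_UA,
                  frequencies: Sequence[float] = EXP2_FREQUENCIES_HZ
                  ) -> SessionData:
    """Amplitude x frequency follow-up on the most reliably responsive
    electrodes (highest baseline detection probability)."""
    config = SimulationConfig() if config is None else config
    config.validate()
    streams = rng_streams(config.seed)
    profiles = make_electrode_population(config, rng=streams["population"])
    responsive = [p for p in profiles if p.responsive]
    if len(responsive) < n_electrodes:
        raise ConfigurationError(
            f"population has only {len(responsive)} responsive electrodes")
    chosen = sorted(responsive, key=lambda p: (-p.p_detect_base, p.electrode_id))
    ids = [p.electrode_id for p in chosen[:n_electrodes]]
    schedule = design.build_exp2_schedule(
        ids, amplitudes=amplitudes, frequencies=frequencies, days=days,
        reps_per_day=reps_per_day, rng=streams["schedule"])
    return simulate_experiment(schedule, profiles, config,
                               rng=streams["responses"],
                               impedance_rng=streams["impedance"])
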