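"""Trial-schedule construction and charge-safety validation.

Two designs are supported:

* Experiment 1 (amplitude mapping): blocks over a random electrode subset,
  three replicates per (electrode, amplitude) pair at a fixed 150 Hz, with
  ~10% randomly interleaved catch trials and the constraint that no two
  consecutive stimulation trials use the same or adjacent electrodes.
* Experiment 2 (amplitude x frequency mapping): five electrodes, each
  (electrode, amplitude, frequency) triple twice per day over three days,
  pseudorandom order, so every triple is tested six times in total.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

from .errors import ChargeSafetyError, ParameterError, ScheduleError
from .types import (EXP1_AMPLITUDES_UA, EXP1_FREQUENCY_HZ, EXP2_AMPLITUDES_UA,
                    EXP2_FREQUENCIES_HZ, MAX_CHARGE_NC, ElectrodeProfile,
                    StimParams, Trial)

__all__ = [
    "charge_per_phase", "validate_stim", "electrode_adjacency",
    "build_exp1_block", "build_exp1_schedule", "build_exp2_schedule",
    "adjacency_violations",
]


def charge_per_phase(stim: StimParams) -> float:
    """Charge delivered in one pulse phase, in nC (µA x µs / 1000)."""
    if stim.amplitude_uA <= 0:
        raise ParameterError(f"amplitude must be positive, got {stim.amplitude_uA}")
    if stim.pulse_width_us <= 0:
        raise ParameterError(f"pulse width must be positive, got {stim.pulse_width_us}")
    return stim.amplitude_uA * stim.pulse_width_us / 1000.0


def validate_stim(stim: StimParams, max_charge_nc: float = MAX_CHARGE_NC) -> float:
    """Validate a stimulus against the per-phase charge ceiling.

    Returns the charge (nC); raises ChargeSafetyError above *max_charge_nc*.
    """
    q = charge_per_phase(stim)
    if q > max_charge_nc * (1 + 1e-12):
        raise ChargeSafetyError(
            f"charge per phase {q:.3f} nC exceeds the {max_charge_nc} nC limit "
            f"(amplitude {stim.amplitude_uA} µA, width {stim.pulse_width_us} µs)")
    return q


def electrode_adjacency(profiles: Iterable[ElectrodeProfile]) -> Dict[int, Set[int]]:
    """8-neighbourhood adjacency between electrodes on the same array.

    Two electrodes are adjacent iff they sit on the same array and their grid
    coordinates differ by at most one in each direction (Chebyshev distance
    1).  The relation is symmetric and irreflexive; sites on different arrays
    are never adjacent.
    """
    profiles = list(profiles)
    adj: Dict[int, Set[int]] = {p.electrode_id: set() for p in profiles}
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            if a.array != b.array:
                continue
            if max(abs(a.row - b.row), abs(a.col - b.col)) == 1:
                adj[a.electrode_id].add(b.electrode_id)
                adj[b.electrode_id].add(a.electrode_id)
    return adj


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _maximal_cliques(ids: List[int],
                     adjacency: Dict[int, Set[int]]) -> List[frozenset]:
    """All cliques of the same/adjacent conflict graph over *ids* (small
    subsets only; enumerated exhaustively).  Singletons excluded."""
    cliques: List[frozenset] = []
    n = len(ids)
    for mask in range(1, 1 << n):
        members = [ids[i] for i in range(n) if mask >> i & 1]
        if len(members) < 2:
            continue
        if all(b in adjacency.get(a, set())
               for i, a in enumerate(members) for b in members[i + 1:]):
            cliques.append(frozenset(members))
    # keep only maximal ones
    return [c for c in cliques
            if not any(c < d for d in cliques)]


def _sequence_without_adjacent(electrode_trial_counts: Dict[int, int],
                               adjacency: Dict[int, Set[int]],
                               rng: np.random.Generator,
                               max_restarts: int) -> List[int]:
    """Order a multiset of electrode labels so that no two consecutive labels
    are equal or adjacent.

    Randomized sequential construction: at each step choose uniformly among
    the eligible electrodes holding the maximum remaining trial count (the
    balanced-scheduling rule, which keeps counts level and makes dead ends
    rare).  Mutually-adjacent electrode cliques act like a single label --
    no two of their trials may be consecutive -- so whenever a clique holds
    at least half of the remaining trials the next trial is forced to come
    from it.  Bounded restarts; deterministic under *rng*.
    """
    ids = sorted(electrode_trial_counts)
    total0 = sum(electrode_trial_counts.values())
    cliques = _maximal_cliques(ids, adjacency) if len(ids) <= 16 else []
    for _ in range(max_restarts):
        remaining = dict(electrode_trial_counts)
        seq: List[int] = []
        prev: Optional[int] = None
        total = total0
        dead = False
        while total > 0:
            blocked = set() if prev is None else ({prev} | adjacency.get(prev, set()))
            eligible = [e for e in ids if remaining[e] > 0 and e not in blocked]
            forced: Optional[frozenset] = None
            for k in cliques:
                if 2 * sum(remaining[e] for e in k) >= total + 1:
                    forced = k
                    break
            if forced is not None:
                eligible = [e for e in eligible if e in forced]
            if not eligible:
                dead = True
                break
            top = max(remaining[e] for e in eligible)
            pool = [e for e in eligible if remaining[e] == top]
            choice = pool[int(rng.integers(len(pool)))]
            seq.append(choice)
            remaining[choice] -= 1
            total -= 1
            prev = choice
        if not dead:
            return seq
    raise ScheduleError(
        f"could not order {total0} trials over {len(ids)} electrodes without "
        f"same/adjacent-electrode repeats after {max_restarts} restarts")


def build_exp1_block(profiles: Sequence[ElectrodeProfile],
                     amplitudes: Sequence[float] = EXP1_AMPLITUDES_UA,
                     reps_per_param: int = 3,
                     catch_fraction: float = 0.10,
                     rng: Optional[np.random.Generator] = None,
                     frequency_hz: float = EXP1_FREQUENCY_HZ,
                     session_day: int = 1,
                     block: int = 1,
                     adjacency: Optional[Dict[int, Set[int]]] = None,
                     max_restarts: int = 10_000) -> List[Trial]:
    """One amplitude-mapping block over an electrode subset.

    Each (electrode, amplitude) pair appears exactly *reps_per_param* times;
    round(catch_fraction x stimulation count) catch trials are interleaved at
    uniformly random positions; no two consecutive stimulation trials use the
    same or adjacent electrodes (catch trials, which deliver no current, are
    exempt and do not break the constraint across them).
    """
    rng = np.random.default_rng(rng)
    profiles = list(profiles)
    if not profiles:
        raise ParameterError("electrode subset must be non-empty")
    if reps_per_param < 1:
        raise ParameterError("reps_per_param must be >= 1")
    if not 0 <= catch_fraction <= 1:
        raise ParameterError("catch_fraction must be in [0, 1]")
    stims = {a: StimParams(amplitude_uA=float(a), frequency_hz=frequency_hz)
             for a in amplitudes}
    for s in stims.values():
        validate_stim(s)

    adjacency = electrode_adjacency(profiles) if adjacency is None else adjacency
    counts = {p.electrode_id: reps_per_param * len(amplitudes) for p in profiles}
    order = _sequence_without_adjacent(counts, adjacency, rng, max_restarts)

    # assign amplitudes: every electrode uses each amplitude reps_per_param
    # times, in per-electrode random order
    amp_pools = {
        p.electrode_id: list(rng.permutation(
            np.repeat(np.asarray(amplitudes, dtype=float), reps_per_param)))
        for p in profiles
    }
    n_stim = len(order)
    n_catch = _round_half_up(catch_fraction * n_stim)
    n_total = n_stim + n_catch
    catch_pos = set(rng.choice(n_total, size=n_catch, replace=False).tolist())

    trials: List[Trial] = []
    it = iter(order)
    for idx in range(n_total):
        if idx in catch_pos:
            trials.append(Trial("exp1", session_day, block, idx,
                                electrode_id=None, stim=None, is_catch=True))
        else:
            e = next(it)
            a = amp_pools[e].pop()
            trials.append(Trial("exp1", session_day, block, idx,
                                electrode_id=e, stim=stims[a], is_catch=False))
    return trials


def build_exp1_schedule(profiles: Sequence[ElectrodeProfile],
                        subset_size: int = 8,
                        amplitudes: Sequence[float] = EXP1_AMPLITUDES_UA,
                        reps_per_param: int = 3,
                        catch_fraction: float = 0.10,
                        rng: Optional[np.random.Generator] = None,
                        max_restarts: int = 10_000) -> List[Trial]:
    """Full amplitude-mapping schedule covering every electrode.

    Electrodes are partitioned into random subsets of *subset_size* (the last
    block may be smaller); each subset forms one block, run as one session.
    """
    rng = np.random.default_rng(rng)
    profiles = list(profiles)
    if subset_size < 1:
        raise ParameterError("subset_size must be >= 1")
    last_err: Optional[ScheduleError] = None
    for _ in range(20):  # re-draw the partition if a subset is unschedulable
        perm = rng.permutation(len(profiles))
        trials: List[Trial] = []
        block = 0
        try:
            for start in range(0, len(profiles), subset_size):
                block += 1
                subset = [profiles[i] for i in perm[start:start + subset_size]]
                trials.extend(build_exp1_block(
                    subset, amplitudes=amplitudes,
                    reps_per_param=reps_per_param,
                    catch_fraction=catch_fraction, rng=rng, session_day=block,
                    block=block, max_restarts=max_restarts))
            return trials
        except ScheduleError as err:
            last_err = err
    raise last_err


def build_exp2_schedule(electrode_ids: Sequence[int],
                        amplitudes: Sequence[float] = EXP2_AMPLITUDES_UA,
                        frequencies: Sequence[float] = EXP2_FREQUENCIES_HZ,
                        days: int = 3,
                        reps_per_day: int = 2,
                        rng: Optional[np.random.Generator] = None,
                        start_day: int = 1) -> List[Trial]:
    """Amplitude x frequency mapping schedule.

    Per day, every (electrode, amplitude, frequency) triple appears exactly
    *reps_per_day* times in pseudorandom order; across *days* days each triple
    is tested days x reps_per_day times.
    """
    rng = np.random.default_rng(rng)
    ids = list(electrode_ids)
    if len(set(ids)) != len(ids):
        raise ParameterError("duplicated electrode ids in Experiment-2 subset")
    if not ids:
        raise ParameterError("need at least one electrode")
    stims = {(a, f): StimParams(amplitude_uA=float(a), frequency_hz=float(f))
             for a in amplitudes for f in frequencies}
    for s in stims.values():
        validate_stim(s)
    items = [(e, a, f) for e in ids for a in amplitudes for f in frequencies
             for _ in range(reps_per_day)]
    trials: List[Trial] = []
    for d in range(days):
        day = start_day + d
        order = rng.permutation(len(items))
        for idx, j in enumerate(order):
            e, a, f = items[j]
            trials.append(Trial("exp2", day, 1, idx,
                                electrode_id=e, stim=stims[(a, f)],
                                is_catch=False))
    return trials


def adjacency_violations(trials: Sequence[Trial],
                         adjacency: Dict[int, Set[int]]) -> List[int]:
    """Linear scan for consecutive same/adjacent-electrode stimulation trials.

    Returns the order indices of offending trials (the second of each pair),
    scanning stimulation trials per (session_day, block) in order and ignoring
    interleaved catch trials.
    """
    bad: List[int] = []
    by_block: Dict[tuple, List[Trial]] = {}
    for t in trials:
        by_block.setdefault((t.session_day, t.block), []).append(t)
    for key, blk in by_block.items():
        blk = sorted(blk, key=lambda t: t.order_index)
        prev = None
        for t in blk:
            if t.is_catch:
                continue
            if prev is not None and (
                    t.electrode_id == prev or
                    t.electrode_id in adjacency.get(prev, set())):
                bad.append(t.order_index)
            prev = t.electrode_id
    return bad


def schedule_multiset(trials: Sequence[Trial]) -> Counter:
    """Multiset of (electrode, amplitude, frequency) over stimulation trials."""
    return Counter((t.electrode_id, t.stim.amplitude_uA, t.stim.frequency_hz)
                   for t in trials if not t.is_catch)
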