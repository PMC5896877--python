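"""Trial-design construction: charge safety, adjacency, block and schedule
structure."""

import numpy as np
import pytest

from icmsmap import SimulationConfig, make_electrode_population
from icmsmap.design import (adjacency_violations, build_exp1_block,
                            build_exp1_schedule, build_exp2_schedule,
                            charge_per_phase, electrode_adjacency,
                            schedule_multiset, validate_stim)
from icmsmap.errors import ChargeSafetyError, ParameterError, ScheduleError
from icmsmap.types import (EXP1_AMPLITUDES_UA, EXP2_AMPLITUDES_UA,
                           EXP2_FREQUENCIES_HZ, ElectrodeProfile, StimParams)


def profile(eid, array="medial", row=0, col=0):
    return ElectrodeProfile(
        electrode_id=eid, array=array, row=row, col=col, connected=True,
        impedance_kohm=50.0, responsive=True, p_detect_base=0.5,
        detect_amp_slope=0.0, modality_beta0=0.0, modality_beta1=0.0)


class TestChargeSafety:
    def test_max_protocol_amplitude_hits_limit(self):
        assert charge_per_phase(StimParams(100.0)) == pytest.approx(20.0)
        validate_stim(StimParams(100.0))  # exactly at the limit is allowed

    def test_direct_arithmetic(self):
        assert charge_per_phase(StimParams(60.0)) == pytest.approx(12.0)

    def test_degenerate_amplitude(self):
        with pytest.raises(ParameterError):
            charge_per_phase(StimParams(0.0))
        with pytest.raises(ParameterError):
            charge_per_phase(StimParams(50.0, pulse_width_us=0.0))

    def test_above_limit_rejected(self):
        with pytest.raises(ChargeSafetyError):
            validate_stim(StimParams(110.0))
        with pytest.raises(ChargeSafetyError):
            validate_stim(StimParams(100.0, pulse_width_us=250.0))


class TestAdjacency:
    def test_unit_offset_same_array(self):
        adj = electrode_adjacency([profile(1, row=0, col=0),
                                   profile(2, row=0, col=1)])
        assert 2 in adj[1] and 1 in adj[2]

    def test_diagonal_counts(self):
        adj = electrode_adjacency([profile(1, row=3, col=3),
                                   profile(2, row=4, col=4)])
        assert 2 in adj[1]

    def test_same_coordinates_different_arrays_not_adjacent(self):
        adj = electrode_adjacency([profile(1, array="medial"),
                                   profile(2, array="lateral")])
        assert adj[1] == set() and adj[2] == set()

    def test_corner_site_has_three_neighbours_on_full_grid(self):
        profs = [profile(r * 7 + c + 1, row=r, col=c)
                 for r in range(7) for c in range(7)]
        adj = electrode_adjacency(profs)
        assert len(adj[1]) == 3          # corner (0,0)
        assert len(adj[3 * 7 + 3 + 1]) == 8  # interior (3,3)

    def test_irreflexive_and_symmetric(self):
        profs = [profile(i + 1, row=i // 7, col=i % 7) for i in range(20)]
        adj = electrode_adjacency(profs)
        for e, nb in adj.items():
            assert e not in nb
            assert all(e in adj[o] for o in nb)


class TestExp1Block:
    def test_counts_and_catch_rounding(self):
        # 4 mutually non-adjacent electrodes: 96 stim + round(9.6) = 10 catch
        profs = [profile(i + 1, row=2 * i, col=2 * i) for i in range(4)]
        trials = build_exp1_block(profs, rng=np.random.default_rng(0))
        stim = [t for t in trials if not t.is_catch]
        catch = [t for t in trials if t.is_catch]
        assert len(stim) == 4 * 8 * 3 and len(catch) == 10
        multiset = schedule_multiset(trials)
        assert all(v == 3 for v in multiset.values())
        assert len(multiset) == 4 * 8

    def test_single_trial_no_catch(self):
        trials = build_exp1_block([profile(1)], amplitudes=[60.0],
                                  reps_per_param=1,
                                  rng=np.random.default_rng(0))
        assert len(trials) == 1 and not trials[0].is_catch

    def test_single_electrode_many_trials_unschedulable(self):
        with pytest.raises(ScheduleError):
            build_exp1_block([profile(1)], amplitudes=[60.0],
                             reps_per_param=2, rng=np.random.default_rng(0),
                             max_restarts=50)

    def test_order_indices_contiguous(self):
        profs = [profile(i + 1, row=2 * i, col=0) for i in range(4)]
        trials = build_exp1_block(profs, rng=np.random.default_rng(1))
        assert [t.order_index for t in trials] == list(range(len(trials)))

    def test_no_adjacency_violations_across_seeds(self):
        rng = np.random.default_rng(2024)
        cfg = SimulationConfig(seed=0)
        population = make_electrode_population(cfg)
        for _ in range(200):
            idx = rng.choice(len(population), 8, replace=False)
            subset = [population[i] for i in idx]
            trials = build_exp1_block(subset, rng=rng)
            adj = electrode_adjacency(subset)
            assert adjacency_violations(trials, adj) == []
            # independent scan, written separately from the package checker
            prev = None
            for t in sorted(trials, key=lambda t: t.order_index):
                if t.is_catch:
                    continue
                if prev is not None:
                    assert t.electrode_id != prev
                    assert t.electrode_id not in adj[prev]
                prev = t.electrode_id

    def test_clique_subset_still_schedulable(self):
        # a 2x2 block of mutually adjacent electrodes holds exactly half the
        # trials: only strict alternation works
        profs = ([profile(i + 1, row=2 + i // 2, col=2 + i % 2)
                  for i in range(4)] +
                 [profile(5, row=0, col=6), profile(6, row=6, col=0),
                  profile(7, array="lateral", row=0, col=0),
                  profile(8, array="lateral", row=6, col=6)])
        trials = build_exp1_block(profs, rng=np.random.default_rng(5))
        adj = electrode_adjacency(profs)
        assert adjacency_violations(trials, adj) == []

    def test_multiset_invariant_under_seed(self):
        profs = [profile(i + 1, row=2 * i, col=2 * i) for i in range(4)]
        m1 = schedule_multiset(build_exp1_block(profs, rng=np.random.default_rng(1)))
        m2 = schedule_multiset(build_exp1_block(profs, rng=np.random.default_rng(9)))
        assert m1 == m2

    def test_all_stims_pass_charge_limit(self):
        profs = [profile(i + 1, row=2 * i, col=2 * i) for i in range(4)]
        trials = build_exp1_block(profs, rng=np.random.default_rng(3))
        for t in trials:
            if not t.is_catch:
                assert charge_per_phase(t.stim) <= 20.0 + 1e-12


class TestExp1Schedule:
    def test_covers_all_electrodes(self):
        cfg = SimulationConfig(seed=1)
        population = make_electrode_population(cfg)
        trials = build_exp1_schedule(population, rng=np.random.default_rng(1))
        stim = [t for t in trials if not t.is_catch]
        assert len(stim) == 96 * 8 * 3
        ids = {t.electrode_id for t in stim}
        assert ids == {p.electrode_id for p in population}
        adj = electrode_adjacency(population)
        assert adjacency_violations(trials, adj) == []


class TestExp2Schedule:
    def test_default_counts(self):
        trials = build_exp2_schedule([1, 2, 3, 4, 5],
                                     rng=np.random.default_rng(0))
        assert len(trials) == 900
        per_day = {}
        for t in trials:
            per_day.setdefault(t.session_day, []).append(t)
        assert sorted(per_day) == [1, 2, 3]
        assert all(len(v) == 300 for v in per_day.values())
        multiset = schedule_multiset(trials)
        assert len(multiset) == 5 * 5 * 6
        assert all(v == 6 for v in multiset.values())
        # per day, every triple appears exactly twice
        for day, ts in per_day.items():
            m = schedule_multiset(ts)
            assert all(v == 2 for v in m.values())

    def test_pooled_stimulations_per_combination(self):
        trials = build_exp2_schedule([1, 2, 3, 4, 5],
                                     rng=np.random.default_rng(4))
        pooled = {}
        for t in trials:
            key = (t.stim.amplitude_uA, t.stim.frequency_hz)
            pooled[key] = pooled.get(key, 0) + 1
        assert len(pooled) == 30
        assert all(v == 30 for v in pooled.values())

    def test_single_day_single_rep(self):
        trials = build_exp2_schedule([1, 2], days=1, reps_per_day=1,
                                     rng=np.random.default_rng(0))
        m = schedule_multiset(trials)
        assert all(v == 1 for v in m.values())
        assert len(trials) == 2 * len(EXP2_AMPLITUDES_UA) * len(EXP2_FREQUENCIES_HZ)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ParameterError):
            build_exp2_schedule([1, 1, 2, 3, 4], rng=np.random.default_rng(0))
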