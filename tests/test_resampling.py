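"""Bootstrap of modality composition and trial-history shuffle null."""

import numpy as np
import pytest

from icmsmap.errors import CoverageError
from icmsmap.resampling import bootstrap_modality_slopes, trial_history_null
from icmsmap.types import PROPRIOCEPTIVE


def toy_pools(rng, n_per_amp=40, p_by_amp=None):
    amps = [20.0, 40.0, 60.0, 80.0, 100.0]
    p_by_amp = p_by_amp or {a: 0.3 for a in amps}
    amplitude, prop = [], []
    for a in amps:
        amplitude += [a] * n_per_amp
        prop += list(rng.random(n_per_amp) < p_by_amp[a])
    return np.array(amplitude), np.array(prop)


class TestBootstrap:
    def test_all_proprioceptive_gives_flat_100pct(self):
        amp = np.repeat([20.0, 60.0, 100.0], 5)
        boot = bootstrap_modality_slopes(amp, np.ones(15, bool), n_iter=200,
                                         rng=np.random.default_rng(0))
        assert np.all(boot.pct_prop == 100.0)
        assert np.all(boot.slopes_prop == 0.0)
        assert boot.kde_prop is None  # degenerate slope distribution

    def test_composition_sums_to_100(self):
        rng = np.random.default_rng(1)
        amp, prop = toy_pools(rng)
        boot = bootstrap_modality_slopes(amp, prop, n_iter=500, rng=rng)
        pct_cut = 100.0 - boot.pct_prop
        assert np.allclose(boot.pct_prop + pct_cut, 100.0)
        assert np.allclose(boot.slopes_cut, -boot.slopes_prop)
        assert len(boot.slopes_prop) == 500

    def test_null_composition_symmetric_slopes(self):
        # modality independent of amplitude: slope distribution centred at 0
        rng = np.random.default_rng(2)
        amp, prop = toy_pools(rng, n_per_amp=200)
        boot = bootstrap_modality_slopes(amp, prop, n_iter=10_000, rng=rng)
        mean = boot.slopes_prop.mean()
        mc_se = boot.slopes_prop.std() / np.sqrt(boot.n_iter)
        # centre within Monte-Carlo error of the pool's own (finite) slope
        pool_pct = [100 * prop[amp == a].mean() for a in boot.amplitudes]
        xc = boot.amplitudes - boot.amplitudes.mean()
        pool_slope = float(xc @ (pool_pct - np.mean(pool_pct)) / (xc @ xc))
        assert abs(mean - pool_slope) < 5 * mc_se
        assert (boot.slopes_prop > 0).mean() > 0.05
        assert (boot.slopes_prop < 0).mean() > 0.05

    def test_amplitude_dependent_composition_slope_signs(self):
        rng = np.random.default_rng(3)
        amp, prop = toy_pools(
            rng, n_per_amp=80,
            p_by_amp={20.0: 0.1, 40.0: 0.15, 60.0: 0.2, 80.0: 0.3, 100.0: 0.4})
        boot = bootstrap_modality_slopes(amp, prop, n_iter=5_000, rng=rng)
        assert (boot.slopes_prop > 0).mean() >= 0.95
        assert (boot.slopes_cut < 0).mean() >= 0.95

    def test_median_converges_to_pool_percentage(self):
        # pool proportions on the 15-draw lattice (k/15), where the binomial
        # median equals the pool percentage exactly as n_iter grows
        amps = [20.0, 40.0, 60.0, 80.0, 100.0]
        fracs = [3, 5, 6, 8, 9]  # out of 15
        amplitude, prop = [], []
        for a, k in zip(amps, fracs):
            amplitude += [a] * 60
            prop += [True] * (4 * k) + [False] * (60 - 4 * k)
        amp = np.array(amplitude)
        prop = np.array(prop)
        boot = bootstrap_modality_slopes(amp, prop, n_iter=10_000,
                                         rng=np.random.default_rng(4))
        for j, a in enumerate(boot.amplitudes):
            pool_pct = 100.0 * prop[amp == a].mean()
            assert abs(boot.median_pct_prop[j] - pool_pct) <= 2.0

    def test_empty_amplitude_pool_names_level(self):
        amp = np.repeat([20.0, 60.0], 10)
        prop = np.zeros(20, bool)
        with pytest.raises(CoverageError, match="100"):
            bootstrap_modality_slopes(amp, prop, amplitudes=[20., 60., 100.],
                                      n_iter=10, rng=np.random.default_rng(0))

    def test_without_replacement_mode(self):
        rng = np.random.default_rng(5)
        amp, prop = toy_pools(rng, n_per_amp=30)
        boot = bootstrap_modality_slopes(amp, prop, n_iter=200, rng=rng,
                                         with_replacement=False)
        assert boot.pct_prop.shape == (200, 5)
        with pytest.raises(CoverageError):
            bootstrap_modality_slopes(amp, prop, n_iter=10,
                                      draws_per_amplitude=31, rng=rng,
                                      with_replacement=False)

    def test_exchangeable_in_response_order(self):
        rng = np.random.default_rng(6)
        amp, prop = toy_pools(rng, n_per_amp=25)
        b1 = bootstrap_modality_slopes(amp, prop, n_iter=300,
                                       rng=np.random.default_rng(7))
        order = np.argsort(rng.random(amp.size), kind="stable")
        # permute within amplitude pools only (pools must be preserved)
        idx = np.arange(amp.size)
        for a in np.unique(amp):
            sel = np.where(amp == a)[0]
            idx[sel] = sel[np.argsort(rng.random(sel.size))]
        b2 = bootstrap_modality_slopes(amp[idx], prop[idx], n_iter=300,
                                       rng=np.random.default_rng(7))
        # same per-amplitude pools + same seed -> same sampled compositions
        # distributionally; medians agree closely
        assert np.allclose(np.sort(b1.median_pct_prop),
                           np.sort(b2.median_pct_prop), atol=7.0)


def iid_sessions(make_session_rows, rng, n_sessions=3, n_per_amp=20,
                 amps=(20.0, 60.0, 100.0), p=0.3):
    rows = []
    for day in range(1, n_sessions + 1):
        amp_seq = rng.permutation(np.repeat(amps, n_per_amp))
        for i, a in enumerate(amp_seq):
            det = bool(rng.random() < p)
            rows.append({
                "session_day": day, "trial_index": i, "amplitude_uA": float(a),
                "detected": det,
                "modality": "cutaneous" if det else None,
                "intensity": 5 if det else None,
            })
    return make_session_rows(rows)


class TestTrialHistoryNull:
    def test_all_detected(self, make_session_rows):
        rows = [{"detected": True, "modality": "cutaneous", "intensity": 5,
                 "trial_index": i} for i in range(6)]
        out = trial_history_null(make_session_rows(rows),
                                 n_perm=200, rng=np.random.default_rng(0))
        row = out.table.iloc[0]
        assert row["p_report_after_hit"] == 1.0
        assert not row["computed_after_miss"]

    def test_two_trial_hit_hit_exhaustive(self, make_session_rows):
        # outcomes (1,1): the only arrangement; null P(hit | prev hit) = 1
        rows = [{"detected": True, "modality": "cutaneous", "trial_index": 0},
                {"detected": True, "modality": "cutaneous", "trial_index": 1}]
        out = trial_history_null(make_session_rows(rows), n_perm=500,
                                 rng=np.random.default_rng(1))
        row = out.table.iloc[0]
        assert row["p_report_after_hit"] == 1.0
        assert row["q05_after_hit"] == 1.0 and row["q95_after_hit"] == 1.0
        assert row["within_envelope_after_hit"]

    def test_first_trial_excluded_from_conditionals(self, make_session_rows):
        # single session (miss, hit): only trial 2 conditions, on a miss
        rows = [{"detected": False, "trial_index": 0},
                {"detected": True, "modality": "cutaneous", "trial_index": 1}]
        out = trial_history_null(make_session_rows(rows), n_perm=100,
                                 rng=np.random.default_rng(2))
        row = out.table.iloc[0]
        assert not row["computed_after_hit"]
        assert row["p_report_after_miss"] == 1.0

    def test_iid_outcomes_inside_envelope(self, make_session_rows):
        # smoke-scale version (20 simulations); the full 100-simulation
        # calibration runs in the acceptance suite
        rng = np.random.default_rng(10)
        inside = total = 0
        for _ in range(20):
            data = iid_sessions(make_session_rows, rng)
            out = trial_history_null(data, n_perm=2_000, rng=rng)
            for _, row in out.table.iterrows():
                for cond in ("after_hit", "after_miss"):
                    if row[f"computed_{cond}"] and \
                            row[f"within_envelope_{cond}"] is not None:
                        total += 1
                        inside += bool(row[f"within_envelope_{cond}"])
        assert total > 0
        assert inside / total >= 0.85

    def test_catch_trials_excluded_by_default(self, make_session_rows):
        rows = [{"detected": True, "modality": "cutaneous", "trial_index": 0},
                {"is_catch": True, "detected": False, "electrode_id": None,
                 "amplitude_uA": None, "trial_index": 1},
                {"detected": True, "modality": "cutaneous", "trial_index": 2}]
        out = trial_history_null(make_session_rows(rows), n_perm=100,
                                 rng=np.random.default_rng(3))
        # with the catch removed, trial 2's predecessor is the trial-0 hit
        row = out.table.iloc[0]
        assert row["p_report_after_hit"] == 1.0
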