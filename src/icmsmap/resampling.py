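"""Bespoke resampling procedures.

* :func:`bootstrap_modality_slopes` — equal-size bootstrap of the
  proprioceptive/cutaneous composition at each amplitude (15 draws per
  amplitude per iteration by default), with a first-order polynomial slope of
  percentage-vs-amplitude collected per iteration and summarised as kernel
  density estimates.  This removes the bias an uneven distribution of
  responses across amplitudes would otherwise impose on the composition
  trend.
* :func:`trial_history_null` — sequential-dependence check: empirical
  probability of a report after a hit versus after a miss at each amplitude,
  compared against a shuffle null (outcomes permuted within
  (session, amplitude) strata) through 5th-95th percentile envelopes, with a
  companion Kruskal-Wallis test across the all/after-hit/after-miss
  conditions using per-session proportions and a Dunn-Sidak correction over
  amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, ParameterError
from .stats import GaussianKDE, dunn_sidak, kruskal_wallis, polyfit1
from .types import PROPRIOCEPTIVE, SessionData

__all__ = ["BootstrapSlopes", "bootstrap_modality_slopes",
           "PermutationNull", "trial_history_null"]


@dataclass
class BootstrapSlopes:
    """Bootstrap distributions of the modality-composition slope.

    Percentages are on a 0-100 scale, slopes in percentage points per µA.
    At every iteration and amplitude the proprioceptive and cutaneous
    percentages sum to 100, so the cutaneous slope distribution is the exact
    mirror of the proprioceptive one.
    """

    n_iter: int
    draws_per_amplitude: int
    amplitudes: np.ndarray
    pct_prop: np.ndarray            # (n_iter, n_amplitudes)
    slopes_prop: np.ndarray         # (n_iter,)
    slopes_cut: np.ndarray          # (n_iter,)
    median_pct_prop: np.ndarray     # per amplitude
    median_pct_cut: np.ndarray
    kde_prop: Optional[GaussianKDE]
    kde_cut: Optional[GaussianKDE]

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "amplitude_uA": self.amplitudes,
            "median_pct_proprioceptive": self.median_pct_prop,
            "median_pct_cutaneous": self.median_pct_cut,
        })


def bootstrap_modality_slopes(amplitude: Sequence[float],
                              is_proprioceptive: Sequence[bool],
                              amplitudes: Optional[Sequence[float]] = None,
                              n_iter: int = 10_000,
                              draws_per_amplitude: int = 15,
                              rng: Optional[np.random.Generator] = None,
                              with_replacement: bool = True) -> BootstrapSlopes:
    """Bootstrap the modality composition against amplitude.

    Parameters
    ----------
    amplitude, is_proprioceptive
        Per detected response: the stimulation amplitude and whether the
        report was proprioceptive (False = cutaneous).
    amplitudes
        Amplitude levels to resample at (default: the sorted unique levels
        present).  A level with no responses raises CoverageError.
    with_replacement
        Standard bootstrap (default).  Without replacement requires every
        amplitude pool to hold at least *draws_per_amplitude* responses.
    """
    rng = np.random.default_rng(rng)
    amp = np.asarray(amplitude, dtype=float)
    prop = np.asarray(is_proprioceptive, dtype=bool)
    if amp.size != prop.size:
        raise ParameterError("amplitude and modality arrays must align")
    levels = (np.sort(np.unique(amp)) if amplitudes is None
              else np.asarray(sorted(amplitudes), dtype=float))
    if levels.size < 2:
        raise ParameterError("need at least two amplitude levels for a slope")

    pct_prop = np.empty((n_iter, levels.size), dtype=float)
    for j, a in enumerate(levels):
        pool = prop[amp == a]
        if pool.size == 0:
            raise CoverageError(f"no detected responses at amplitude {a} µA")
        if with_replacement:
            idx = rng.integers(0, pool.size, size=(n_iter, draws_per_amplitude))
        else:
            if pool.size < draws_per_amplitude:
                raise CoverageError(
                    f"amplitude {a} µA has {pool.size} < {draws_per_amplitude} "
                    "responses; without-replacement draws impossible")
            idx = np.argsort(rng.random((n_iter, pool.size)),
                             axis=1)[:, :draws_per_amplitude]
        pct_prop[:, j] = pool[idx].mean(axis=1) * 100.0

    # vectorised per-iteration OLS slope of percentage vs amplitude
    xc = levels - levels.mean()
    sxx = float((xc * xc).sum())
    slopes_prop = (pct_prop - pct_prop.mean(axis=1, keepdims=True)) @ xc / sxx
    slopes_cut = -slopes_prop

    def _kde(v):
        try:
            return GaussianKDE.fit(v)
        except Exception:
            return None  # degenerate compositions (e.g. all one modality)

    return BootstrapSlopes(
        n_iter=n_iter, draws_per_amplitude=draws_per_amplitude,
        amplitudes=levels, pct_prop=pct_prop,
        slopes_prop=slopes_prop, slopes_cut=slopes_cut,
        median_pct_prop=np.median(pct_prop, axis=0),
        median_pct_cut=np.median(100.0 - pct_prop, axis=0),
        kde_prop=_kde(slopes_prop), kde_cut=_kde(slopes_cut))


# ---------------------------------------------------------------------------
# Trial-history permutation null
# ---------------------------------------------------------------------------


@dataclass
class PermutationNull:
    """Per-amplitude sequential-dependence summary.

    ``table`` has one row per amplitude with the empirical report
    probabilities overall / after a hit / after a miss, the 5th and 95th
    percentiles of the shuffle distributions of the two conditionals, flags
    for whether the empirical conditionals fall inside their envelopes, and
    the Dunn-Sidak-corrected Kruskal-Wallis p-value across the three
    conditions.  Conditionals without any qualifying predecessor are NaN with
    ``computed_after_hit`` / ``computed_after_miss`` False.
    """

    n_perm: int
    table: pd.DataFrame
    shuffle_after_hit: Dict[float, np.ndarray] = field(default_factory=dict)
    shuffle_after_miss: Dict[float, np.ndarray] = field(default_factory=dict)


def _conditionals(det: np.ndarray, prev: np.ndarray, valid: np.ndarray,
                  sel: np.ndarray):
    """P(report | prev hit) and P(report | prev miss) over selected trials.

    det/prev may be (n,) or (n_perm, n); returns scalars or vectors.
    """
    use_hit = valid & sel & (prev == 1)
    use_miss = valid & sel & (prev == 0)
    if det.ndim == 1:
        ph = det[use_hit].mean() if use_hit.any() else np.nan
        pm = det[use_miss].mean() if use_miss.any() else np.nan
        return ph, pm
    n_hit = use_hit.sum(axis=1)
    n_miss = use_miss.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ph = np.where(n_hit > 0, (det * use_hit).sum(axis=1) / n_hit, np.nan)
        pm = np.where(n_miss > 0, (det * use_miss).sum(axis=1) / n_miss, np.nan)
    return ph, pm


def trial_history_null(sessions: SessionData,
                       n_perm: int = 10_000,
                       rng: Optional[np.random.Generator] = None,
                       include_catch_as_miss: bool = False) -> PermutationNull:
    """Shuffle null for sequential dependence of detection reports.

    Within every session, non-catch trials are taken in presentation order
    (catch trials are excluded from conditioning by default; with
    ``include_catch_as_miss`` they act as forced-miss predecessors).  The
    predecessor of a trial is the preceding conditioning trial in the same
    session; session-initial trials have none and enter only the
    unconditional proportion.  The null permutes detection outcomes within
    (session, amplitude) strata, preserving per-stratum hit counts.
    """
    rng = np.random.default_rng(rng)
    t = sessions.table
    cond = t if include_catch_as_miss else t[~t["is_catch"]]
    if cond.empty:
        raise ParameterError("no trials available for history conditioning")

    per_session = []
    for day, grp in cond.groupby("session_day"):
        grp = grp.sort_values(["block", "trial_index"])
        det = np.where(grp["is_catch"].to_numpy(), 0,
                       grp["detected"].to_numpy().astype(np.int8))
        amps = grp["amplitude_uA"].to_numpy(dtype=float)
        amps = np.where(np.isnan(amps), -1.0, amps)
        is_stim = ~grp["is_catch"].to_numpy()
        prev = np.concatenate([[-1], det[:-1]]).astype(np.int8)
        valid = np.concatenate([[False], np.ones(det.size - 1, dtype=bool)])
        per_session.append((day, det, prev, valid, amps, is_stim))

    levels = np.sort(np.unique(
        cond.loc[~cond["is_catch"], "amplitude_uA"].dropna().to_numpy(float)))

    # shuffle matrices: permute outcomes within (session, amplitude) strata,
    # built once, then pooled; predecessor matrices are shifted per session
    md_parts: List[np.ndarray] = []
    mprev_parts: List[np.ndarray] = []
    for day, det, prev, valid, amps, is_stim in per_session:
        m = np.tile(det, (n_perm, 1))
        for a in levels:
            idx = np.where(is_stim & (amps == a))[0]
            if idx.size > 1:
                m[:, idx] = rng.permuted(m[:, idx], axis=1)
        md_parts.append(m)
        mprev_parts.append(np.concatenate(
            [np.full((n_perm, 1), -1, dtype=np.int8), m[:, :-1]], axis=1))
    md = np.concatenate(md_parts, axis=1)
    mprev = np.concatenate(mprev_parts, axis=1)
    det_c = np.concatenate([s[1] for s in per_session])
    prev_c = np.concatenate([s[2] for s in per_session])
    valid_c = np.concatenate([s[3] for s in per_session])
    amps_c = np.concatenate([s[4] for s in per_session])
    stim_c = np.concatenate([s[5] for s in per_session])

    rows = []
    shuffle_hit: Dict[float, np.ndarray] = {}
    shuffle_miss: Dict[float, np.ndarray] = {}
    kw_pvals = []
    for a in levels:
        sel_c = stim_c & (amps_c == a)
        p_all = float(det_c[sel_c].mean()) if sel_c.any() else np.nan
        ph, pm = _conditionals(det_c, prev_c, valid_c, sel_c)

        # shuffle distribution, pooled the same way (restricted columns)
        cols = np.where(sel_c & valid_c)[0]
        ones = np.ones(cols.size, dtype=bool)[None, :]
        sph, spm = _conditionals(md[:, cols].astype(float),
                                 mprev[:, cols], ones & True, ones)
        shuffle_hit[float(a)] = sph
        shuffle_miss[float(a)] = spm

        def _bounds(v):
            # order-statistic percentiles: envelope endpoints are attainable
            # values of the (discrete) shuffle distribution
            v = v[~np.isnan(v)]
            if v.size == 0:
                return np.nan, np.nan
            return (float(np.percentile(v, 5, method="lower")),
                    float(np.percentile(v, 95, method="higher")))

        lo_h, hi_h = _bounds(sph)
        lo_m, hi_m = _bounds(spm)

        # companion KW on per-session proportions across the three conditions
        g_all, g_hit, g_miss = [], [], []
        for day, det, prev, valid, amps, is_stim in per_session:
            sel = is_stim & (amps == a)
            if sel.any():
                g_all.append(det[sel].mean())
            sph_s, spm_s = _conditionals(det, prev, valid, sel)
            if not np.isnan(sph_s):
                g_hit.append(sph_s)
            if not np.isnan(spm_s):
                g_miss.append(spm_s)
        groups = [g for g in (g_all, g_hit, g_miss) if len(g) > 0]
        if len(groups) >= 2 and sum(len(g) for g in groups) >= 3:
            kw_p = kruskal_wallis(groups).p_value
        else:
            kw_p = np.nan
        kw_pvals.append(kw_p)

        rows.append({
            "amplitude_uA": float(a),
            "p_report_all": p_all,
            "p_report_after_hit": ph,
            "p_report_after_miss": pm,
            "computed_after_hit": not np.isnan(ph),
            "computed_after_miss": not np.isnan(pm),
            "q05_after_hit": lo_h, "q95_after_hit": hi_h,
            "q05_after_miss": lo_m, "q95_after_miss": hi_m,
            "within_envelope_after_hit": (
                bool(lo_h <= ph <= hi_h) if not np.isnan(ph) and
                not np.isnan(lo_h) else None),
            "within_envelope_after_miss": (
                bool(lo_m <= pm <= hi_m) if not np.isnan(pm) and
                not np.isnan(lo_m) else None),
        })

    table = pd.DataFrame(rows)
    kw = np.asarray(kw_pvals, dtype=float)
    adj = np.full_like(kw, np.nan)
    ok = ~np.isnan(kw)
    if ok.any():
        adj[ok] = dunn_sidak(kw[ok], m=int(ok.sum()))
    table["kw_p_conditions"] = kw
    table["kw_p_conditions_sidak"] = adj
    return PermutationNull(n_perm=n_perm, table=table,
                           shuffle_after_hit=shuffle_hit,
                           shuffle_after_miss=shuffle_miss)
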