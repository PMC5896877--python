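"""End-to-end analysis of percept-mapping sessions.

Given per-trial session data (simulated or read from CSV) this module
produces the study's summary quantities: detection counts, per-electrode
modality classification, descriptor tables with amplitude/intensity
percentiles, Kruskal-Wallis tests of stimulation parameters against percept
modality, impedance comparisons, intensity and duration analyses, and
receptive-field consistency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataCompletenessError, DegenerateDataError, ParameterError
from .stats import (TestResult, kruskal_wallis, ks_two_sample, pearson_corr,
                    polyfit1)
from .types import (CUTANEOUS, DURATION_CATEGORIES, PROPRIOCEPTIVE,
                    SessionData)

__all__ = [
    "summarize_detection", "classify_electrodes", "ElectrodeModalityClass",
    "descriptor_table", "modality_parameter_tests", "impedance_tests",
    "intensity_analysis", "duration_analysis", "receptive_field_consistency",
    "run_full_analysis",
]


# ---------------------------------------------------------------------------
# Detection summary
# ---------------------------------------------------------------------------


def summarize_detection(sessions: SessionData) -> Dict[str, object]:
    """Headline counts: responsive electrodes, detected responses, catch
    statistics.  ``responsive_pct`` is None when no non-catch trials exist."""
    t = sessions.table
    non_catch = sessions.non_catch
    detected = sessions.detected
    stimulable = non_catch["electrode_id"].dropna().unique()
    responsive = detected["electrode_id"].dropna().unique()
    catch = sessions.catch
    n_stimulable = int(len(stimulable))
    out = {
        "responsive_electrodes": int(len(responsive)),
        "total_stimulable_electrodes": n_stimulable,
        "responsive_pct": (100.0 * len(responsive) / n_stimulable
                           if n_stimulable else None),
        "detected_responses": int(len(detected)),
        "non_catch_trials": int(len(non_catch)),
        "catch_trials": int(len(catch)),
        "catch_false_positives": int(catch["detected"].sum()),
    }
    return out


# ---------------------------------------------------------------------------
# Electrode modality classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeModalityClass:
    electrode_id: int
    klass: str                      # cutaneous_only | proprioceptive_only | mixed
    mixed_subclass: Optional[str]   # mostly_cutaneous | mostly_proprioceptive | equal
    n_cutaneous: int
    n_proprioceptive: int


def classify_electrodes(sessions: SessionData) -> List[ElectrodeModalityClass]:
    """Classify every responsive electrode by the modalities it elicited.

    Electrodes with both modalities are ``mixed`` and sub-classified by
    strict majority (exact ties are ``equal``); electrodes with no detected
    responses are excluded.
    """
    detected = sessions.detected
    out: List[ElectrodeModalityClass] = []
    for eid, grp in detected.groupby("electrode_id"):
        n_cut = int((grp["modality"] == CUTANEOUS).sum())
        n_prop = int((grp["modality"] == PROPRIOCEPTIVE).sum())
        if n_cut > 0 and n_prop > 0:
            if n_cut > n_prop:
                sub = "mostly_cutaneous"
            elif n_prop > n_cut:
                sub = "mostly_proprioceptive"
            else:
                sub = "equal"
            out.append(ElectrodeModalityClass(int(eid), "mixed", sub,
                                              n_cut, n_prop))
        elif n_cut > 0:
            out.append(ElectrodeModalityClass(int(eid), "cutaneous_only",
                                              None, n_cut, 0))
        elif n_prop > 0:
            out.append(ElectrodeModalityClass(int(eid), "proprioceptive_only",
                                              None, 0, n_prop))
    return sorted(out, key=lambda c: c.electrode_id)


def classification_summary(classes: Sequence[ElectrodeModalityClass]
                           ) -> Dict[str, object]:
    n_mixed = sum(1 for c in classes if c.klass == "mixed")
    subs = [c.mixed_subclass for c in classes if c.klass == "mixed"]
    return {
        "cutaneous_only": sum(1 for c in classes if c.klass == "cutaneous_only"),
        "proprioceptive_only": sum(1 for c in classes
                                   if c.klass == "proprioceptive_only"),
        "mixed": n_mixed,
        "mixed_pct_mostly_cutaneous": (100.0 * subs.count("mostly_cutaneous")
                                       / n_mixed if n_mixed else None),
        "mixed_pct_mostly_proprioceptive": (
            100.0 * subs.count("mostly_proprioceptive") / n_mixed
            if n_mixed else None),
        "mixed_pct_equal": (100.0 * subs.count("equal") / n_mixed
                            if n_mixed else None),
    }


# ---------------------------------------------------------------------------
# Descriptor table
# ---------------------------------------------------------------------------


def _mode_smallest(values: np.ndarray) -> float:
    """Mode of a discrete sample, smallest value among tied modes."""
    uniq, counts = np.unique(values, return_counts=True)
    return float(uniq[np.argmax(counts)])


def descriptor_table(sessions: SessionData,
                     coverage: float = 0.90) -> pd.DataFrame:
    """Most prevalent descriptors with amplitude/intensity modes and
    25th-75th percentiles (linear interpolation), sorted by share of total
    responses; descriptors beyond the cumulative *coverage* threshold are
    pooled into an ``other`` row."""
    d = sessions.detected.dropna(subset=["descriptor"])
    n_total = len(sessions.detected)
    if n_total == 0:
        return pd.DataFrame(columns=[
            "descriptor", "pct_of_total", "amplitude_mode", "amplitude_q25",
            "amplitude_q75", "intensity_mode", "intensity_q25", "intensity_q75"])

    def _row(name, grp):
        amp = grp["amplitude_uA"].to_numpy(dtype=float)
        inten = grp["intensity"].dropna().to_numpy(dtype=float)
        return {
            "descriptor": name,
            "pct_of_total": 100.0 * len(grp) / n_total,
            "amplitude_mode": _mode_smallest(amp),
            "amplitude_q25": float(np.percentile(amp, 25)),
            "amplitude_q75": float(np.percentile(amp, 75)),
            "intensity_mode": _mode_smallest(inten) if inten.size else np.nan,
            "intensity_q25": (float(np.percentile(inten, 25))
                              if inten.size else np.nan),
            "intensity_q75": (float(np.percentile(inten, 75))
                              if inten.size else np.nan),
        }

    rows = [_row(name, grp) for name, grp in d.groupby("descriptor")]
    rows.sort(key=lambda r: (-r["pct_of_total"], r["descriptor"]))
    kept, pooled_names = [], []
    cum = 0.0
    for r in rows:
        if r["descriptor"] != "other" and cum < coverage * 100.0:
            kept.append(r)
            cum += r["pct_of_total"]
        else:
            pooled_names.append(r["descriptor"])
    if pooled_names:
        pooled = d[d["descriptor"].isin(pooled_names)]
        kept.append(_row("other", pooled))
    return pd.DataFrame(kept).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Modality vs stimulation-parameter tests
# ---------------------------------------------------------------------------


def modality_parameter_tests(sessions: SessionData,
                             parameter: str = "amplitude") -> TestResult:
    """Kruskal-Wallis test of a stimulation parameter (amplitude or
    frequency) across the two percept modalities."""
    col = {"amplitude": "amplitude_uA", "frequency": "frequency_hz"}.get(parameter)
    if col is None:
        raise ParameterError(f"unknown parameter {parameter!r}")
    d = sessions.detected
    groups = [d.loc[d["modality"] == m, col].to_numpy(dtype=float)
              for m in (PROPRIOCEPTIVE, CUTANEOUS)]
    if any(g.size == 0 for g in groups):
        raise DegenerateDataError(
            "both modalities must be present to test a parameter effect")
    return kruskal_wallis(groups)


# ---------------------------------------------------------------------------
# Impedance tests
# ---------------------------------------------------------------------------


def impedance_tests(sessions: SessionData) -> Dict[str, TestResult]:
    """Impedance comparisons.

    (a) KS two-sample: per-electrode mean impedance, responsive vs
        non-responsive electrodes;
    (b) KW: per-response impedance (snapshot of the stimulated electrode in
        that session) across the two modalities;
    (c) KW: per-electrode mean impedance, proprioceptive-only vs
        cutaneous-only electrodes, and unimodal vs mixed;
    (d) Pearson correlation of per-electrode mean impedance with the
        electrode's report rate (detected / non-catch trials, pooled days).
    """
    t = sessions.non_catch
    if t["impedance_kohm"].isna().any():
        missing = sorted(t.loc[t["impedance_kohm"].isna(), "electrode_id"]
                         .dropna().unique().tolist())
        raise DataCompletenessError(
            f"missing impedance snapshots for electrodes {missing}")
    per_electrode = t.groupby("electrode_id").agg(
        impedance=("impedance_kohm", "mean"),
        n_trials=("electrode_id", "size"),
        n_detected=("detected", "sum"))
    per_electrode["rate"] = per_electrode["n_detected"] / per_electrode["n_trials"]

    detected = sessions.detected
    responsive_ids = set(detected["electrode_id"].dropna().astype(int))
    resp_mask = per_electrode.index.astype(int).isin(responsive_ids)

    out: Dict[str, TestResult] = {}
    imp = per_electrode["impedance"].to_numpy(dtype=float)
    if np.all(imp == imp[0]):
        raise DegenerateDataError("all impedances identical: tests degenerate")
    if resp_mask.any() and (~resp_mask).any():
        out["responsive_vs_not_ks"] = ks_two_sample(imp[resp_mask],
                                                    imp[~resp_mask])
    by_modality = [detected.loc[detected["modality"] == m, "impedance_kohm"]
                   .to_numpy(dtype=float)
                   for m in (PROPRIOCEPTIVE, CUTANEOUS)]
    if all(g.size for g in by_modality):
        out["modality_kw"] = kruskal_wallis(by_modality)

    classes = classify_electrodes(sessions)
    imp_of = per_electrode["impedance"]
    prop_only = [imp_of[c.electrode_id] for c in classes
                 if c.klass == "proprioceptive_only"]
    cut_only = [imp_of[c.electrode_id] for c in classes
                if c.klass == "cutaneous_only"]
    mixed = [imp_of[c.electrode_id] for c in classes if c.klass == "mixed"]
    if prop_only and cut_only:
        out["prop_only_vs_cut_only_kw"] = kruskal_wallis([prop_only, cut_only])
    if mixed and (prop_only or cut_only):
        out["unimodal_vs_mixed_kw"] = kruskal_wallis(
            [prop_only + cut_only, mixed])
    out["impedance_vs_rate_pearson"] = pearson_corr(
        per_electrode["impedance"].to_numpy(dtype=float),
        per_electrode["rate"].to_numpy(dtype=float))
    return out


# ---------------------------------------------------------------------------
# Intensity
# ---------------------------------------------------------------------------


def intensity_analysis(sessions: SessionData,
                       literal_normalization: bool = False) -> Dict[str, object]:
    """Intensity-vs-amplitude analysis.

    Raw reported intensities (1-10) are correlated with amplitude (Pearson)
    and fitted with an ordinary least-squares line.  Per session, intensities
    are rescaled to [0, 1]; min-max scaling ``(x - min) / (max - min)`` by
    default, or the literal ``(x - min) / max`` variant when
    *literal_normalization* is set.  Sessions with constant intensity cannot
    be normalized and are flagged and excluded from the per-amplitude
    SD-vs-amplitude correlation.
    """
    d = sessions.detected.dropna(subset=["intensity", "amplitude_uA"])
    if len(d) < 3:
        raise ParameterError("need at least 3 detected responses with intensity")
    amp = d["amplitude_uA"].to_numpy(dtype=float)
    inten = d["intensity"].to_numpy(dtype=float)
    try:
        corr = pearson_corr(inten, amp)
        slope, intercept = polyfit1(amp, inten)
    except DegenerateDataError:
        # single amplitude level (or constant intensity): no trend estimable
        corr, slope, intercept = None, None, None

    norm = np.full(len(d), np.nan)
    degenerate_sessions: List[int] = []
    for day, grp in d.groupby("session_day"):
        v = grp["intensity"].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        denom = hi if literal_normalization else hi - lo
        if denom <= 0:
            degenerate_sessions.append(int(day))
            continue
        norm[d.index.get_indexer(grp.index)] = (v - lo) / denom
    d = d.assign(norm_intensity=norm)

    per_amp = (d.dropna(subset=["norm_intensity"])
               .groupby("amplitude_uA")["norm_intensity"]
               .agg(["std", "mean", "size"]))
    mean_by_amp = d.groupby("amplitude_uA")["intensity"].mean()
    sd_corr = None
    usable = per_amp["std"].dropna()
    if len(usable) >= 3 and usable.nunique() > 1:
        sd_corr = pearson_corr(usable.index.to_numpy(dtype=float),
                               usable.to_numpy(dtype=float))
    return {
        "pearson": corr,
        "slope": slope,
        "intercept": intercept,
        "mean_intensity_by_amplitude": mean_by_amp,
        "normalized_sd_by_amplitude": per_amp["std"],
        "sd_vs_amplitude_pearson": sd_corr,
        "degenerate_sessions": degenerate_sessions,
        "n": int(len(d)),
    }


# ---------------------------------------------------------------------------
# Duration
# ---------------------------------------------------------------------------


def duration_analysis(sessions: SessionData) -> Dict[str, object]:
    """Duration-category counts plus KW tests of amplitude (and frequency,
    when several frequencies were tested) across categories."""
    d = sessions.detected
    counts = {c: int((d["duration_category"] == c).sum())
              for c in DURATION_CATEGORIES}
    missing = int(d["duration_category"].isna().sum())
    out: Dict[str, object] = {"counts": counts, "missing": missing}

    with_dur = d.dropna(subset=["duration_category"])
    groups_amp = [with_dur.loc[with_dur["duration_category"] == c,
                               "amplitude_uA"].to_numpy(dtype=float)
                  for c in DURATION_CATEGORIES]
    groups_amp = [g for g in groups_amp if g.size > 0]
    out["amplitude_kw"] = (kruskal_wallis(groups_amp)
                           if len(groups_amp) >= 2 else None)
    if with_dur["frequency_hz"].nunique() > 1:
        groups_f = [with_dur.loc[with_dur["duration_category"] == c,
                                 "frequency_hz"].to_numpy(dtype=float)
                    for c in DURATION_CATEGORIES]
        groups_f = [g for g in groups_f if g.size > 0]
        out["frequency_kw"] = (kruskal_wallis(groups_f)
                               if len(groups_f) >= 2 else None)
    else:
        out["frequency_kw"] = None
    return out


# ---------------------------------------------------------------------------
# Receptive fields
# ---------------------------------------------------------------------------


def receptive_field_consistency(sessions: SessionData) -> Dict[str, object]:
    """Per-electrode receptive-field consistency and per-array modal shares.

    An electrode is region-consistent (plane-consistent) when all its
    detected responses report the same body region (plane); its modal
    receptive field is the most frequent (region, plane) pair.  Per array,
    the distribution of (region, plane) over all responses is reported with
    the modal category's share.
    """
    d = sessions.detected.dropna(subset=["region", "plane"])
    electrodes = []
    for eid, grp in d.groupby("electrode_id"):
        pairs = list(zip(grp["region"], grp["plane"]))
        uniq, counts = np.unique([f"{r}|{p}" for r, p in pairs],
                                 return_counts=True)
        modal = uniq[np.argmax(counts)]
        electrodes.append({
            "electrode_id": int(eid),
            "consistent_region": grp["region"].nunique() == 1,
            "consistent_plane": grp["plane"].nunique() == 1,
            "modal_rf": tuple(modal.split("|")),
            "n_responses": int(len(grp)),
        })
    n_consistent = sum(1 for e in electrodes
                       if e["consistent_region"] or e["consistent_plane"])
    arrays = {}
    for arr, grp in d.groupby("array"):
        shares = (grp.groupby(["region", "plane"]).size()
                  / len(grp)).sort_values(ascending=False)
        arrays[arr] = {
            "distribution": shares,
            "modal_cell": shares.index[0],
            "modal_share": float(shares.iloc[0]),
        }
    return {
        "electrodes": electrodes,
        "n_consistent_region_or_plane": n_consistent,
        "n_classified": len(electrodes),
        "arrays": arrays,
    }


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


def run_full_analysis(sessions: SessionData,
                      n_boot: int = 10_000,
                      n_perm: int = 10_000,
                      rng: Optional[np.random.Generator] = None
                      ) -> Dict[str, object]:
    """Run every analysis stage on one dataset and return the results bundle."""
    from .resampling import bootstrap_modality_slopes, trial_history_null

    rng = np.random.default_rng(rng)
    out: Dict[str, object] = {}
    out["summary"] = summarize_detection(sessions)
    classes = classify_electrodes(sessions)
    out["electrode_classes"] = classes
    out["classification_summary"] = classification_summary(classes)
    out["descriptor_table"] = descriptor_table(sessions)
    d = sessions.detected
    both = (d["modality"] == PROPRIOCEPTIVE).any() and \
        (d["modality"] == CUTANEOUS).any()
    out["amplitude_modality_kw"] = (
        modality_parameter_tests(sessions, "amplitude") if both else None)
    out["frequency_modality_kw"] = (
        modality_parameter_tests(sessions, "frequency")
        if both and d["frequency_hz"].nunique() > 1 else None)
    out["impedance_tests"] = impedance_tests(sessions)
    out["intensity"] = intensity_analysis(sessions)
    out["duration"] = duration_analysis(sessions)
    out["receptive_fields"] = receptive_field_consistency(sessions)
    if both and n_boot > 0:
        out["bootstrap"] = bootstrap_modality_slopes(
            d["amplitude_uA"].to_numpy(dtype=float),
            (d["modality"] == PROPRIOCEPTIVE).to_numpy(),
            n_iter=n_boot, rng=rng)
    else:
        out["bootstrap"] = None
    out["history_null"] = (trial_history_null(sessions, n_perm=n_perm, rng=rng)
                           if n_perm > 0 else None)
    return out
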