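"""Pupillometry preprocessing.

Pipeline: blink interpolation (linear between flanking valid samples), per-run
percent normalisation against the run mean, extraction of a per-trial
baseline (mean over the 20 ms window preceding feedback), and trial
exclusions (first 25 trials of each run, trials whose baseline window was
lost to blinks).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "interpolate_blinks",
    "normalize_trace",
    "baseline_per_trial",
    "apply_exclusions",
    "preprocess",
    "detect_blinks_threshold",
]


def detect_blinks_threshold(values: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Missing-sample mask for imported data: a sample is a blink when its
    value is <= threshold or non-finite."""
    v = np.asarray(values, dtype=float)
    return ~np.isfinite(v) | (v <= threshold)


def interpolate_blinks(trace: pd.DataFrame) -> pd.DataFrame:
    """Fill interior gaps linearly between the flanking valid samples.

    Expects columns (time_ms, value, is_missing). Gaps at the very start or
    end of the trace have no anchor on one side and are never extrapolated:
    they stay missing (``still_missing`` True) and downstream baseline
    extraction flags the affected trials as lost.
    """
    out = trace.copy()
    v = out["value"].to_numpy(dtype=float).copy()
    missing = out["is_missing"].to_numpy(dtype=bool) | ~np.isfinite(v)
    if missing.all():
        out["value"] = np.nan
        out["still_missing"] = True
        return out
    idx = np.arange(len(v))
    valid = ~missing
    interior = missing & (idx > idx[valid].min()) & (idx < idx[valid].max())
    v[interior] = np.interp(idx[interior], idx[valid], v[valid])
    v[missing & ~interior] = np.nan
    out["value"] = v
    out["still_missing"] = missing & ~interior
    return out


def normalize_trace(trace: pd.DataFrame) -> pd.DataFrame:
    """Percent signal change from the run mean, per run, over retained samples."""
    out = trace.copy()
    v = out["value"].to_numpy(dtype=float)
    norm = np.full_like(v, np.nan)
    for _, idx in out.groupby("run", sort=True).indices.items():
        seg = v[idx]
        m = np.nanmean(seg)
        if not np.isfinite(m) or m <= 0:
            raise ValueError("run mean must be positive for percent normalisation")
        norm[idx] = 100.0 * (seg - m) / m
    out["normalized"] = norm
    return out


def baseline_per_trial(
    trace: pd.DataFrame,
    feedback_ms: np.ndarray,
    window_ms: float = 20.0,
    column: str = "normalized",
) -> pd.DataFrame:
    """Mean of samples in the half-open window [feedback - window, feedback).

    At 1000 Hz this is 20 samples. A trial whose window holds no finite
    sample is flagged lost.
    """
    t = trace["time_ms"].to_numpy(dtype=float)
    v = trace[column].to_numpy(dtype=float)
    rows = []
    for trial, fb in enumerate(np.asarray(feedback_ms, dtype=float)):
        sel = (t >= fb - window_ms) & (t < fb)
        window = v[sel]
        window = window[np.isfinite(window)]
        lost = len(window) == 0
        rows.append(
            {
                "trial": trial,
                "baseline": float(window.mean()) if not lost else np.nan,
                "lost": lost,
                "n_samples": len(window),
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    baselines: pd.DataFrame,
    trials: pd.DataFrame,
    n_lead_trials: int = 25,
    core_exploit_only: bool = False,
) -> pd.DataFrame:
    """Attach exclusion flags; returns baselines with (run, t, excluded, reason).

    Drops the first ``n_lead_trials`` trials of each run (screen-luminance
    settling), trials lost to blinks, and optionally non-core-exploit trials.
    """
    out = baselines.copy()
    out["run"] = trials["run"].to_numpy()
    out["t"] = trials["t"].to_numpy()
    reason = np.array([""] * len(out), dtype=object)
    excluded = np.zeros(len(out), dtype=bool)

    lead = trials["t"].to_numpy() < n_lead_trials
    excluded |= lead
    reason[lead] = "lead_in"
    lost = out["lost"].to_numpy(dtype=bool)
    reason[lost & ~excluded] = "lost"
    excluded |= lost
    if core_exploit_only:
        if "core_exploit" not in trials.columns:
            raise ValueError("trials lack core_exploit labels")
        non_core = ~trials["core_exploit"].to_numpy(dtype=bool)
        reason[non_core & ~excluded] = "non_core"
        excluded |= non_core
    out["excluded"] = excluded
    out["reason"] = reason
    return out


def preprocess(trace: pd.DataFrame, feedback_ms: np.ndarray, trials: pd.DataFrame,
               window_ms: float = 20.0, n_lead_trials: int = 25,
               core_exploit_only: bool = False) -> pd.DataFrame:
    """Full pipeline: interpolate, normalise, baseline, exclude."""
    clean = interpolate_blinks(trace)
    norm = normalize_trace(clean)
    base = baseline_per_trial(norm, feedback_ms, window_ms=window_ms)
    return apply_exclusions(base, trials, n_lead_trials=n_lead_trials,
                            core_exploit_only=core_exploit_only)
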