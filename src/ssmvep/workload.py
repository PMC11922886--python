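"""Bandpower-ratio cognitive-load and fatigue metrics with task trends.

Cognitive load is tracked by the θ/α bandpower ratio and fatigue by
(θ+α)/β: rising θ with falling α marks growing load, while fatigue raises
θ and α against β.  Each block's four tasks are fitted with a least-squares
line over the task index, and the *variation extent* is the percent change
of the fitted line between task 4 and task 1:

    extent = 100 * (fit(4) - fit(1)) / |fit(1)|

Extents are computed on raw fitted ratio values; per-subject z-scoring is
applied only for cross-subject aggregation (relative differences of
z-scored values are ill-defined near zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .spectral import welch_psd, band_power
from .synth_eeg import BANDS, TrialTensor

__all__ = ["bandpowers", "ratio_trend", "fatigue_report"]

#: Relative threshold below which a fitted task-1 ratio counts as zero.
_EXTENT_EPS = 1e-6


def bandpowers(trials: TrialTensor, bands: dict | None = None,
               window_seconds: float = 2.0) -> pd.DataFrame:
    """Per-task mean θ/α/β bandpowers and the two ratios.

    Welch PSDs are computed per trial, integrated over each named band,
    averaged over channels and then over the trials of each
    (subject, paradigm, task) cell.  Returns one row per cell with columns
    ``theta_power, alpha_power, beta_power, load_ratio, fatigue_ratio``.
    """
    bands = dict(bands or BANDS)
    fs = trials.sampling_rate_hz
    nyq = fs / 2
    for name, (lo, hi) in bands.items():
        if not (0 < lo < hi <= nyq):
            raise ValueError(f"band {name}={lo, hi} outside the spectrum")

    psd = welch_psd(trials.data, fs, window_seconds=window_seconds)
    per_trial = {name: np.asarray(band_power(psd, edges)).mean(axis=-1)
                 for name, edges in bands.items()}  # mean over channels

    df = trials.labels[["subject", "paradigm", "task"]].copy()
    for name, values in per_trial.items():
        df[f"{name}_power"] = values
    out = (df.groupby(["subject", "paradigm", "task"], sort=True)
             .mean().reset_index())
    out["load_ratio"] = out["theta_power"] / out["alpha_power"]
    out["fatigue_ratio"] = (out["theta_power"] + out["alpha_power"]) / out["beta_power"]
    return out


def _extent(tasks: np.ndarray, ratios: np.ndarray) -> tuple[float, float, float]:
    """Fit a line over task index; return (slope, intercept, extent_pct)."""
    if len(np.unique(tasks)) < 2:
        raise ValueError("need at least 2 distinct task points for a trend")
    slope, intercept = np.polyfit(tasks, ratios, 1)
    first, last = tasks.min(), tasks.max()
    fit1 = slope * first + intercept
    fit4 = slope * last + intercept
    if abs(fit1) < _EXTENT_EPS * abs(ratios.mean()):
        return float(slope), float(intercept), float("nan")
    return float(slope), float(intercept), float(100.0 * (fit4 - fit1) / abs(fit1))


def ratio_trend(series: pd.DataFrame) -> pd.DataFrame:
    """Linear task trends and variation extents per subject and paradigm.

    ``series`` is the output of :func:`bandpowers`.  Returns one row per
    (subject, paradigm) with fitted slope/intercept and variation extent
    (%) for the load and fatigue ratios; an extent whose task-1 fitted
    value is numerically zero is reported as NaN rather than a blown-up
    percentage.
    """
    required = {"subject", "paradigm", "task", "load_ratio", "fatigue_ratio"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns {sorted(missing)}")
    rows = []
    for (subject, paradigm), grp in series.groupby(["subject", "paradigm"], sort=True):
        tasks = grp["task"].to_numpy(dtype=float)
        row = {"subject": subject, "paradigm": paradigm}
        for label, col in (("load", "load_ratio"), ("fatigue", "fatigue_ratio")):
            slope, intercept, extent = _extent(tasks, grp[col].to_numpy(dtype=float))
            row[f"{label}_slope"] = slope
            row[f"{label}_intercept"] = intercept
            row[f"{label}_extent_pct"] = extent
        rows.append(row)
    return pd.DataFrame(rows)


def fatigue_report(series: pd.DataFrame) -> dict:
    """Full report: per-subject trends plus per-subject z-scored ratios.

    The z-scored ratios (mean removed, unit variance per subject, across
    that subject's task × paradigm cells) support cross-subject comparison
    of trajectories; extents in the trend table remain on the raw scale.
    """
    trends = ratio_trend(series)
    normalized = series.copy()
    for col in ("load_ratio", "fatigue_ratio"):
        z = normalized.groupby("subject")[col].transform(
            lambda v: (v - v.mean()) / (v.std(ddof=0) or 1.0))
        normalized[f"{col}_z"] = z
    summary = (trends.groupby("paradigm")[["load_extent_pct", "fatigue_extent_pct"]]
               .mean().rename(columns=lambda c: f"mean_{c}"))
    return {"trends": trends, "normalized": normalized,
            "paradigm_means": summary.reset_index()}
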