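"""Filtering chain, epoching and trial averaging.

The acquisition chain is an 8th-order Butterworth band-pass (2–100 Hz)
followed by a 4th-order Butterworth band-stop notch over 48–52 Hz (powerline
region).  Two analysis presets exist downstream: 1–30 Hz before trial
averaging / bandpower work and 2–40 Hz before FFT amplitude spectra.  All
filters are applied zero-phase (forward-backward, ``sosfiltfilt``) to keep
evoked-response latencies intact for averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synth_eeg import TrialTensor

__all__ = ["FilterSpec", "FILTER_PRESETS", "apply_filter_chain",
           "epoch_trials", "average_trials"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """One Butterworth stage of the preprocessing chain."""

    kind: str                  # "bandpass" | "notch"
    order: int
    band_hz: tuple[float, float]

    def __post_init__(self):
        low, high = self.band_hz
        if not (0 < low < high):
            raise ValueError(f"need 0 < low < high, got {self.band_hz}")
        if self.kind not in ("bandpass", "notch"):
            raise ValueError(f"kind must be 'bandpass' or 'notch', got {self.kind!r}")
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self, fs: float) -> np.ndarray:
        low, high = self.band_hz
        if high >= fs / 2:
            raise ValueError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
        btype = "bandpass" if self.kind == "bandpass" else "bandstop"
        return signal.butter(self.order, [low, high], btype=btype, fs=fs,
                             output="sos")


#: Named chain presets: acquisition, pre-averaging, pre-FFT.
FILTER_PRESETS = {
    "acq": (FilterSpec("bandpass", 8, (2.0, 100.0)),
            FilterSpec("notch", 4, (48.0, 52.0))),
    "avg_1_30": (FilterSpec("bandpass", 4, (1.0, 30.0)),),
    "fft_2_40": (FilterSpec("bandpass", 4, (2.0, 40.0)),),
}


def apply_filter_chain(trials, specs, fs: float | None = None):
    """Apply a sequence of filter stages zero-phase along the time axis.

    ``trials`` may be a :class:`TrialTensor` (its sampling rate is used) or
    a bare array whose last axis is time (then ``fs`` is required).
    ``specs`` is an iterable of :class:`FilterSpec` or a preset name.
    """
    if isinstance(specs, str):
        specs = FILTER_PRESETS[specs]
    if isinstance(trials, TrialTensor):
        out = apply_filter_chain(trials.data, specs, fs=trials.sampling_rate_hz)
        return TrialTensor(out, trials.labels, trials.sampling_rate_hz,
                           trials.channels)
    if fs is None:
        raise ValueError("fs required for bare arrays")
    data = np.asarray(trials, dtype=float)
    for spec in specs:
        data = signal.sosfiltfilt(spec.sos(fs), data, axis=-1)
    return data


def epoch_trials(continuous: np.ndarray, events: pd.DataFrame, fs: float,
                 trial_seconds: float = 5.0, channels=None) -> TrialTensor:
    """Cut stimulation epochs out of a continuous recording.

    ``events`` needs an ``onset_sample`` column; remaining columns become
    the trial labels.  Epochs cover ``[onset, onset + trial_seconds)`` —
    cue and gray-screen intervals fall outside by construction.  Epochs
    running past the recording end are dropped with a warning; overlapping
    epochs are an error (they indicate a malformed event table).
    """
    n_samples = int(round(trial_seconds * fs))
    onsets = events["onset_sample"].to_numpy(dtype=int)
    if np.any(np.diff(np.sort(onsets)) < n_samples):
        raise ValueError("overlapping epochs: event spacing shorter than a trial")
    keep, chunks = [], []
    for idx, onset in enumerate(onsets):
        if onset < 0 or onset + n_samples > continuous.shape[-1]:
            logger.warning("dropping epoch %d at sample %d: extends past the "
                           "recording end", idx, onset)
            continue
        keep.append(idx)
        chunks.append(continuous[:, onset:onset + n_samples])
    labels = events.iloc[keep].drop(columns=["onset_sample"]).reset_index(drop=True)
    data = (np.stack(chunks) if chunks
            else np.empty((0, continuous.shape[0], n_samples)))
    return TrialTensor(data=data, labels=labels, sampling_rate_hz=fs,
                       channels=tuple(channels) if channels else TrialTensor.channels)


def average_trials(trials: TrialTensor, by=None):
    """Average trials, optionally per label group.

    With ``by=None`` returns one (n_channels, n_samples) mean over all
    trials; with ``by`` a label column (or list of columns) returns a dict
    mapping group key -> mean array.  Averaging N trials of i.i.d. noise
    shrinks the noise RMS by about 1/sqrt(N) while the phase-locked evoked
    response survives intact.
    """
    if trials.n_trials == 0:
        raise ValueError("cannot average an empty trial set")
    if by is None:
        return trials.data.mean(axis=0)
    out = {}
    for key, group in trials.labels.groupby(by, sort=True):
        out[key] = trials.data[group.index.to_numpy()].mean(axis=0)
    return out
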