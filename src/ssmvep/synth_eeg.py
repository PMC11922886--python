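"""Synthetic multichannel EEG sessions with the study's structure.

A forward model standing in for human recordings: each 5-s trial at
1,200 Hz over the six parieto-occipital channels (Po3, Poz, Po4, O1, Oz,
O2) is the sum of

* a phase-locked steady-state response — sinusoids at the stimulation
  frequency and its harmonics, scaled by a paradigm gain (bimodal >
  single-motion > single-color under the default calibration), per-channel
  gains peaking at Oz, and a lognormal per-subject factor;
* 1/f^gamma background noise;
* band-limited theta/alpha/beta oscillatory components whose powers drift
  linearly across the four tasks of a block (the workload/fatigue
  substrate), with alpha the most prominent, as over posterior cortex.

Everything is deterministic given the master seed: per-trial generators are
spawned from a ``SeedSequence`` keyed on (subject, paradigm, brightness,
task, trial).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "BANDS",
    "BAND_PROFILES",
    "SessionLayout",
    "ResponseModel",
    "TrialTensor",
    "generate_trial",
    "generate_session",
    "noise_band_power",
    "component_band_fraction",
    "expected_band_power",
]

CHANNELS = ("Po3", "Poz", "Po4", "O1", "Oz", "O2")

#: Conventional clinical band edges in Hz.
BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

#: Spectral profile (center Hz, Gaussian sigma Hz) of each rhythmic
#: component.  EEG rhythms are narrowband humps, not flat bands; centering
#: them inside their bands also keeps their power from straddling band
#: edges, so band-integrated power measurements track the injected values.
BAND_PROFILES = {"theta": (6.0, 0.8), "alpha": (10.0, 1.2), "beta": (20.0, 3.0)}

PARADIGMS = ("bimodal", "single_motion", "single_color")


@dataclass(frozen=True)
class SessionLayout:
    """Structural constants of one recording block.

    Defaults mirror the study protocol: 10 subjects, 3 brightness levels,
    4 stimulation frequencies (the 4 tasks of a block), 20 trials per run,
    6 channels at 1,200 Hz, 5-s trials flanked by a 1-s cue and a 1-s gray
    screen.
    """

    n_subjects: int = 10
    brightness_levels: tuple = ("low", "medium", "high")
    frequencies_hz: tuple = (3.0, 3.5, 4.0, 4.5)
    trials_per_run: int = 20
    channels: tuple = CHANNELS
    sampling_rate_hz: float = 1200.0
    trial_seconds: float = 5.0
    cue_seconds: float = 1.0
    gray_seconds: float = 1.0
    blocks: tuple = PARADIGMS
    area_ratio_C: float = 0.6

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.sampling_rate_hz * self.trial_seconds))

    @property
    def tasks_per_block(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class ResponseModel:
    """Amplitudes, gains and noise parameters of the forward model.

    Units are microvolts (amplitudes) and µV² (powers).  The defaults are
    calibrated only to preserve the orderings the analyses test (paradigm
    gain ordering, alpha prominence), not to reproduce any subject's
    absolute values.
    """

    harmonic_amplitudes: tuple = (1.0, 0.4)       # µV, fundamental + harmonics
    harmonic_phases: tuple = (0.0, 0.7853981633974483)  # rad, phase-locked
    paradigm_gains: dict = field(default_factory=lambda: {
        "bimodal": 1.0, "single_motion": 0.75, "single_color": 0.6})
    brightness_gains: dict = field(default_factory=lambda: {
        "low": 0.85, "medium": 1.0, "high": 0.92})
    channel_gains: tuple = (0.8, 0.9, 0.8, 0.9, 1.0, 0.9)  # Po3..O2, Oz peak
    noise_exponent: float = 1.0                   # 1/f^gamma slope
    noise_scale: float = 1.5                      # µV RMS of the 1/f floor
    band_powers: dict = field(default_factory=lambda: {
        "theta": 1.0, "alpha": 4.0, "beta": 0.6})  # µV² per component
    band_drift_slopes: dict = field(default_factory=lambda: {
        "theta": 0.0, "alpha": 0.0, "beta": 0.0})  # fractional power / task
    subject_sigma: float = 0.3                    # lognormal amplitude spread

    def subject_factor(self, subject: int, master_seed: int) -> float:
        """Deterministic lognormal amplitude factor for one subject."""
        rng = np.random.default_rng(_child_seed(master_seed, "subject", subject))
        return float(rng.lognormal(mean=0.0, sigma=self.subject_sigma))

    def band_power_at_task(self, band: str, task_index: int) -> float:
        """Component power in a band at task 1..4 (linear drift)."""
        slope = self.band_drift_slopes.get(band, 0.0)
        return self.band_powers[band] * (1.0 + slope * (task_index - 1))


@dataclass
class TrialTensor:
    """Trials as a flat (n_trials, n_channels, n_samples) array + labels.

    ``labels`` is a DataFrame aligned with the first axis, carrying
    subject, paradigm, brightness, area ratio C, stimulation frequency,
    task index (1-based) and trial index.
    """

    data: np.ndarray
    labels: pd.DataFrame
    sampling_rate_hz: float
    channels: tuple = CHANNELS

    def __post_init__(self):
        if self.data.shape[0] != len(self.labels):
            raise ValueError("labels must align with the trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, **conditions) -> "TrialTensor":
        """Subset trials by label equality, e.g. ``select(paradigm='bimodal')``."""
        mask = np.ones(len(self.labels), dtype=bool)
        for key, value in conditions.items():
            mask &= (self.labels[key] == value).to_numpy()
        return TrialTensor(self.data[mask], self.labels[mask].reset_index(drop=True),
                           self.sampling_rate_hz, self.channels)


def _child_seed(master_seed: int, *key) -> np.random.SeedSequence:
    """Stable per-entity seed derived from the master seed and a label key."""
    digest = hashlib.sha256(repr(key).encode()).digest()
    words = [int.from_bytes(digest[i:i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *words])


def _pink_noise(rng: np.random.Generator, n_samples: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    """1/f^gamma noise with the requested RMS, flat below 1 Hz."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.maximum(freqs, 1.0) ** (exponent / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n_samples)
    scale = _pink_rms_scale(n_samples, fs, exponent)
    return x * (rms / scale)


def _pink_rms_scale(n_samples: int, fs: float, exponent: float) -> float:
    """Analytic RMS of unit-white noise after the 1/f shaping filter."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.maximum(freqs, 1.0) ** (exponent / 2.0)
    shaping[0] = 0.0
    # Parseval over the rfft grid (interior bins carry double weight)
    w = np.full_like(shaping, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    return float(np.sqrt((w * shaping**2).sum() / n_samples))


def noise_band_power(model: ResponseModel, fs: float, n_samples: int,
                     band: tuple[float, float]) -> float:
    """Analytic power of the 1/f floor inside a band (per channel, µV²)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = 1.0 / np.maximum(freqs, 1.0) ** (model.noise_exponent / 2.0)
    shaping[0] = 0.0
    w = np.full_like(shaping, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    total = (w * shaping**2).sum()
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float(model.noise_scale**2 * (w * shaping**2)[sel].sum() / total)


def _component_shaping(n_samples: int, fs: float,
                       profile: tuple[float, float]) -> np.ndarray:
    """Gaussian spectral-amplitude profile of a rhythmic component."""
    center, sigma = profile
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    shaping[0] = 0.0
    return shaping


def _band_noise(rng: np.random.Generator, n_samples: int, fs: float,
                profile: tuple[float, float], power: float) -> np.ndarray:
    """Narrowband Gaussian-profile noise with exact expected power (µV²)."""
    if power <= 0:
        return np.zeros(n_samples)
    shaping = _component_shaping(n_samples, fs, profile)
    white = rng.standard_normal(n_samples)
    x = np.fft.irfft(np.fft.rfft(white) * shaping, n=n_samples)
    w = np.full_like(shaping, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    expected = (w * shaping**2).sum() / n_samples
    return x * np.sqrt(power / expected)


def component_band_fraction(profile: tuple[float, float], fs: float,
                            n_samples: int, band: tuple[float, float]) -> float:
    """Fraction of a component's power falling inside a band (analytic)."""
    shaping = _component_shaping(n_samples, fs, profile)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.full_like(shaping, 2.0)
    w[0] = 1.0
    if n_samples % 2 == 0:
        w[-1] = 1.0
    sel = (freqs >= band[0]) & (freqs < band[1])
    return float((w * shaping**2)[sel].sum() / (w * shaping**2).sum())


def expected_band_power(model: ResponseModel, fs: float, n_samples: int,
                        band_name: str, task_index: int) -> float:
    """Analytic expected band-integrated power for one task (µV²).

    Sums every rhythmic component's in-band share (Gaussian profiles make
    cross-band shares negligible but they are included exactly) plus the
    1/f floor's in-band power.  The evoked steady-state harmonics are *not*
    included — they depend on paradigm/channel/subject gains; callers
    wanting a clean band-power oracle disable them in the model.
    """
    band = BANDS[band_name]
    total = noise_band_power(model, fs, n_samples, band)
    for comp, profile in BAND_PROFILES.items():
        frac = component_band_fraction(profile, fs, n_samples, band)
        total += model.band_power_at_task(comp, task_index) * frac
    return total


def generate_trial(layout: SessionLayout, model: ResponseModel, frequency_hz: float,
                   paradigm: str, seed, *, brightness: str = "medium",
                   task_index: int = 1, subject_factor: float = 1.0) -> np.ndarray:
    """One (n_channels, samples_per_trial) trial in µV.

    Deterministic given ``seed`` (an int or ``SeedSequence``).  The evoked
    response is phase-locked (fixed harmonic phases) so trial averaging
    accumulates it while averaging the noise down.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}")
    fs = layout.sampling_rate_hz
    n = layout.samples_per_trial
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)

    gain = (model.paradigm_gains[paradigm]
            * model.brightness_gains.get(brightness, 1.0) * subject_factor)
    signal = np.zeros(n)
    for h, (amp, phase) in enumerate(zip(model.harmonic_amplitudes,
                                         model.harmonic_phases), start=1):
        signal += amp * gain * np.sin(2.0 * np.pi * h * frequency_hz * t + phase)

    trial = np.empty((layout.n_channels, n))
    for c in range(layout.n_channels):
        x = signal * model.channel_gains[c]
        x = x + _pink_noise(rng, n, fs, model.noise_exponent, model.noise_scale)
        for band, profile in BAND_PROFILES.items():
            x = x + _band_noise(rng, n, fs, profile,
                                model.band_power_at_task(band, task_index))
        trial[c] = x
    return trial


def generate_session(layout: SessionLayout, model: ResponseModel, seed: int,
                     *, paradigms=None, brightness_levels=None,
                     subjects=None) -> TrialTensor:
    """Generate a full (or subsetted) session as a :class:`TrialTensor`.

    Iterates subjects × paradigms × brightness levels × tasks × trials;
    task ``k`` presents ``layout.frequencies_hz[k-1]``, matching the
    sequential task protocol.  Per-task band drifts from
    ``model.band_drift_slopes`` are applied inside :func:`generate_trial`.
    """
    paradigms = tuple(paradigms or layout.blocks)
    brightness_levels = tuple(brightness_levels or layout.brightness_levels)
    subjects = tuple(subjects if subjects is not None else range(1, layout.n_subjects + 1))

    rows = []
    chunks = []
    for subject in subjects:
        sfac = model.subject_factor(subject, seed)
        for paradigm in paradigms:
            for brightness in brightness_levels:
                for task_index, freq in enumerate(layout.frequencies_hz, start=1):
                    for trial_index in range(1, layout.trials_per_run + 1):
                        child = _child_seed(seed, subject, paradigm, brightness,
                                            task_index, trial_index)
                        chunks.append(generate_trial(
                            layout, model, freq, paradigm, child,
                            brightness=brightness, task_index=task_index,
                            subject_factor=sfac).astype(np.float32))
                        rows.append((subject, paradigm, brightness,
                                     layout.area_ratio_C, freq, task_index,
                                     trial_index))
    labels = pd.DataFrame(rows, columns=["subject", "paradigm", "brightness",
                                         "area_ratio_C", "frequency_hz",
                                         "task", "trial"])
    data = np.stack(chunks) if chunks else np.empty((0, layout.n_channels,
                                                     layout.samples_per_trial),
                                                    dtype=np.float32)
    return TrialTensor(data=data, labels=labels,
                       sampling_rate_hz=layout.sampling_rate_hz,
                       channels=layout.channels)
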