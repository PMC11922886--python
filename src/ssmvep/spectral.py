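"""Welch PSD, FFT amplitude spectra and the harmonic SNR statistic.

The SNR of a steady-state response is the decibel ratio of the PSD summed
at the stimulation frequency and its harmonics (4 by default) to the
remaining PSD inside the analysis band:

    SNR = 10 log10( sum_l P(l f) / (P_band_total - sum_l P(l f)) )

Welch defaults are 2-s Hann windows with 50% overlap (0.5 Hz resolution,
enough to separate 3 from 3.5 Hz).  Because the Hann main lobe spreads a
sinusoid's power across the peak bin and its two neighbours, each
harmonic's signal power aggregates the nearest bin ±1; a single-bin reading
would be biased low by ~1.8 dB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["SpectrumResult", "SNRResult", "welch_psd", "band_power",
           "compute_snr", "fft_amplitude_spectrum", "find_peak"]

logger = logging.getLogger(__name__)

#: Analysis band (Hz) for the SNR denominator; stops short of the notch.
DEFAULT_ANALYSIS_BAND = (1.0, 45.0)


@dataclass
class SpectrumResult:
    """A frequency grid with amplitude or PSD values."""

    freqs_hz: np.ndarray
    values: np.ndarray          # PSD (µV²/Hz) or amplitude (µV); last axis = freq
    kind: str                   # "welch_psd" | "fft_amplitude"

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def nearest_bin(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - f_hz)))


@dataclass
class SNRResult:
    """Harmonic SNR at one stimulation frequency."""

    stimulus_freq_hz: float
    n_harmonics: int
    snr_db: float
    signal_power: float
    noise_power: float
    harmonics_used: tuple = ()
    infinite: bool = False


def welch_psd(x: np.ndarray, fs: float, window_seconds: float = 2.0,
              overlap: float = 0.5) -> SpectrumResult:
    """Welch PSD with Hann windows (density normalization, µV²/Hz).

    The density normalization makes the integral of the PSD match the
    time-domain variance (Parseval), so band powers are integrals over the
    grid.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_seconds * fs))
    if x.shape[-1] < nperseg:
        raise ValueError(f"signal ({x.shape[-1]} samples) shorter than the "
                         f"window ({nperseg} samples)")
    freqs, psd = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=int(nperseg * overlap), detrend="constant",
                           scaling="density", axis=-1)
    return SpectrumResult(freqs_hz=freqs, values=psd, kind="welch_psd")


def band_power(psd: SpectrumResult, band: tuple[float, float]) -> float | np.ndarray:
    """Integral of the PSD over a band (µV²), trapezoid-free bin sum."""
    if psd.kind != "welch_psd":
        raise ValueError("band_power expects a Welch PSD")
    lo, hi = band
    if lo >= hi or hi > psd.freqs_hz[-1] + psd.resolution_hz:
        raise ValueError(f"band {band} outside the spectrum")
    sel = (psd.freqs_hz >= lo) & (psd.freqs_hz < hi)
    return psd.values[..., sel].sum(axis=-1) * psd.resolution_hz


def compute_snr(psd: SpectrumResult, stimulus_freq_hz: float,
                n_harmonics: int = 4,
                analysis_band: tuple[float, float] = DEFAULT_ANALYSIS_BAND,
                debias: bool = True) -> SNRResult:
    """Harmonic SNR from a Welch PSD (single spectrum, last-axis freq).

    Signal power sums the PSD over the nearest bin ±1 at each of the first
    ``n_harmonics`` multiples of the stimulation frequency that fall inside
    the analysis band and below Nyquist (others are dropped with a log
    note); noise power is the band total minus the signal bins.

    With ``debias=True`` (default) the noise density estimated from the
    non-signal bins is subtracted from the signal bins and the noise power
    is rescaled to the full analysis band, so the statistic recovers the
    true signal/noise power ratio without the low-SNR bias the raw
    bin-ratio carries (the signal bins otherwise count the noise beneath
    the peaks as signal).  Degenerate pure-signal inputs yield an
    ``infinite`` flagged result.
    """
    if psd.kind != "welch_psd":
        raise ValueError("compute_snr expects a Welch PSD")
    values = np.asarray(psd.values)
    if values.ndim > 1:
        values = values.mean(axis=tuple(range(values.ndim - 1)))
    lo, hi = analysis_band
    nyquist = psd.freqs_hz[-1]
    band_sel = (psd.freqs_hz >= lo) & (psd.freqs_hz <= hi)
    total = values[band_sel].sum()

    signal_bins: set[int] = set()
    used = []
    for l in range(1, n_harmonics + 1):
        f = l * stimulus_freq_hz
        if f > min(hi, nyquist):
            logger.info("harmonic %d (%.2f Hz) outside the analysis band; dropped", l, f)
            continue
        k = psd.nearest_bin(f)
        used.append(f)
        signal_bins.update(k + d for d in (-1, 0, 1) if 0 <= k + d < len(psd.freqs_hz))
    sig = values[sorted(signal_bins)].sum()
    noise = total - sig
    if debias and noise > 0:
        n_band = int(band_sel.sum())
        n_sig = len(signal_bins)
        n_noise = n_band - n_sig
        if n_noise > 0:
            density = noise / n_noise
            sig = max(sig - density * n_sig, 1e-300)
            noise = density * n_band
    if noise <= 0:
        return SNRResult(stimulus_freq_hz, n_harmonics, float("inf"), float(sig),
                         float(noise), tuple(used), infinite=True)
    return SNRResult(stimulus_freq_hz, n_harmonics,
                     float(10.0 * np.log10(sig / noise)), float(sig),
                     float(noise), tuple(used))


def fft_amplitude_spectrum(avg: np.ndarray, fs: float) -> SpectrumResult:
    """One-sided FFT amplitude spectrum of a trial-averaged response (µV).

    Amplitude normalization ``2|X|/N`` returns each sinusoid's true peak
    amplitude; a 5-s epoch gives a 0.2 Hz grid that puts all study
    frequencies (3, 3.5, 4, 4.5 Hz and harmonics) exactly on a bin.
    """
    avg = np.asarray(avg, dtype=float)
    n = avg.shape[-1]
    spec = np.abs(np.fft.rfft(avg, axis=-1)) * 2.0 / n
    spec[..., 0] /= 2.0
    if n % 2 == 0:
        spec[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return SpectrumResult(freqs_hz=freqs, values=spec, kind="fft_amplitude")


def find_peak(spectrum: SpectrumResult, candidate_hz: float,
              halfwidth_hz: float = 0.5) -> tuple[float, float]:
    """Grid frequency and value of the maximal amplitude near a candidate.

    Searches within ``candidate_hz ± halfwidth_hz``; multichannel input is
    averaged over the leading axes first.
    """
    values = np.asarray(spectrum.values)
    if values.ndim > 1:
        values = values.mean(axis=tuple(range(values.ndim - 1)))
    sel = np.abs(spectrum.freqs_hz - candidate_hz) <= halfwidth_hz
    if not sel.any():
        raise ValueError(f"no grid bins within {halfwidth_hz} Hz of {candidate_hz}")
    idx = np.flatnonzero(sel)
    best = idx[np.argmax(values[idx])]
    return float(spectrum.freqs_hz[best]), float(values[best])
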