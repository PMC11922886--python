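"""EDF export of synthetic sessions and continuous-recording assembly.

EDF (European Data Format) stores 16-bit samples in fixed-length data
records with an ASCII header.  Reading goes through MNE; writing is done
here directly because no EDF writer library is part of the runtime stack.
The writer emits plain EDF (one data record per second, identical physical
scaling for all channels), which MNE reads back exactly up to the 16-bit
quantization.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .synth_eeg import SessionLayout, TrialTensor

__all__ = ["write_edf", "read_edf", "assemble_continuous", "write_session_edf"]


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, data: np.ndarray, sampling_rate_hz: float, channel_names,
              physical_range: tuple[float, float] = (-500.0, 500.0)) -> None:
    """Write a continuous multichannel recording to an EDF file.

    ``data`` is (n_channels, n_samples) in µV.  Samples are quantized to
    16 bits over ``physical_range``; the trailing partial second, if any, is
    zero-padded into the final record (callers should pass whole seconds).
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    fs = sampling_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    fs = int(round(fs))
    n_records = int(np.ceil(n_samp / fs))
    pmin, pmax = physical_range
    if np.any(data < pmin) or np.any(data > pmax):
        raise ValueError("data exceeds the physical range; widen physical_range")
    dmin, dmax = -32768, 32767

    header = bytearray()
    header += _pad("0", 8)                                   # version
    header += _pad("X X X X", 80)                            # patient id
    header += _pad("Startdate X X X X", 80)                  # recording id
    start = datetime.datetime(2000, 1, 1)
    header += _pad(start.strftime("%d.%m.%y"), 8)
    header += _pad(start.strftime("%H.%M.%S"), 8)
    header += _pad(str(256 * (1 + n_ch)), 8)                 # header bytes
    header += _pad("", 44)                                   # reserved
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                                   # record duration s
    header += _pad(str(n_ch), 4)

    fields = [
        ([_pad(name, 16) for name in channel_names]),
        ([_pad("AgAgCl electrode", 80)] * n_ch),
        ([_pad("uV", 8)] * n_ch),
        ([_pad(repr(float(pmin)), 8)] * n_ch),
        ([_pad(repr(float(pmax)), 8)] * n_ch),
        ([_pad(str(dmin), 8)] * n_ch),
        ([_pad(str(dmax), 8)] * n_ch),
        ([_pad("", 80)] * n_ch),                             # prefiltering
        ([_pad(str(fs), 8)] * n_ch),                         # samples/record
        ([_pad("", 32)] * n_ch),                             # reserved
    ]
    for group in fields:
        for item in group:
            header += item

    scale = (dmax - dmin) / (pmax - pmin)
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = data
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            fh.write(digital[:, rec * fs:(rec + 1) * fs].tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list]:
    """Read an EDF file via MNE; returns (data_µV, fs, channel_names)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def assemble_continuous(trials: TrialTensor, layout: SessionLayout,
                        rng_or_zero: str = "zero") -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate trials into a continuous recording with an event table.

    Each trial is preceded by the cue interval and followed by the gray
    screen interval (both zero-filled — the generator models stimulation
    epochs only).  Returns ``(continuous, events)`` where the event table
    holds the onset sample of every stimulation epoch plus its labels.
    """
    fs = layout.sampling_rate_hz
    n_cue = int(round(layout.cue_seconds * fs))
    n_gray = int(round(layout.gray_seconds * fs))
    n_trial = layout.samples_per_trial
    step = n_cue + n_trial + n_gray

    n_ch = trials.data.shape[1]
    continuous = np.zeros((n_ch, step * trials.n_trials))
    onsets = []
    for k in range(trials.n_trials):
        onset = k * step + n_cue
        continuous[:, onset:onset + n_trial] = trials.data[k]
        onsets.append(onset)
    events = trials.labels.copy()
    events.insert(0, "onset_sample", onsets)
    return continuous, events


def write_session_edf(trials: TrialTensor, layout: SessionLayout, out_dir,
                      stem: str = "session") -> tuple[Path, Path]:
    """Write a session as one EDF file plus a sidecar CSV event table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    continuous, events = assemble_continuous(trials, layout)
    edf_path = out_dir / f"{stem}.edf"
    csv_path = out_dir / f"{stem}_events.csv"
    write_edf(edf_path, continuous, layout.sampling_rate_hz, trials.channels)
    events.to_csv(csv_path, index=False)
    return edf_path, csv_path
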