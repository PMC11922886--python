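"""Frequency-recognition evaluation: CCA and compact-CNN protocols.

CCA needs no training: each segment is scored against the sinusoidal
reference set directly.  The CNN is evaluated with stratified k-fold
cross-validation over trials (per subject when subject labels are
present).  ``sweep_segment_length`` truncates trials to each requested
duration and reports accuracy per length.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cca import make_references, cca_classify
from .cnn import CompactCNNSpec, decimate_trials, train_compact_cnn
from .synth_eeg import TrialTensor

__all__ = ["cca_accuracy", "cnn_crossval_accuracy", "sweep_segment_length"]

logger = logging.getLogger(__name__)


def _segments(trials: TrialTensor, seconds: float) -> np.ndarray:
    n = int(round(seconds * trials.sampling_rate_hz))
    if n > trials.data.shape[-1]:
        raise ValueError(f"segment of {seconds} s exceeds the {trials.data.shape[-1]}"
                         f"-sample trials")
    if n < 1:
        raise ValueError("segment length must be positive")
    return trials.data[:, :, :n]


def cca_accuracy(trials: TrialTensor, seconds: float, frequencies=None,
                 n_harmonics: int = 4) -> float:
    """Fraction of trials whose CCA-predicted frequency matches the label."""
    X = _segments(trials, seconds)
    freqs = tuple(frequencies or sorted(trials.labels["frequency_hz"].unique()))
    refs = make_references(freqs, X.shape[-1], trials.sampling_rate_hz,
                           n_harmonics=n_harmonics)
    truth = trials.labels["frequency_hz"].to_numpy(dtype=float)
    hits = 0
    for k in range(X.shape[0]):
        pred, _ = cca_classify(X[k], refs)
        hits += pred == truth[k]
    return hits / X.shape[0]


def cnn_crossval_accuracy(trials: TrialTensor, seconds: float,
                          spec: CompactCNNSpec | None = None, n_folds: int = 5,
                          seed: int = 0, decimate: int | None = 4) -> pd.DataFrame:
    """Stratified k-fold accuracy of the compact CNN.

    Trials are truncated to ``seconds``, optionally decimated (the temporal
    kernel rescales to half the new rate), then split into stratified folds
    over the frequency labels.  Returns one row per fold with its accuracy.
    The whole protocol is deterministic given ``seed``.
    """
    X = _segments(trials, seconds)
    fs = trials.sampling_rate_hz
    if decimate:
        X = decimate_trials(X, decimate)
        fs = fs / decimate
    y = trials.labels["frequency_hz"].to_numpy(dtype=float)
    if spec is None:
        spec = CompactCNNSpec(sampling_rate_hz=fs, n_channels=X.shape[1],
                              n_classes=len(np.unique(y)))
    else:
        spec = replace(spec, sampling_rate_hz=fs)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    _, y_codes = np.unique(y, return_inverse=True)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y_codes)):
        model = train_compact_cnn(X[tr], y[tr], spec, seed=seed + fold)
        acc = float((model.predict(X[te]) == y[te]).mean())
        rows.append({"fold": fold, "n_test": len(te), "accuracy": acc})
        logger.info("fold %d: accuracy %.3f", fold, acc)
    return pd.DataFrame(rows)


def sweep_segment_length(trials: TrialTensor, lengths, method: str = "cca",
                         seed: int = 0, n_folds: int = 5,
                         spec: CompactCNNSpec | None = None,
                         decimate: int | None = 4) -> pd.DataFrame:
    """Accuracy as a function of data segment length.

    For ``method='cca'`` the accuracy is over all trials at each length;
    for ``'cnn'`` it is the mean cross-validated accuracy.  Returns a
    DataFrame (length_s, accuracy, sd) where sd is the across-fold SD for
    the CNN and the binomial SD for CCA.
    """
    if method not in ("cca", "cnn"):
        raise ValueError("method must be 'cca' or 'cnn'")
    rows = []
    for seconds in lengths:
        if method == "cca":
            acc = cca_accuracy(trials, seconds)
            n = trials.n_trials
            sd = float(np.sqrt(acc * (1 - acc) / n))
        else:
            folds = cnn_crossval_accuracy(trials, seconds, spec=spec,
                                          n_folds=n_folds, seed=seed,
                                          decimate=decimate)
            acc = float(folds["accuracy"].mean())
            sd = float(folds["accuracy"].std(ddof=0))
        rows.append({"length_s": float(seconds), "accuracy": acc, "sd": sd})
    return pd.DataFrame(rows)
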