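"""Canonical-correlation frequency recognition.

Classic SSVEP decoding: an EEG segment (channels × time) is correlated
against a reference set of sine/cosine pairs at each candidate stimulation
frequency and its harmonics; the predicted frequency maximises the largest
canonical correlation.  Canonical correlations are computed via QR
decompositions of the centered data blocks (singular values of Qx^T Qy),
which is numerically stable for the short, tall matrices involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["ReferenceSet", "make_references", "canonical_correlations",
           "cca_classify"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceSet:
    """Sine/cosine reference matrices per candidate frequency."""

    frequencies_hz: tuple
    n_harmonics: int
    sampling_rate_hz: float
    n_samples: int
    references: dict            # freq -> (n_samples, 2*n_harmonics) array


def make_references(frequencies_hz, n_samples: int, fs: float,
                    n_harmonics: int = 4) -> ReferenceSet:
    """Build sin/cos references at harmonics 1..n for each frequency."""
    t = np.arange(n_samples) / fs
    refs = {}
    for f in frequencies_hz:
        cols = []
        for h in range(1, n_harmonics + 1):
            cols.append(np.sin(2 * np.pi * h * f * t))
            cols.append(np.cos(2 * np.pi * h * f * t))
        refs[float(f)] = np.column_stack(cols)
    return ReferenceSet(tuple(float(f) for f in frequencies_hz), n_harmonics,
                        fs, n_samples, refs)


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """All canonical correlations between column blocks X and Y.

    Columns are centered; rank-deficient directions are discarded.  Values
    are clipped into [0, 1].
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y need the same number of rows (samples)")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, rx = np.linalg.qr(Xc)
    qy, ry = np.linalg.qr(Yc)
    # drop numerically dependent columns
    tol = max(Xc.shape) * np.finfo(float).eps
    kx = np.abs(np.diag(rx)) > tol * max(1.0, np.abs(np.diag(rx)).max())
    ky = np.abs(np.diag(ry)) > tol * max(1.0, np.abs(np.diag(ry)).max())
    sv = np.linalg.svd(qx[:, kx].T @ qy[:, ky], compute_uv=False)
    return np.clip(sv, 0.0, 1.0)


def cca_classify(segment: np.ndarray, refs: ReferenceSet):
    """Predict the stimulation frequency of one EEG segment.

    ``segment`` is (n_channels, n_samples); its length must cover at least
    one period of the lowest candidate frequency and match the reference
    length.  Returns ``(predicted_frequency, {freq: max_corr})``; exact
    ties go to the lowest frequency (logged).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2:
        raise ValueError("segment must be (n_channels, n_samples)")
    n = segment.shape[1]
    min_f = min(refs.frequencies_hz)
    if n < refs.sampling_rate_hz / min_f:
        raise ValueError(
            f"segment of {n} samples shorter than one period of {min_f} Hz")
    if n != refs.n_samples:
        raise ValueError(f"segment length {n} != reference length {refs.n_samples}")
    scores = {}
    for f in sorted(refs.frequencies_hz):
        rho = canonical_correlations(segment.T, refs.references[f])
        scores[f] = float(rho[0]) if rho.size else 0.0
    best = max(scores, key=lambda f: (scores[f], -f))
    ties = [f for f in scores if scores[f] == scores[best] and f != best]
    if ties:
        logger.info("tie between %s and %s; choosing lowest frequency", best, ties)
    return best, scores
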