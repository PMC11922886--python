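"""Compact convolutional EEG classifier (EEGNet-style), in NumPy.

The network mirrors the compact architecture used for SSVEP decoding:

1. a temporal convolution of ``F1`` filters with kernel length ``L`` set to
   half the sampling rate (600 at 1,200 Hz), applied identically to every
   electrode — a bank of learned band-pass filters;
2. a depthwise *spatial* convolution whose kernel height equals the number
   of channels (one spatial filter pair per temporal filter, depth
   multiplier ``D``), collapsing the electrode dimension;
3. a separable convolution — a depthwise temporal kernel followed by a
   pointwise mix — refining the temporal features;

with batch normalization, ELU activations, average pooling and dropout
between stages and a dense softmax head.  Forward and backward passes are
written directly against im2col/einsum primitives and trained with Adam;
training is bit-reproducible given the seed.

Input trials may optionally be decimated (factor 4 by default when
enabled); the temporal kernel then rescales to half the new rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import fft
from scipy import signal as sps

__all__ = ["CompactCNNSpec", "CompactCNN", "train_compact_cnn", "decimate_trials"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompactCNNSpec:
    """Architecture and training hyperparameters.

    ``temporal_kernel`` defaults to half the sampling rate; everything else
    follows published compact-EEG-network practice (8 temporal filters,
    depth multiplier 2, 16 separable filters, pooling 4 and 8, dropout
    0.25, Adam at 1e-3).
    """

    sampling_rate_hz: float = 1200.0
    n_channels: int = 6
    n_classes: int = 4
    F1: int = 8
    depth_multiplier: int = 2
    F2: int = 16
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 120
    patience: int = 12
    temporal_kernel: int | None = None

    @property
    def L(self) -> int:
        """Temporal kernel length: half the sampling frequency."""
        if self.temporal_kernel is not None:
            return int(self.temporal_kernel)
        return int(self.sampling_rate_hz // 2)


def decimate_trials(data: np.ndarray, factor: int = 4) -> np.ndarray:
    """Anti-aliased decimation along time (zero-phase FIR)."""
    return sps.decimate(np.asarray(data, dtype=float), factor, ftype="fir",
                        zero_phase=True, axis=-1)


# ---------------------------------------------------------------------------
# primitive ops (forward + backward)
# ---------------------------------------------------------------------------

def _same_pads(L: int) -> tuple[int, int]:
    return L // 2, L - 1 - L // 2  # (left, right)


class _TemporalConv:
    """F1 learned temporal filters shared across electrodes.

    At kernel lengths of half the sampling rate a direct im2col pass is the
    training bottleneck, so forward correlation, the weight gradient
    (a correlation of input with output gradient) and the input gradient
    (a convolution) are all evaluated exactly in the frequency domain.
    """

    def __init__(self, F1, L, rng):
        limit = np.sqrt(6.0 / (L + F1 * L))
        self.w = rng.uniform(-limit, limit, size=(F1, L)).astype(np.float64)

    def _plan(self, T):
        L = self.w.shape[1]
        M = fft.next_fast_len(T + L - 1)
        return M, _same_pads(L)[0]

    def forward(self, x, training):
        # x: (N, C, T) -> (N, F1, C, T); y[t] = sum_l x[t - pl + l] w[l]
        self._x = x
        N, C, T = x.shape
        F1, L = self.w.shape
        M, pl = self._plan(T)
        self._Xf = fft.rfft(x, M)                       # (N, C, Mf)
        Wf = fft.rfft(self.w, M)                        # (F1, Mf)
        z = fft.irfft(self._Xf[:, None] * Wf[None, :, None].conj(), M)
        idx = (np.arange(T) - pl) % M
        return np.ascontiguousarray(z[..., idx])        # (N, F1, C, T)

    def backward(self, dy):
        # dy: (N, F1, C, T)
        N, F1, C, T = dy.shape
        L = self.w.shape[1]
        M, pl = self._plan(T)
        DYf = fft.rfft(dy, M)                           # (N, F1, C, Mf)
        # dw[f, l] = sum_{n,c,t} x[n,c,t-pl+l] dy[n,f,c,t]
        cross = (self._Xf[:, None] * DYf.conj()).sum(axis=(0, 2))  # (F1, Mf)
        corr = fft.irfft(cross, M)
        self.dw = corr[:, (np.arange(L) - pl) % M]
        # dx[s] = sum_{f,t} dy[f,t] w[f, s - t + pl]  (a convolution)
        Wf = fft.rfft(self.w, M)
        conv = fft.irfft((DYf * Wf[None, :, None]).sum(axis=1), M)  # (N, C, M)
        return np.ascontiguousarray(conv[..., (np.arange(T) + pl) % M])

    def grads(self):
        return [("w", self.dw)]


class _DepthwiseSpatial:
    """One (C,) spatial filter per temporal feature map, depth multiplier D."""

    def __init__(self, F1, D, C, rng):
        limit = np.sqrt(6.0 / (C + C * D))
        self.w = rng.uniform(-limit, limit, size=(F1, D, C))

    def forward(self, x, training):
        # x: (N, F1, C, T) -> (N, F1*D, T)
        self._x = x
        y = np.einsum("nfct,fdc->nfdt", x, self.w, optimize=True)
        n, f1, d, t = y.shape
        return y.reshape(n, f1 * d, t)

    def backward(self, dy):
        n, fd, t = dy.shape
        F1, D, C = self.w.shape
        dy4 = dy.reshape(n, F1, D, t)
        self.dw = np.einsum("nfct,nfdt->fdc", self._x, dy4, optimize=True)
        return np.einsum("nfdt,fdc->nfct", dy4, self.w, optimize=True)

    def grads(self):
        return [("w", self.dw)]


class _SeparableConv:
    """Depthwise temporal kernel + pointwise channel mix."""

    def __init__(self, C_in, F2, L, rng):
        limit_d = np.sqrt(6.0 / (2 * L))
        self.wd = rng.uniform(-limit_d, limit_d, size=(C_in, L))
        limit_p = np.sqrt(6.0 / (C_in + F2))
        self.wp = rng.uniform(-limit_p, limit_p, size=(F2, C_in))
        self.b = np.zeros(F2)

    def forward(self, x, training):
        # x: (N, C_in, T)
        self._x = x
        C, L = self.wd.shape
        pl, pr = _same_pads(L)
        xp = np.pad(x, [(0, 0), (0, 0), (pl, pr)])
        win = sliding_window_view(xp, L, axis=-1)              # (N, C, T, L)
        self._depth = np.einsum("nctl,cl->nct", win, self.wd, optimize=True)
        y = np.einsum("nct,oc->not", self._depth, self.wp, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, dy):
        C, L = self.wd.shape
        pl, pr = _same_pads(L)
        self.db = dy.sum(axis=(0, 2))
        self.dwp = np.einsum("not,nct->oc", dy, self._depth, optimize=True)
        ddepth = np.einsum("not,oc->nct", dy, self.wp, optimize=True)
        xp = np.pad(self._x, [(0, 0), (0, 0), (pl, pr)])
        win = sliding_window_view(xp, L, axis=-1)
        self.dwd = np.einsum("nctl,nct->cl", win, ddepth, optimize=True)
        dp = np.pad(ddepth, [(0, 0), (0, 0), (pr, pl)])
        dwin = sliding_window_view(dp, L, axis=-1)
        return np.einsum("nctl,cl->nct", dwin, self.wd[:, ::-1], optimize=True)

    def grads(self):
        return [("wd", self.dwd), ("wp", self.dwp), ("b", self.db)]


class _BatchNorm:
    """Per-feature batch normalization over the remaining axes."""

    def __init__(self, n_features, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, training):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mean
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mean, var = self.run_mean, self.run_var
        self._axes, self._m = axes, x.size // x.shape[1]
        self._xhat = (x - mean.reshape(shp)) / np.sqrt(var.reshape(shp) + self.eps)
        self._std = np.sqrt(var + self.eps)
        return self.gamma.reshape(shp) * self._xhat + self.beta.reshape(shp)

    def backward(self, dy):
        shp = self._shape(dy)
        axes, m = self._axes, self._m
        self.dgamma = (dy * self._xhat).sum(axis=axes)
        self.dbeta = dy.sum(axis=axes)
        g = self.gamma.reshape(shp)
        std = self._std.reshape(shp)
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)) / std

    def grads(self):
        return [("gamma", self.dgamma), ("beta", self.dbeta)]

    @property
    def params_(self):
        return [("gamma", self.gamma), ("beta", self.beta)]


class _ELU:
    def __init__(self, alpha=1.0):
        self.alpha = alpha

    def forward(self, x, training):
        self._y = np.where(x > 0, x, self.alpha * np.expm1(x))
        return self._y

    def backward(self, dy):
        return dy * np.where(self._y > 0, 1.0, self._y + self.alpha)

    def grads(self):
        return []


class _AvgPool:
    def __init__(self, factor):
        self.p = factor

    def forward(self, x, training):
        T = x.shape[-1] - x.shape[-1] % self.p
        self._T_in = x.shape[-1]
        xt = x[..., :T]
        return xt.reshape(*x.shape[:-1], T // self.p, self.p).mean(axis=-1)

    def backward(self, dy):
        dx = np.repeat(dy, self.p, axis=-1) / self.p
        if dx.shape[-1] < self._T_in:
            pad = [(0, 0)] * (dx.ndim - 1) + [(0, self._T_in - dx.shape[-1])]
            dx = np.pad(dx, pad)
        return dx

    def grads(self):
        return []


class _Dropout:
    def __init__(self, rate, rng):
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    def grads(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x, training):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def grads(self):
        return [("w", self.dw), ("b", self.db)]


class _Flatten:
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)

    def grads(self):
        return []


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.state = {}
        self.t = 0

    def step(self, params_and_grads):
        self.t += 1
        for key, param, grad in params_and_grads:
            m, v = self.state.get(key, (np.zeros_like(param), np.zeros_like(param)))
            m = self.b1 * m + (1 - self.b1) * grad
            v = self.b2 * v + (1 - self.b2) * grad * grad
            self.state[key] = (m, v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class CompactCNN:
    """The assembled network; see the module docstring for the stages."""

    def __init__(self, spec: CompactCNNSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(rng.integers(2**31))
        F1, D, F2 = spec.F1, spec.depth_multiplier, spec.F2
        self.layers = [
            _TemporalConv(F1, spec.L, rng),
            _BatchNorm(F1),
            _DepthwiseSpatial(F1, D, spec.n_channels, rng),
            _BatchNorm(F1 * D),
            _ELU(),
            _AvgPool(spec.pool1),
            _Dropout(spec.dropout, self._drop_rng),
            _SeparableConv(F1 * D, F2, spec.separable_kernel, rng),
            _BatchNorm(F2),
            _ELU(),
            _AvgPool(spec.pool2),
            _Dropout(spec.dropout, self._drop_rng),
            _Flatten(),
        ]
        self._dense = None  # built lazily once the flattened size is known
        self._rng = rng
        self.history: list[float] = []
        self.classes_: np.ndarray | None = None

    # -- plumbing ----------------------------------------------------------
    def _ensure_dense(self, n_features: int):
        if self._dense is None:
            self._dense = _Dense(n_features, self.spec.n_classes, self._rng)
            self.layers.append(self._dense)

    def _forward(self, x, training):
        for layer in self.layers[:13]:
            x = layer.forward(x, training)
        self._ensure_dense(x.shape[1])
        return self._dense.forward(x, training)

    def _backward(self, dlogits):
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def _params_and_grads(self):
        out = []
        for i, layer in enumerate(self.layers):
            grads = dict(layer.grads())
            if not grads:
                continue
            params = (dict(layer.params_) if isinstance(layer, _BatchNorm)
                      else {k: getattr(layer, k) for k in grads})
            for name, grad in grads.items():
                out.append((f"{i}.{name}", params[name], grad))
        return out

    # -- API ---------------------------------------------------------------
    def fit(self, X: np.ndarray, y, sample_order_seed: int = 0) -> "CompactCNN":
        """Train on trials (N, C, T) with integer/float class labels."""
        X = np.asarray(X, dtype=np.float64)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < self.spec.n_classes:
            raise ValueError(
                f"training data covers {len(self.classes_)} of "
                f"{self.spec.n_classes} classes; every class must be present")
        # per-trial standardization keeps the unnormalized first layer stable
        X = (X - X.mean(axis=(1, 2), keepdims=True)) / (
            X.std(axis=(1, 2), keepdims=True) + 1e-12)
        n = X.shape[0]
        order_rng = np.random.default_rng(sample_order_seed)
        opt = _Adam(self.spec.learning_rate)
        best, stale = np.inf, 0
        for epoch in range(self.spec.max_epochs):
            perm = order_rng.permutation(n)
            losses = []
            for start in range(0, n, self.spec.batch_size):
                idx = perm[start:start + self.spec.batch_size]
                logits = self._forward(X[idx], training=True)
                probs = _softmax(logits)
                eps = 1e-12
                losses.append(-np.log(probs[np.arange(len(idx)),
                                            y_idx[idx]] + eps).mean())
                onehot = np.zeros_like(probs)
                onehot[np.arange(len(idx)), y_idx[idx]] = 1.0
                self._backward((probs - onehot) / len(idx))
                opt.step(self._params_and_grads())
            loss = float(np.mean(losses))
            self.history.append(loss)
            if loss < best - 1e-4:
                best, stale = loss, 0
            else:
                stale += 1
            if loss < 1e-3 or stale >= self.spec.patience:
                logger.info("early stop at epoch %d (loss %.4f)", epoch, loss)
                break
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        X = (X - X.mean(axis=(1, 2), keepdims=True)) / (
            X.std(axis=(1, 2), keepdims=True) + 1e-12)
        out = []
        for start in range(0, X.shape[0], self.spec.batch_size):
            logits = self._forward(X[start:start + self.spec.batch_size],
                                   training=False)
            out.append(_softmax(logits))
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def state_hash(self) -> str:
        """Digest of all weights — for determinism checks."""
        import hashlib

        h = hashlib.sha256()
        for key, param, _ in [(k, p, g) for (k, p, g) in self._params_and_grads()]:
            h.update(key.encode())
            h.update(np.ascontiguousarray(param).tobytes())
        return h.hexdigest()


def train_compact_cnn(X: np.ndarray, y, spec: CompactCNNSpec,
                      seed: int = 0) -> CompactCNN:
    """Train a :class:`CompactCNN` on labeled trials; deterministic in seed."""
    model = CompactCNN(spec, seed=seed)
    return model.fit(X, y, sample_order_seed=seed)
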