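"""Compact bidirectional LSTM sequence classifier in plain numpy.

Classifies raw event waveforms end-to-end (no feature engineering): stacked
bidirectional LSTM layers over the (end-padded, masked) sequence, masked
mean-pooling over time, and a logistic output unit, trained with Adam on
binary cross-entropy.  Padded steps are copy-through in both directions
(state is carried unchanged, and pooling ignores them), so predictions are
invariant to trailing padding beyond an event's true length.

The implementation is deliberately small and CPU-oriented: fixture-scale
corpora (a few thousand sequences of at most a few hundred samples) train in
well under a minute.  Gradients are hand-derived BPTT; a finite-difference
check lives in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ValidationError


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _LSTMLayer:
    """One direction of one LSTM layer (gate order: i, f, o, g)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_in + d_hidden)
        self.W = rng.uniform(-s, s, size=(d_in, 4 * d_hidden))
        self.U = rng.uniform(-s, s, size=(d_hidden, 4 * d_hidden))
        self.b = np.zeros(4 * d_hidden)
        self.b[d_hidden:2 * d_hidden] = 1.0  # forget-gate bias
        self.d_hidden = d_hidden

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray, mask: np.ndarray):
        """X: (N, T, D); mask: (N, T) in {0,1}. Returns H_seq (N, T, H)."""
        N, T, _ = X.shape
        H = self.d_hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        H_seq = np.zeros((N, T, H))
        cache = []
        for t in range(T):
            x_t = X[:, t]
            z = x_t @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            o = _sigmoid(z[:, 2 * H:3 * H])
            g = np.tanh(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t][:, None]
            cache.append((x_t, h, c, i, f, o, g, tc, m))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
            H_seq[:, t] = h
        self._cache = cache
        return H_seq

    def backward(self, X: np.ndarray, dH_seq: np.ndarray):
        """Returns (dX, [dW, dU, db]) given upstream dH_seq."""
        N, T, D = X.shape
        H = self.d_hidden
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, o, g, tc, m = self._cache[t]
            dh = dH_seq[:, t] + dh_next
            dh_new = dh * m
            dh_carry = dh * (1 - m)
            dc = dc_next
            dc_new = dc * m
            dc_carry = dc * (1 - m)
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc**2)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dc_prev = dc_new * f + dc_carry
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o),
                 dg * (1 - g**2)],
                axis=1,
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T + dh_carry
            dc_next = dc_prev
        return dX, [dW, dU, db]


class _BiLayer:
    """A bidirectional pair of LSTM directions; output is concatenated."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = _LSTMLayer(d_in, d_hidden, rng)
        self.bwd = _LSTMLayer(d_in, d_hidden, rng)

    def params(self):
        return self.fwd.params() + self.bwd.params()

    def forward(self, X, mask):
        Hf = self.fwd.forward(X, mask)
        Hb = self.bwd.forward(X[:, ::-1], mask[:, ::-1])[:, ::-1]
        self._X_rev = X[:, ::-1].copy()
        return np.concatenate([Hf, Hb], axis=2)

    def backward(self, X, dH):
        H = self.fwd.d_hidden
        dXf, gf = self.fwd.backward(X, dH[:, :, :H])
        dXb_rev, gb = self.bwd.backward(self._X_rev, dH[:, ::-1, H:])
        return dXf + dXb_rev[:, ::-1], gf + gb


@dataclass
class BiLSTMClassifier:
    """Binary sequence classifier over variable-length waveforms.

    Parameters
    ----------
    hidden_sizes
        Hidden units per bidirectional layer (two small layers by default).
    n_epochs, learning_rate, batch_size
        Adam training schedule; training stops early once the loss plateaus.
    seed
        Controls initialisation and batch shuffling; training is
        deterministic given the seed.
    """

    hidden_sizes: tuple[int, ...] = (16, 8)
    n_epochs: int = 80
    learning_rate: float = 1e-2
    batch_size: int = 256
    seed: int = 0
    patience: int = 30
    tol: float = 1e-5

    def _pad(self, waveforms) -> tuple[np.ndarray, np.ndarray]:
        lengths = [len(np.asarray(w).ravel()) for w in waveforms]
        if min(lengths) == 0:
            raise ParameterError("empty waveform in input")
        T = max(lengths)
        N = len(waveforms)
        X = np.zeros((N, T, 1))
        mask = np.zeros((N, T))
        for i, w in enumerate(waveforms):
            w = np.asarray(w, dtype=np.float64).ravel()
            X[i, :w.size, 0] = w
            mask[i, :w.size] = 1.0
        return X, mask

    def _forward(self, X, mask):
        out = X
        for layer in self.layers_:
            out = layer.forward(out, mask)
        denom = mask.sum(axis=1, keepdims=True)
        pooled = (out * mask[:, :, None]).sum(axis=1) / denom
        logits = pooled @ self.w_out_ + self.b_out_
        return out, pooled, logits

    def fit(self, waveforms, labels) -> "BiLSTMClassifier":
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if self.classes_.size != 2:
            raise ValidationError(
                f"binary classifier requires 2 classes, got {self.classes_.size}"
            )
        y = (labels == self.classes_[1]).astype(np.float64)
        X, mask = self._pad(waveforms)
        # standardise amplitudes over observed (unpadded) samples
        obs = X[mask.astype(bool)]
        self.x_mean_ = float(obs.mean())
        self.x_std_ = float(obs.std()) or 1.0
        X = np.where(mask[:, :, None] > 0, (X - self.x_mean_) / self.x_std_, 0.0)

        rng = np.random.default_rng(self.seed)
        self.layers_ = []
        d_in = 1
        for h in self.hidden_sizes:
            self.layers_.append(_BiLayer(d_in, h, rng))
            d_in = 2 * h
        self.w_out_ = rng.uniform(-0.1, 0.1, size=d_in)
        self.b_out_ = 0.0

        params = [p for layer in self.layers_ for p in layer.params()]
        params_out = [self.w_out_]
        m_adam = [np.zeros_like(p) for p in params] + [np.zeros(d_in), 0.0]
        v_adam = [np.zeros_like(p) for p in params] + [np.zeros(d_in), 0.0]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        best_loss, stale = np.inf, 0
        N = X.shape[0]
        self.loss_history_ = []
        for epoch in range(self.n_epochs):
            order = rng.permutation(N)
            epoch_loss = 0.0
            for lo in range(0, N, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                Xb, mb, yb = X[idx], mask[idx], y[idx]
                acts = [Xb]
                out = Xb
                for layer in self.layers_:
                    out = layer.forward(out, mb)
                    acts.append(out)
                denom = mb.sum(axis=1, keepdims=True)
                pooled = (out * mb[:, :, None]).sum(axis=1) / denom
                logits = pooled @ self.w_out_ + self.b_out_
                p = _sigmoid(logits)
                eps_p = 1e-12
                loss = -np.mean(
                    yb * np.log(p + eps_p) + (1 - yb) * np.log(1 - p + eps_p)
                )
                epoch_loss += loss * idx.size
                # backward
                dlogits = (p - yb) / idx.size
                dw_out = pooled.T @ dlogits
                db_out = dlogits.sum()
                dpooled = np.outer(dlogits, self.w_out_)
                dH = dpooled[:, None, :] * (mb[:, :, None] / denom[:, :, None])
                grads: list = []
                for li in reversed(range(len(self.layers_))):
                    dH, g = self.layers_[li].backward(acts[li], dH)
                    grads = g + grads
                grads = grads + [dw_out, db_out]
                # Adam update
                step += 1
                targets = params + [self.w_out_, None]
                for k, grad in enumerate(grads):
                    m_adam[k] = b1 * m_adam[k] + (1 - b1) * grad
                    v_adam[k] = b2 * v_adam[k] + (1 - b2) * np.square(grad)
                    mhat = m_adam[k] / (1 - b1**step)
                    vhat = v_adam[k] / (1 - b2**step)
                    delta = self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                    if k < len(params):
                        params[k] -= delta
                    elif k == len(params):
                        self.w_out_ -= delta
                    else:
                        self.b_out_ -= float(delta)
            epoch_loss /= N
            self.loss_history_.append(epoch_loss)
            if epoch_loss < best_loss - self.tol:
                best_loss, stale = epoch_loss, 0
            else:
                stale += 1
                if stale >= self.patience:
                    break
        return self

    def predict_proba(self, waveforms) -> np.ndarray:
        """Probability of the second class (``classes_[1]``) per waveform."""
        X, mask = self._pad(waveforms)
        X = np.where(mask[:, :, None] > 0, (X - self.x_mean_) / self.x_std_, 0.0)
        _, _, logits = self._forward(X, mask)
        return _sigmoid(logits)

    def predict(self, waveforms) -> np.ndarray:
        p = self.predict_proba(waveforms)
        return np.where(p > 0.5, self.classes_[1], self.classes_[0])
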