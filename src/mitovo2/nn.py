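"""A small bidirectional-LSTM sequence labeler, implemented on numpy.

The network is the per-sample classifier used for start-point detection:
a scalar input sequence runs through an LSTM forward and another backward,
their hidden states are concatenated per time step, and a shared linear
layer plus softmax yields a probability over the three point classes.
Training is mini-batch Adam on the per-sample cross-entropy, with global
gradient-norm clipping; everything is driven by an explicit seeded
generator so that retraining reproduces weights bit for bit.

Shapes follow the convention ``X: (batch, time, features)``,
``targets: (batch, time)`` as integer classes, with an optional boolean
weight mask to exclude padded samples from the loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMNetwork"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _LSTMDirection:
    """One direction of the biLSTM: weights plus forward/backward passes.

    Gate layout along the 4H axis is (input, forget, cell, output).
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(hidden)
        self.Wx = rng.uniform(-k, k, (4 * hidden, n_in))
        self.Wh = rng.uniform(-k, k, (4 * hidden, hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden: 2 * hidden] = 1.0  # forget-gate bias
        self.H = hidden

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, reverse: bool):
        B, T, _ = X.shape
        H = self.H
        order = range(T - 1, -1, -1) if reverse else range(T)
        Xp = X @ self.Wx.T + self.b  # (B,T,4H)
        gates = np.empty((T, B, 4 * H))
        cells = np.empty((T, B, H))
        hidden = np.empty((T, B, H))
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        for t in order:
            a = Xp[:, t] + h @ self.Wh.T
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H: 2 * H])
            g = np.tanh(a[:, 2 * H: 3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t] = np.concatenate([i, f, g, o], axis=1)
            cells[t] = c
            hidden[t] = h
        cache = (X, gates, cells, hidden, reverse)
        return hidden.transpose(1, 0, 2), cache  # (B,T,H)

    def backward(self, dH_seq: np.ndarray, cache):
        """dH_seq: (B,T,H) gradient w.r.t. this direction's hidden states."""
        X, gates, cells, hidden, reverse = cache
        B, T, _ = X.shape
        H = self.H
        order = range(T) if reverse else range(T - 1, -1, -1)
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        first = T - 1 if reverse else 0  # time step with zero-state input
        for t in order:
            i = gates[t][:, :H]
            f = gates[t][:, H: 2 * H]
            g = gates[t][:, 2 * H: 3 * H]
            o = gates[t][:, 3 * H:]
            c = cells[t]
            if t == first:
                c_prev = np.zeros((B, H))
                h_prev = np.zeros((B, H))
            else:
                prev_t = t + 1 if reverse else t - 1
                c_prev = cells[prev_t]
                h_prev = hidden[prev_t]
            dh = dH_seq[:, t] + dh_next
            tc = np.tanh(c)
            dc = dh * o * (1.0 - tc * tc) + dc_next
            da = np.concatenate([
                dc * g * i * (1.0 - i),
                dc * c_prev * f * (1.0 - f),
                dc * i * (1.0 - g * g),
                dh * tc * o * (1.0 - o),
            ], axis=1)
            dWx += da.T @ X[:, t]
            dWh += da.T @ h_prev
            db += da.sum(axis=0)
            dh_next = da @ self.Wh
            dc_next = dc * f
        return [dWx, dWh, db]


class BiLSTMNetwork:
    """biLSTM -> per-sample linear layer -> softmax over three classes."""

    def __init__(self, hidden_units: int, n_classes: int = 3,
                 n_features: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden_units = hidden_units
        self.n_classes = n_classes
        self.fwd = _LSTMDirection(n_features, hidden_units, rng)
        self.bwd = _LSTMDirection(n_features, hidden_units, rng)
        k = 1.0 / np.sqrt(2 * hidden_units)
        self.Wo = rng.uniform(-k, k, (n_classes, 2 * hidden_units))
        self.bo = np.zeros(n_classes)

    # --- parameter plumbing -------------------------------------------------
    def params(self) -> list[np.ndarray]:
        return self.fwd.params() + self.bwd.params() + [self.Wo, self.bo]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w

    # --- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, with_cache: bool = False):
        Hf, cf = self.fwd.forward(X, reverse=False)
        Hb, cb = self.bwd.forward(X, reverse=True)
        Hcat = np.concatenate([Hf, Hb], axis=2)  # (B,T,2H)
        logits = Hcat @ self.Wo.T + self.bo
        logits -= logits.max(axis=2, keepdims=True)
        ex = np.exp(logits)
        probs = ex / ex.sum(axis=2, keepdims=True)
        if with_cache:
            return probs, (cf, cb, Hcat)
        return probs

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # --- loss and gradients -------------------------------------------------
    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray,
                       weight: np.ndarray | None = None):
        """Mean per-sample cross-entropy and gradients for all parameters.

        ``Y`` holds integer classes, ``weight`` an optional (B,T) mask
        (padded samples get weight 0).
        """
        B, T, _ = X.shape
        probs, (cf, cb, Hcat) = self.forward(X, with_cache=True)
        if weight is None:
            weight = np.ones((B, T))
        wsum = weight.sum()
        py = np.take_along_axis(probs, Y[..., None], axis=2)[..., 0]
        loss = float(-(weight * np.log(np.clip(py, 1e-12, None))).sum() / wsum)

        dlogits = probs.copy()
        np.put_along_axis(dlogits, Y[..., None],
                          np.take_along_axis(dlogits, Y[..., None], axis=2) - 1.0,
                          axis=2)
        dlogits *= (weight / wsum)[..., None]
        dWo = np.einsum("btc,bth->ch", dlogits, Hcat)
        dbo = dlogits.sum(axis=(0, 1))
        dHcat = dlogits @ self.Wo
        H = self.hidden_units
        g_f = self.fwd.backward(dHcat[:, :, :H], cf)
        g_b = self.bwd.backward(dHcat[:, :, H:], cb)
        return loss, g_f + g_b + [dWo, dbo]

    # --- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, Y: np.ndarray, weight: np.ndarray | None,
            learn_rate: float, epochs: int, batch_size: int,
            rng: np.random.Generator, clip_norm: float = 1.0) -> list[float]:
        """Adam training over shuffled mini-batches; returns per-batch losses."""
        n = X.shape[0]
        params = self.params()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        losses: list[float] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, batch_size):
                idx = order[lo: lo + batch_size]
                w = None if weight is None else weight[idx]
                loss, grads = self.loss_and_grads(X[idx], Y[idx], w)
                losses.append(loss)
                gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads))
                if gnorm > clip_norm:
                    grads = [g * (clip_norm / gnorm) for g in grads]
                step += 1
                corr = np.sqrt(1.0 - b2 ** step) / (1.0 - b1 ** step)
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= b1
                    mi += (1 - b1) * g
                    vi *= b2
                    vi += (1 - b2) * g * g
                    p -= learn_rate * corr * mi / (np.sqrt(vi) + eps)
        return losses
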