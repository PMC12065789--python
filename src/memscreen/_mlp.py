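"""Minimal feed-forward regressor: ReLU hidden layers, linear output,
mean-absolute-error loss, Adam optimizer.

Implemented directly on numpy so the ensemble's training recipe (per-member
architecture, batch size, fixed epoch count, lr 1e-3) is fully controlled
and seeded.  Weights use He initialization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLPRegressor"]


class MLPRegressor:
    def __init__(self, hidden_layers, lr=1e-3, batch_size=32, epochs=100, seed=0):
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.lr = float(lr)
        self.batch_size = int(batch_size)
        self.epochs = int(epochs)
        self.seed = int(seed)
        self._params = None

    def _init_params(self, n_in):
        rng = np.random.default_rng(self.seed)
        sizes = [n_in, *self.hidden_layers, 1]
        W, b = [], []
        for a, c in zip(sizes[:-1], sizes[1:]):
            W.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, c)))
            b.append(np.zeros(c))
        return W, b

    def _forward(self, X, W, b):
        acts = [X]
        h = X
        for i in range(len(W) - 1):
            h = np.maximum(h @ W[i] + b[i], 0.0)
            acts.append(h)
        out = h @ W[-1] + b[-1]
        return out[:, 0], acts

    def fit(self, X, y):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        n = X.shape[0]
        W, b = self._init_params(X.shape[1])
        # Adam state
        mW = [np.zeros_like(w) for w in W]
        vW = [np.zeros_like(w) for w in W]
        mb = [np.zeros_like(v) for v in b]
        vb = [np.zeros_like(v) for v in b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        rng = np.random.default_rng(self.seed + 1)
        bs = min(self.batch_size, n)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for s in range(0, n, bs):
                idx = order[s : s + bs]
                Xb, yb = X[idx], y[idx]
                pred, acts = self._forward(Xb, W, b)
                m = len(idx)
                # dL/dpred for MAE
                g = np.sign(pred - yb)[:, None] / m
                gW = [None] * len(W)
                gb = [None] * len(b)
                delta = g
                for i in range(len(W) - 1, -1, -1):
                    gW[i] = acts[i].T @ delta
                    gb[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = (delta @ W[i].T) * (acts[i] > 0)
                t += 1
                corr1 = 1 - beta1**t
                corr2 = 1 - beta2**t
                for i in range(len(W)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    W[i] -= self.lr * (mW[i] / corr1) / (np.sqrt(vW[i] / corr2) + eps)
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    b[i] -= self.lr * (mb[i] / corr1) / (np.sqrt(vb[i] / corr2) + eps)
        self._params = (W, b)
        return self

    def predict(self, X):
        if self._params is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, float)
        pred, _ = self._forward(X, *self._params)
        return pred
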