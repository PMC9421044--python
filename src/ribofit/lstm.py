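"""A small LSTM regressor for fixed-length nucleotide sequences, in NumPy.

One recurrent layer reads the sequence left to right; the final hidden state
h_n summarizes the whole sequence and doubles as a learned feature vector
for downstream regressors. Training is supervised against the scalar
activity target with mean-squared-error loss, minibatch Adam, and inverted
dropout applied to h_n before the linear head. Gate layout follows the
common (input, forget, cell, output) convention; recurrent weights are
initialized uniform in ±1/sqrt(hidden_dim); the nucleotide embedding is a
learned 4-vector per symbol initialized from the one-hot basis, so the
untrained network sees exactly the one-hot representation.

Everything is seeded: weight init, batch shuffling, and dropout masks all
derive from one integer, so training is bit-reproducible on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class LSTMConfig:
    hidden_dim: int = 32
    dropout: float = 0.2
    embedding_dim: int = 4
    batch_size: int = 64
    epochs: int = 25
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_dim, self.embedding_dim, self.batch_size, self.epochs) < 1:
            raise ValueError("hidden_dim, embedding_dim, batch_size, epochs must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LSTMRegressor:
    """LSTM + linear head trained with Adam on (sequence, activity) pairs."""

    PARAM_NAMES = ("E", "Wx", "Wh", "b", "w_out", "b_out")

    def __init__(self, cfg: LSTMConfig, n_symbols: int = 4):
        self.cfg = cfg
        self.n_symbols = n_symbols
        H, D = cfg.hidden_dim, cfg.embedding_dim
        rng = np.random.default_rng(cfg.seed)
        k = 1.0 / np.sqrt(H)
        if D == n_symbols:
            E = np.eye(n_symbols)
        else:
            E = rng.uniform(-k, k, size=(n_symbols, D))
        self.params: dict[str, np.ndarray] = {
            "E": E,
            "Wx": rng.uniform(-k, k, size=(D, 4 * H)),
            "Wh": rng.uniform(-k, k, size=(H, 4 * H)),
            "b": rng.uniform(-k, k, size=(4 * H,)),
            "w_out": rng.uniform(-k, k, size=(H,)),
            "b_out": np.zeros(1),
        }
        self._rng = rng
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []

    # -- forward -----------------------------------------------------------

    def _forward(self, X: np.ndarray, keep_cache: bool = False):
        """Run the recurrence over a batch of index sequences (B x T)."""
        P = self.params
        B, T = X.shape
        H = self.cfg.hidden_dim
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = [] if keep_cache else None
        for t in range(T):
            x = P["E"][X[:, t]]  # B x D
            z = x @ P["Wx"] + h @ P["Wh"] + P["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            h_prev = h
            h = o * np.tanh(c)
            if keep_cache:
                cache.append((X[:, t], i, f, g, o, c, c_prev, h_prev))
        return h, cache

    def hidden_features(self, X: np.ndarray) -> np.ndarray:
        """Final hidden state h_n per sequence (evaluation mode, no dropout)."""
        X = np.asarray(X, dtype=np.int64)
        if X.ndim != 2:
            raise ValueError("expected a B x T array of symbol indices")
        h, _ = self._forward(X)
        return h

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Head output on h_n (evaluation mode)."""
        h = self.hidden_features(X)
        return h @ self.params["w_out"] + self.params["b_out"][0]

    # -- backward ----------------------------------------------------------

    def _backward(self, X, cache, dh_last):
        P = self.params
        H = self.cfg.hidden_dim
        grads = {k_: np.zeros_like(v) for k_, v in P.items()}
        dh = dh_last
        dc = np.zeros_like(dh)
        for t in range(X.shape[1] - 1, -1, -1):
            idx, i, f, g, o, c, c_prev, h_prev = cache[t]
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            x = P["E"][idx]
            grads["Wx"] += x.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dx = dz @ P["Wx"].T
            np.add.at(grads["E"], idx, dx)
            dh = dz @ P["Wh"].T
            dc = dc * f
        return grads

    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.cfg.learning_rate, 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        for k_, g in grads.items():
            self._adam_m[k_] = b1 * self._adam_m[k_] + (1 - b1) * g
            self._adam_v[k_] = b2 * self._adam_v[k_] + (1 - b2) * g**2
            m_hat = self._adam_m[k_] / (1 - b1**t)
            v_hat = self._adam_v[k_] / (1 - b2**t)
            self.params[k_] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def train_batch(self, X: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on a minibatch; returns the batch MSE."""
        P = self.params
        h, cache = self._forward(X, keep_cache=True)
        if self.cfg.dropout > 0.0:
            mask = (
                self._rng.random(h.shape) >= self.cfg.dropout
            ) / (1.0 - self.cfg.dropout)
        else:
            mask = np.ones_like(h)
        h_drop = h * mask
        yhat = h_drop @ P["w_out"] + P["b_out"][0]
        resid = yhat - y
        loss = float(np.mean(resid**2))
        dyhat = 2.0 * resid / len(y)
        grads_head = {
            "w_out": h_drop.T @ dyhat,
            "b_out": np.array([dyhat.sum()]),
        }
        dh_last = np.outer(dyhat, P["w_out"]) * mask
        grads = self._backward(X, cache, dh_last)
        grads["w_out"] = grads_head["w_out"]
        grads["b_out"] = grads_head["b_out"]
        self._adam_step(grads)
        return loss

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        """Minibatch training for cfg.epochs epochs over shuffled data."""
        X = np.asarray(X, dtype=np.int64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be B x T aligned with y")
        n = len(X)
        bs = self.cfg.batch_size
        for _ in range(self.cfg.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, bs):
                sel = order[start : start + bs]
                epoch_loss += self.train_batch(X[sel], y[sel])
                n_batches += 1
            self.loss_history.append(epoch_loss / max(n_batches, 1))
        return self

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            **self.params,
            _hidden_dim=self.cfg.hidden_dim,
            _dropout=self.cfg.dropout,
            _embedding_dim=self.cfg.embedding_dim,
            _batch_size=self.cfg.batch_size,
            _epochs=self.cfg.epochs,
            _learning_rate=self.cfg.learning_rate,
            _seed=self.cfg.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSTMRegressor":
        data = np.load(path)
        cfg = LSTMConfig(
            hidden_dim=int(data["_hidden_dim"]),
            dropout=float(data["_dropout"]),
            embedding_dim=int(data["_embedding_dim"]),
            batch_size=int(data["_batch_size"]),
            epochs=int(data["_epochs"]),
            learning_rate=float(data["_learning_rate"]),
            seed=int(data["_seed"]),
        )
        net = cls(cfg)
        for name in cls.PARAM_NAMES:
            net.params[name] = data[name]
        return net
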