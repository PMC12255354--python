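"""A small sequence-to-sequence LSTM autoencoder in NumPy.

Architecture: three stacked LSTM encoder layers of strictly decreasing width,
the last hidden state repeated along time as the bottleneck code, three
mirrored decoder layers of increasing width, and a time-distributed one-unit
sigmoid readout.  Trained with mini-batch Adam on mean-squared reconstruction
error.  Everything is float32 and driven by a single seeded Generator, so a
fixed seed reproduces the training trajectory bit-for-bit on one machine.

Backpropagation through time is implemented directly: the input projections
``X @ Wx`` are batched over all timesteps in one GEMM per layer, and the
per-step recurrence only adds the ``h @ Wh`` term, which keeps the Python-loop
overhead acceptable for 160-step sequences on a single CPU core.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

_DT = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # Plain logistic; float32 exp overflow saturates to 0/1 which is exactly
    # the limit value, so no masking is needed.
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


class _LSTMLayer:
    """Single LSTM layer (gate order i, f, g, o; forget-gate bias 1)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + 4 * n_units))
        self.Wx = rng.uniform(-limit, limit, size=(n_in, 4 * n_units)).astype(_DT)
        blocks = []
        for _ in range(4):
            q, _r = np.linalg.qr(rng.standard_normal((n_units, n_units)))
            blocks.append(q)
        self.Wh = np.concatenate(blocks, axis=1).astype(_DT)
        self.b = np.zeros(4 * n_units, dtype=_DT)
        self.b[n_units : 2 * n_units] = 1.0
        self.n_in = n_in
        self.n_units = n_units
        self._cache = None

    @property
    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, keep_cache: bool = True) -> np.ndarray:
        """X: (B, T, n_in) -> hidden sequence (B, T, n_units)."""
        B, T, _ = X.shape
        H = self.n_units
        zx = X.reshape(B * T, self.n_in) @ self.Wx
        zx = zx.reshape(B, T, 4 * H) + self.b
        h = np.zeros((B, H), dtype=_DT)
        c = np.zeros((B, H), dtype=_DT)
        Hs = np.empty((B, T, H), dtype=_DT)
        if keep_cache:
            gates = np.empty((B, T, 4 * H), dtype=_DT)  # i, f, g, o post-activation
            Cs = np.empty((B, T, H), dtype=_DT)
            Hprev = np.empty((B, T, H), dtype=_DT)
            Cprev = np.empty((B, T, H), dtype=_DT)
        for t in range(T):
            z = zx[:, t] + h @ self.Wh
            # sigmoid on the i,f block and the o block, tanh on the g block
            z[:, : 2 * H] = _sigmoid(z[:, : 2 * H])
            z[:, 3 * H :] = _sigmoid(z[:, 3 * H :])
            np.tanh(z[:, 2 * H : 3 * H], out=z[:, 2 * H : 3 * H])
            i = z[:, :H]
            f = z[:, H : 2 * H]
            g = z[:, 2 * H : 3 * H]
            o = z[:, 3 * H :]
            if keep_cache:
                Hprev[:, t] = h
                Cprev[:, t] = c
                gates[:, t] = z
            c = f * c + i * g
            h = o * np.tanh(c)
            Hs[:, t] = h
            if keep_cache:
                Cs[:, t] = c
        if keep_cache:
            self._cache = (X, gates, Cs, Hprev, Cprev)
        return Hs

    def backward(
        self, dHs: np.ndarray, dh_last: Optional[np.ndarray] = None
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Gradients given upstream d(hidden sequence) and optional d(last h)."""
        X, gates, Cs, Hprev, Cprev = self._cache
        B, T, _ = X.shape
        H = self.n_units
        dz_all = np.empty((B, T, 4 * H), dtype=_DT)
        dWh = np.zeros_like(self.Wh)
        dh_next = np.zeros((B, H), dtype=_DT)
        dc_next = np.zeros((B, H), dtype=_DT)
        if dh_last is not None:
            dh_next = dh_next + dh_last.astype(_DT)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = np.tanh(Cs[:, t])
            dh = dHs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * Cprev[:, t]
            dg = dc * i
            dz = dz_all[:, t]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            dWh += Hprev[:, t].T @ dz
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        dz_flat = dz_all.reshape(B * T, 4 * H)
        dWx = X.reshape(B * T, self.n_in).T @ dz_flat
        db = dz_flat.sum(axis=0)
        dX = (dz_flat @ self.Wx.T).reshape(B, T, self.n_in)
        self._cache = None
        return dX, [dWx, dWh, db]


class _Adam:
    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-7
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.beta2**self.t) / (1.0 - self.beta1**self.t)
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= _DT(lr_t) * m / (np.sqrt(v) + self.eps)


class LSTMAutoencoder:
    """Sequence autoencoder: 3 LSTM encoder layers, bottleneck, 3 decoder layers.

    Parameters
    ----------
    encoder_units : three strictly decreasing layer widths; the decoder mirrors
        them in reverse.
    seq_len : input sequence length (one feature per step).
    """

    def __init__(
        self,
        encoder_units: Sequence[int] = (32, 16, 8),
        seq_len: int = 160,
        learning_rate: float = 3e-3,
        batch_size: int = 256,
        epochs: int = 20,
        seed: int = 0,
    ):
        encoder_units = tuple(int(u) for u in encoder_units)
        if len(encoder_units) != 3 or not (
            encoder_units[0] > encoder_units[1] > encoder_units[2] > 0
        ):
            raise ValueError("encoder_units must be three strictly decreasing widths")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        self.encoder_units = encoder_units
        self.decoder_units = tuple(reversed(encoder_units))
        self.seq_len = int(seq_len)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.epochs = int(epochs)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        u1, u2, u3 = self.encoder_units
        self.enc = [
            _LSTMLayer(1, u1, rng),
            _LSTMLayer(u1, u2, rng),
            _LSTMLayer(u2, u3, rng),
        ]
        self.dec = [
            _LSTMLayer(u3, u3, rng),
            _LSTMLayer(u3, u2, rng),
            _LSTMLayer(u2, u1, rng),
        ]
        limit = np.sqrt(6.0 / (u1 + 1))
        self.Wd = rng.uniform(-limit, limit, size=(u1, 1)).astype(_DT)
        self.bd = np.zeros(1, dtype=_DT)
        self._rng = rng
        self.history_: list[float] = []

    # -- plumbing ---------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for layer in self.enc + self.dec:
            out.extend(layer.params)
        out.extend([self.Wd, self.bd])
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w

    # -- forward / backward ----------------------------------------------
    def _forward(self, X3: np.ndarray, keep_cache: bool) -> np.ndarray:
        B, T, _ = X3.shape
        h = X3
        for layer in self.enc:
            h = layer.forward(h, keep_cache=keep_cache)
        code = h[:, -1, :]
        rep = np.broadcast_to(code[:, None, :], (B, T, code.shape[1])).copy()
        h = rep
        for layer in self.dec:
            h = layer.forward(h, keep_cache=keep_cache)
        y = _sigmoid(h.reshape(B * T, -1) @ self.Wd + self.bd).reshape(B, T, 1)
        if keep_cache:
            self._cache_dense_in = h
            self._cache_y = y
        return y

    def _backward(self, X3: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        B, T, _ = X3.shape
        Hd = self._cache_dense_in
        dy = (2.0 / y.size) * (y - X3)
        dz = (dy * y * (1.0 - y)).reshape(B * T, 1).astype(_DT)
        Hd_flat = Hd.reshape(B * T, -1)
        dWd = Hd_flat.T @ dz
        dbd = dz.sum(axis=0)
        dH = (dz @ self.Wd.T).reshape(B, T, -1)
        dec_grads: list[list[np.ndarray]] = []
        for layer in reversed(self.dec):
            dH, grads = layer.backward(dH)
            dec_grads.append(grads)
        dcode = dH.sum(axis=1)
        zero_seq = np.zeros(
            (B, T, self.enc[-1].n_units), dtype=_DT
        )
        enc_grads: list[list[np.ndarray]] = []
        dH_enc, grads = self.enc[-1].backward(zero_seq, dh_last=dcode)
        enc_grads.append(grads)
        for layer in (self.enc[1], self.enc[0]):
            dH_enc, grads = layer.backward(dH_enc)
            enc_grads.append(grads)
        all_grads: list[np.ndarray] = []
        for grads in reversed(enc_grads):
            all_grads.extend(grads)
        for grads in reversed(dec_grads):
            all_grads.extend(grads)
        all_grads.extend([dWd, dbd])
        return all_grads

    # -- public API -------------------------------------------------------
    def fit(self, X: np.ndarray) -> "LSTMAutoencoder":
        """Train on (n, seq_len) scaled vectors; records epoch losses."""
        X = np.asarray(X, dtype=_DT)
        if X.ndim != 2 or X.shape[1] != self.seq_len:
            raise ValueError(f"X must have shape (n, {self.seq_len})")
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        n = X.shape[0]
        opt = _Adam(self.params, lr=self.learning_rate)
        for _epoch in range(self.epochs):
            order = self._rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][:, :, None]
                y = self._forward(xb, keep_cache=True)
                losses.append(float(np.mean((y - xb) ** 2)))
                grads = self._backward(xb, y)
                opt.step(grads)
            self.history_.append(float(np.mean(losses)))
        return self

    def predict(self, X: np.ndarray, batch_size: Optional[int] = None) -> np.ndarray:
        """Reconstructions for (n, seq_len) vectors, same shape out."""
        X = np.asarray(X, dtype=_DT)
        if X.ndim != 2 or X.shape[1] != self.seq_len:
            raise ValueError(f"X must have shape (n, {self.seq_len})")
        bs = batch_size or max(self.batch_size, 1)
        outs = []
        for start in range(0, X.shape[0], bs):
            xb = X[start : start + bs][:, :, None]
            outs.append(self._forward(xb, keep_cache=False)[:, :, 0])
        return (
            np.concatenate(outs, axis=0)
            if outs
            else np.empty((0, self.seq_len), dtype=_DT)
        )

    def reconstruction_errors(self, X: np.ndarray) -> np.ndarray:
        """Per-vector mean squared reconstruction error (float64)."""
        recon = self.predict(X).astype(np.float64)
        X64 = np.asarray(X, dtype=_DT).astype(np.float64)
        return np.mean((recon - X64) ** 2, axis=1)
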