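"""Minimal NumPy neural-network engine for stacked-LSTM sequence regression.

Implements exactly what the regressor needs — LSTM layers with full
backpropagation through time, a linear dense output, Glorot-normal
initialization, minibatch Adam and mean-squared-error loss — with no
framework dependency. Gradients are exact (verified against central finite
differences in the test suite), and the trainable-parameter count follows
the closed form 4*(u*(f+u)+u) per LSTM layer plus (u_last + 1) for the
single-output dense layer.

Implementation notes: sequences are processed feature-major internally,
as (T, features, batch) arrays, so every per-step gate block is a
contiguous slice and the elementwise kernels run on contiguous memory;
the input projection for all time steps is one stacked GEMM and only the
recurrent term is sequential. The fused gate layout is
[input, forget, output | cell] so the three sigmoid gates form one block;
sigmoid is evaluated as (1 + tanh(z/2)) / 2 to reuse the SIMD-vectorized
tanh. The forget-gate bias is initialized to 1 (the standard
stabilization); other biases start at zero, and both the input and
recurrent kernels use Glorot-normal draws.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMLayer", "DenseLayer", "LSTMRegressor", "Adam",
           "glorot_normal", "lstm_param_count"]


def glorot_normal(rng: np.random.Generator, fan_in: int, fan_out: int,
                  shape: tuple[int, ...], dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, size=shape).astype(dtype)


def lstm_param_count(units: int, features: int) -> int:
    """Closed-form trainable-parameter count of one LSTM layer."""
    return 4 * (units * (features + units) + units)


def orthogonal(rng: np.random.Generator, n: int, m: int,
               dtype=np.float32) -> np.ndarray:
    """Random orthogonal (n, m) matrix via QR, sign-fixed."""
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if n < m:
        q = q.T
    return q[:n, :m].astype(dtype)


def _sigmoid_inplace(z: np.ndarray, out: np.ndarray) -> None:
    """sigmoid(z) = (1 + tanh(z/2)) / 2 into ``out`` (may alias ``z``)."""
    np.multiply(z, 0.5, out=out)
    np.tanh(out, out=out)
    out += 1.0
    out *= 0.5


class LSTMLayer:
    """One LSTM layer over feature-major (T, features, B) inputs.

    Weights use the conventional shapes W (features, 4*units),
    U (units, 4*units), b (4*units,); transposed contiguous copies are
    made per pass for the feature-major GEMMs.
    """

    def __init__(self, units: int, features: int, return_sequences: bool,
                 rng: np.random.Generator, dtype=np.float32):
        self.units = units
        self.features = features
        self.return_sequences = return_sequences
        self.dtype = dtype
        u, f = units, features
        self.W = glorot_normal(rng, f, 4 * u, (f, 4 * u), dtype)   # input kernel
        # recurrent kernel: per-gate orthogonal blocks (the recurrent
        # default of the reference toolchain; Glorot applies to W)
        self.U = np.concatenate(
            [orthogonal(rng, u, u, dtype) for _ in range(4)], axis=1)
        self.b = np.zeros(4 * u, dtype=dtype)
        self.b[u:2 * u] = 1.0  # forget-gate bias
        # reusable buffers keyed by (T, B, kind); avoids per-batch page faults
        self._ws: dict[tuple, dict[str, np.ndarray]] = {}

    def _buffers(self, T: int, B: int, kind: str,
                 names_shapes: list[tuple[str, tuple[int, ...]]]
                 ) -> dict[str, np.ndarray]:
        key = (T, B, kind)
        ws = self._ws.get(key)
        if ws is None:
            ws = {n: np.empty(s, dtype=self.dtype) for n, s in names_shapes}
            if len(self._ws) > 8:   # bound the cache across batch-size changes
                self._ws.clear()
            self._ws[key] = ws
        return ws

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.U, self.b]

    def param_count(self) -> int:
        return sum(p.size for p in self.params)

    def forward(self, X: np.ndarray, cache: bool = False):
        """Run the layer on (T, f, B) input; returns (T, u, B) hidden states.

        With ``cache=True`` the per-step gates and cell states are stored
        for BPTT; without it only the hidden sequence is materialized.
        """
        T, f, B = X.shape
        u = self.units
        WT = np.ascontiguousarray(self.W.T)
        UT = np.ascontiguousarray(self.U.T)
        b2 = self.b[:, None]
        Z = np.matmul(WT, X)                    # (T, 4u, B), one GEMM per step
        if cache:
            ws = self._buffers(T, B, "fwd", [
                ("G", (T, 4 * u, B)), ("C", (T, u, B)), ("Hc", (T, u, B)),
                ("H", (T, u, B)), ("zr", (4 * u, B)), ("tmp", (u, B)),
                ("h0", (u, B)), ("c0", (u, B))])
        else:
            ws = self._buffers(T, B, "pred", [
                ("gt", (4 * u, B)), ("ct", (u, B)), ("hc", (u, B)),
                ("H", (T, u, B)), ("zr", (4 * u, B)), ("tmp", (u, B)),
                ("h0", (u, B)), ("c0", (u, B))])
        H = ws["H"]
        zr, tmp = ws["zr"], ws["tmp"]
        h = ws["h0"]
        h[:] = 0.0
        c = ws["c0"]
        c[:] = 0.0
        for t in range(T):
            z = Z[t]
            np.matmul(UT, h, out=zr)
            z += zr
            z += b2
            gt = ws["G"][t] if cache else ws["gt"]
            _sigmoid_inplace(z[:3 * u], gt[:3 * u])     # i, f, o
            np.tanh(z[3 * u:], out=gt[3 * u:])          # cell candidate
            i = gt[:u]
            fg = gt[u:2 * u]
            o = gt[2 * u:3 * u]
            g = gt[3 * u:]
            ct = ws["C"][t] if cache else ws["ct"]
            np.multiply(fg, c, out=ct)
            np.multiply(i, g, out=tmp)
            ct += tmp
            hc = ws["Hc"][t] if cache else ws["hc"]
            np.tanh(ct, out=hc)
            np.multiply(o, hc, out=H[t])
            h = H[t]
            c = ct
        if cache:
            return H, (X, ws["G"], ws["C"], ws["Hc"], H)
        return H

    def backward(self, cache, dH: np.ndarray):
        """BPTT given upstream gradient dH (T, u, B); dH is consumed.

        Returns (dX, [dW, dU, db]) with dX feature-major like the input.
        """
        X, G, C, Hc, H = cache
        T, f, B = X.shape
        u = self.units
        ws = self._buffers(T, B, "bwd", [
            ("dG", (T, 4 * u, B)), ("dct", (u, B)), ("dc", (u, B)),
            ("t1", (u, B)), ("dhn", (u, B)), ("mUT", (4 * u, u))])
        dG, dct, dc, t1 = ws["dG"], ws["dct"], ws["dc"], ws["t1"]
        mUT = ws["mUT"]
        dc[:] = 0.0
        dUT = np.zeros((4 * u, u), dtype=self.dtype)
        dh_next = None
        for t in range(T - 1, -1, -1):
            gt = G[t]
            i = gt[:u]
            fg = gt[u:2 * u]
            o = gt[2 * u:3 * u]
            g = gt[3 * u:]
            hc = Hc[t]
            dh = dH[t]
            if dh_next is not None:
                dh += dh_next
            # dct = dh * o * (1 - hc^2) + dc
            np.multiply(hc, hc, out=dct)
            np.subtract(1.0, dct, out=dct)
            dct *= o
            dct *= dh
            dct += dc
            dz = dG[t]
            # input gate: dct * g * i * (1 - i)
            di = dz[:u]
            np.subtract(1.0, i, out=di)
            di *= i
            np.multiply(dct, g, out=t1)
            di *= t1
            # forget gate: dct * c_prev * f * (1 - f); c_prev = 0 at t = 0
            df = dz[u:2 * u]
            if t > 0:
                np.subtract(1.0, fg, out=df)
                df *= fg
                np.multiply(dct, C[t - 1], out=t1)
                df *= t1
            else:
                df[:] = 0.0
            # output gate: dh * hc * o * (1 - o)
            do = dz[2 * u:3 * u]
            np.subtract(1.0, o, out=do)
            do *= o
            do *= hc
            do *= dh
            # cell candidate: dct * i * (1 - g^2)
            dg = dz[3 * u:]
            np.multiply(g, g, out=dg)
            np.subtract(1.0, dg, out=dg)
            dg *= i
            dg *= dct
            dh_next = ws["dhn"]
            np.matmul(self.U, dz, out=dh_next)   # (u, B)
            np.multiply(dct, fg, out=dc)
            if t > 0:
                np.matmul(dz, H[t - 1].T, out=mUT)
                dUT += mUT
        # dW = sum_t X[t] @ dz_t.T; stacked GEMM then reduce
        dW = np.matmul(X, dG.transpose(0, 2, 1)).sum(axis=0)
        db = dG.sum(axis=(0, 2))
        dX = np.matmul(self.W, dG)             # (T, f, B)
        return dX, [dW, dUT.T, db]


class DenseLayer:
    """Single linear output unit on the last hidden state."""

    def __init__(self, features: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.W = glorot_normal(rng, features, 1, (features, 1), dtype)
        self.b = np.zeros(1, dtype=dtype)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def param_count(self) -> int:
        return self.W.size + self.b.size

    def forward(self, h: np.ndarray) -> np.ndarray:
        """h: (B, features) -> (B, 1)."""
        return h @ self.W + self.b

    def backward(self, h: np.ndarray, dy: np.ndarray):
        dW = h.T @ dy
        db = dy.sum(axis=0)
        dh = dy @ self.W.T
        return dh, [dW, db]


class LSTMRegressor:
    """Stacked LSTM layers + linear dense head mapping (B, T, F) -> (B,).

    All layers except the last LSTM return full sequences; the last LSTM
    emits only its final hidden state, which the dense head reads. The
    public API is batch-major (B, T, F); the feature-major transpose
    happens once at the boundary.
    """

    def __init__(self, layer_units: list[int], input_features: int,
                 seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.layers: list[LSTMLayer] = []
        f = input_features
        for k, u in enumerate(layer_units):
            last = k == len(layer_units) - 1
            self.layers.append(LSTMLayer(u, f, return_sequences=not last,
                                         rng=rng, dtype=dtype))
            f = u
        self.dense = DenseLayer(f, rng, dtype=dtype)

    # --- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.dense.params)
        return out

    def set_params(self, values: list[np.ndarray]) -> None:
        current = self.params
        if len(values) != len(current):
            raise ValueError("parameter list length mismatch")
        for dst, src in zip(current, values):
            dst[...] = src

    def get_params_copy(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def count_params(self) -> int:
        return sum(layer.param_count() for layer in self.layers) \
            + self.dense.param_count()

    # --- forward / loss -----------------------------------------------------
    def _forward_stack(self, Xb: np.ndarray, want_cache: bool):
        """Xb: (B, T, F) batch; returns (h_last (B, u), caches or None)."""
        h = np.ascontiguousarray(
            np.asarray(Xb, dtype=self.dtype).transpose(1, 2, 0))
        caches = [] if want_cache else None
        for layer in self.layers:
            if want_cache:
                h, cache = layer.forward(h, cache=True)
                caches.append(cache)
            else:
                h = layer.forward(h)
        return np.ascontiguousarray(h[-1].T), caches

    def predict(self, X: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Batched forward pass; returns one scalar per window."""
        X = np.asarray(X, dtype=self.dtype)
        out = np.empty(len(X), dtype=self.dtype)
        for s in range(0, len(X), batch_size):
            h_last, _ = self._forward_stack(X[s:s + batch_size], False)
            out[s:s + batch_size] = self.dense.forward(h_last)[:, 0]
        return out

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """MSE loss and exact gradients for one minibatch ((B, T, F) input)."""
        B = len(X)
        h_last, caches = self._forward_stack(X, True)
        pred = self.dense.forward(h_last)[:, 0]
        err = pred - np.asarray(y, dtype=self.dtype)
        loss = float(np.mean(err.astype(np.float64) ** 2))
        dy = ((2.0 / B) * err[:, None]).astype(self.dtype)
        dh_last, dense_grads = self.dense.backward(h_last, dy)
        top = caches[-1][4]        # H of the last layer, (T, u, B)
        dH = np.zeros_like(top)
        dH[-1] = dh_last.T
        grads_rev = []
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            dH, layer_grads = layer.backward(cache, dH)
            grads_rev.append(layer_grads)
        grads: list[np.ndarray] = []
        for layer_grads in reversed(grads_rev):
            grads.extend(layer_grads)
        grads.extend(dense_grads)
        return loss, grads

    def evaluate_mse(self, X: np.ndarray, y: np.ndarray,
                     batch_size: int = 2048) -> float:
        pred = self.predict(X, batch_size=batch_size)
        return float(np.mean((pred.astype(np.float64) - y) ** 2))


class Adam:
    """Adam optimizer with the usual defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * (g * g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
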