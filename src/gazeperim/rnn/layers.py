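"""Numpy neural-network layers with manual backpropagation.

Minimal set needed by the two-stream recurrent model: dense layers and a
bidirectional GRU.  The BiGRU runs its two directions as one stacked tensor
(leading axis = direction) so each time step costs a single batched matmul
plus a handful of fused elementwise operations.  Every layer exposes
``params`` / ``grads`` dicts keyed by parameter name; ``backward``
accumulates into ``grads`` and returns the input gradient.  All computation
is float32.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Dense:
    """Affine map y = x @ W + b over the last axis."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        k = 1.0 / np.sqrt(n_in)
        self.params: Dict[str, np.ndarray] = {
            "W": rng.uniform(-k, k, size=(n_in, n_out)).astype(DTYPE),
            "b": np.zeros(n_out, dtype=DTYPE),
        }
        self.grads: Dict[str, np.ndarray] = {k_: np.zeros_like(v)
                                             for k_, v in self.params.items()}
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.grads["W"] += xf.T @ dyf
        self.grads["b"] += dyf.sum(axis=0)
        return (dyf @ self.params["W"].T).reshape(x.shape)


class BiGRU:
    """Bidirectional GRU over (B, T, I) inputs, zero initial state.

    Gate order (r, z, n), per direction d in {forward, reversed}:

        r_t = sigmoid(W_r x + b_r + U_r h + c_r)
        z_t = sigmoid(W_z x + b_z + U_z h + c_z)
        n_t = tanh(W_n x + b_n + r_t * (U_n h + c_n))
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}

    Outputs are the per-direction hidden states concatenated on the feature
    axis (the reversed direction re-reversed to input time order).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.nh = n_in, n_hidden
        k = 1.0 / np.sqrt(n_hidden)
        self.params = {
            "W": rng.uniform(-k, k, size=(2, n_in, 3 * n_hidden)).astype(DTYPE),
            "U": rng.uniform(-k, k, size=(2, n_hidden, 3 * n_hidden)).astype(DTYPE),
            "b": np.zeros((2, 1, 3 * n_hidden), dtype=DTYPE),
            "c": np.zeros((2, 1, 3 * n_hidden), dtype=DTYPE),
        }
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    @property
    def n_out(self) -> int:
        return 2 * self.nh

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.nh
        x2 = np.stack([x, x[:, ::-1, :]])                     # (2, B, T, I)
        xp = np.matmul(x2.reshape(2, B * T, self.n_in), self.params["W"])
        xp += self.params["b"]
        xp = xp.reshape(2, B, T, 3 * H)  # per-step views below avoid copies
        U, c = self.params["U"], self.params["c"]
        # per-step caches, written in place inside the loop
        hs = np.zeros((T + 1, 2, B, H), dtype=DTYPE)
        gs = np.empty((T, 2, B, 2 * H), dtype=DTYPE)          # r and z gates
        ns = np.empty((T, 2, B, H), dtype=DTYPE)
        ms = np.empty((T, 2, B, H), dtype=DTYPE)
        hu = np.empty((2, B, 3 * H), dtype=DTYPE)
        h = hs[0]
        for t in range(T):
            np.matmul(h, U, out=hu)
            hu += c
            xp_t = xp[:, :, t, :]
            g = gs[t]
            np.add(xp_t[..., :2 * H], hu[..., :2 * H], out=g)
            np.negative(g, out=g)
            np.minimum(g, 60.0, out=g)  # avoid float32 exp overflow at saturation
            np.exp(g, out=g)
            g += 1.0
            np.reciprocal(g, out=g)                           # sigmoid
            r = g[..., :H]
            z = g[..., H:]
            m = ms[t]
            np.copyto(m, hu[..., 2 * H:])
            n = ns[t]
            np.multiply(r, m, out=n)
            n += xp_t[..., 2 * H:]
            np.tanh(n, out=n)
            hn = hs[t + 1]
            np.subtract(h, n, out=hn)
            hn *= z
            hn += n                                           # (1-z)n + zh
            h = hn
        self._cache = (x2, gs, ns, ms, hs)
        yf = hs[1:, 0].transpose(1, 0, 2)                     # (B, T, H)
        yb = hs[1:, 1].transpose(1, 0, 2)[:, ::-1, :]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2, gs, ns, ms, hs = self._cache
        B, T = dy.shape[0], dy.shape[1]
        H = self.nh
        U = self.params["U"]
        U_t = np.ascontiguousarray(U.transpose(0, 2, 1))
        dU, dc = self.grads["U"], self.grads["c"]
        # per-direction output gradients in each direction's own time order
        dyT = np.empty((T, 2, B, H), dtype=DTYPE)
        dyT[:, 0] = dy[..., :H].transpose(1, 0, 2)
        dyT[:, 1] = dy[:, ::-1, H:].transpose(1, 0, 2)
        dxp = np.empty((2, B, T, 3 * H), dtype=DTYPE)
        dh = np.zeros((2, B, H), dtype=DTYPE)
        dhz = np.empty_like(dh)
        dn = np.empty_like(dh)
        da_n = np.empty_like(dh)
        tmp = np.empty_like(dh)
        tmp2 = np.empty((2, B, 2 * H), dtype=DTYPE)
        dhu = np.empty((2, B, 3 * H), dtype=DTYPE)
        dU_step = np.empty_like(dU)
        for t in range(T - 1, -1, -1):
            dh += dyT[t]
            g, n, m, h_prev = gs[t], ns[t], ms[t], hs[t]
            r = g[..., :H]
            z = g[..., H:]
            np.multiply(dh, z, out=dhz)
            np.subtract(dh, dhz, out=dn)                      # dh * (1 - z)
            np.multiply(n, n, out=tmp)
            np.subtract(1.0, tmp, out=tmp)
            np.multiply(dn, tmp, out=da_n)                    # tanh'
            dhu_rz = dhu[..., :2 * H]
            dhu_n = dhu[..., 2 * H:]
            np.multiply(da_n, m, out=dhu[..., :H])            # dr
            np.subtract(h_prev, n, out=dhu[..., H:2 * H])
            dhu[..., H:2 * H] *= dh                           # dz
            np.subtract(1.0, g, out=tmp2)
            tmp2 *= g
            dhu_rz *= tmp2                                    # sigmoid'
            np.multiply(da_n, r, out=dhu_n)
            np.copyto(dxp[:, :, t, :2 * H], dhu_rz)
            np.copyto(dxp[:, :, t, 2 * H:], da_n)
            np.matmul(h_prev.transpose(0, 2, 1), dhu, out=dU_step)
            dU += dU_step
            dc += dhu.sum(axis=1, keepdims=True)
            np.matmul(dhu, U_t, out=dh)
            dh += dhz
        dxp_f = dxp.reshape(2, B * T, 3 * H)
        x2_f = x2.reshape(2, B * T, self.n_in)
        self.grads["W"] += np.matmul(x2_f.transpose(0, 2, 1), dxp_f)
        self.grads["b"] += dxp_f.sum(axis=1, keepdims=True)
        dx2 = np.matmul(dxp_f, self.params["W"].transpose(0, 2, 1))
        dx2 = dx2.reshape(2, B, T, self.n_in)
        return dx2[0] + dx2[1, :, ::-1, :]


def collect_params(named_modules) -> Dict[str, np.ndarray]:
    """Flatten {name.param: array} over (name, module) pairs."""
    return {f"{name}.{k}": v for name, mod in named_modules
            for k, v in mod.params.items()}


def collect_grads(named_modules) -> Dict[str, np.ndarray]:
    return {f"{name}.{k}": v for name, mod in named_modules
            for k, v in mod.grads.items()}


def zero_grads(named_modules) -> None:
    for _, mod in named_modules:
        for g in mod.grads.values():
            g[...] = 0.0
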