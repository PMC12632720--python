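"""Compact NumPy sequence and graph regressors for brain-age modelling.

Two architectures, both trained with Adam on mean absolute error:

* :class:`BiLSTMRegressor` — stacked (bi)directional LSTM over a window
  sequence of connectivity feature vectors, mean-pooled over time into a
  linear regression head. Used for dynamic FNC.
* :class:`GCNRegressor` — two graph-convolution layers over the static
  FNC matrix itself (absolute value, row-normalized, as weighted
  adjacency; the matrix rows as node features), ReLU activations on the
  hidden layers, global mean pool and a linear output head.

Gradients are hand-derived and verified by finite differences in the
test suite. Dropout (inverted) is applied between recurrent layers at
training time only, so inference is deterministic.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["Adam", "BiLSTMRegressor", "GCNRegressor", "mae_loss", "normalized_adjacency"]


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its subgradient w.r.t. predictions."""
    resid = pred - target
    return float(np.mean(np.abs(resid))), np.sign(resid) / resid.size


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a named-parameter dict, with global-norm clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: Optional[float] = 5.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# LSTM


class _LSTMCell:
    """One direction of one recurrent layer. Gate order: i, f, o, g."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator, prefix: str):
        self.h = hidden
        self.prefix = prefix
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.params = {
            f"{prefix}.Wx": _glorot(rng, (n_in, 4 * hidden)),
            f"{prefix}.Wh": _glorot(rng, (hidden, 4 * hidden)),
            f"{prefix}.b": b,
        }

    def forward(self, x: np.ndarray, params: dict) -> tuple[np.ndarray, dict]:
        B, T, _ = x.shape
        H = self.h
        Wx = params[f"{self.prefix}.Wx"]
        Wh = params[f"{self.prefix}.Wh"]
        b = params[f"{self.prefix}.b"]
        xproj = x @ Wx + b
        dt = xproj.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        hs = np.empty((B, T, H), dtype=dt)
        cache = {"x": x, "gates": np.empty((B, T, 4 * H), dtype=dt),
                 "c": np.empty((B, T, H), dtype=dt),
                 "c_prev": np.empty((B, T, H), dtype=dt),
                 "h_prev": np.empty((B, T, H), dtype=dt),
                 "tanh_c": np.empty((B, T, H), dtype=dt)}
        gates = cache["gates"]
        for t in range(T):
            z = xproj[:, t] + h @ Wh
            gt = gates[:, t]
            _sigmoid(z[:, :3 * H], out=gt[:, :3 * H])
            np.tanh(z[:, 3 * H:], out=gt[:, 3 * H:])
            i, f, o, g = (gt[:, :H], gt[:, H:2 * H], gt[:, 2 * H:3 * H], gt[:, 3 * H:])
            cache["h_prev"][:, t] = h
            cache["c_prev"][:, t] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            cache["c"][:, t] = c
            cache["tanh_c"][:, t] = tc
        return hs, cache

    def backward(self, dhs: np.ndarray, cache: dict, params: dict
                 ) -> tuple[np.ndarray, dict]:
        x = cache["x"]
        B, T, D = x.shape
        H = self.h
        Wx = params[f"{self.prefix}.Wx"]
        Wh = params[f"{self.prefix}.Wh"]
        dt = dhs.dtype
        dz_all = np.empty((B, T, 4 * H), dtype=dt)
        dWh = np.zeros_like(Wh)
        dh_next = np.zeros((B, H), dtype=dt)
        dc_next = np.zeros((B, H), dtype=dt)
        for t in range(T - 1, -1, -1):
            gt = cache["gates"][:, t]
            i, f, o, g = (gt[:, :H], gt[:, H:2 * H], gt[:, 2 * H:3 * H], gt[:, 3 * H:])
            tc = cache["tanh_c"][:, t]
            c_prev = cache["c_prev"][:, t]
            dh = dhs[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            dc_next = dc * f
            dz = dz_all[:, t]
            dz[:, :H] = dc * g * i * (1.0 - i)
            dz[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = do * o * (1.0 - o)
            dz[:, 3 * H:] = dc * i * (1.0 - g * g)
            dWh += cache["h_prev"][:, t].T @ dz
            dh_next = dz @ Wh.T
        flat_x = x.reshape(B * T, D)
        flat_dz = dz_all.reshape(B * T, 4 * H)
        grads = {
            f"{self.prefix}.Wx": flat_x.T @ flat_dz,
            f"{self.prefix}.Wh": dWh,
            f"{self.prefix}.b": flat_dz.sum(axis=0),
        }
        dx = flat_dz @ Wx.T
        return dx.reshape(B, T, D), grads


class BiLSTMRegressor:
    """Stacked (bi)directional LSTM -> temporal mean pool -> linear head."""

    def __init__(self, n_features: int, hidden: int = 32, n_layers: int = 1,
                 bidirectional: bool = True, dropout: float = 0.1,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden = hidden
        self.n_layers = n_layers
        self.bidirectional = bidirectional
        self.dropout = dropout
        self.cells: list[list[_LSTMCell]] = []
        self.params: dict[str, np.ndarray] = {}
        n_dir = 2 if bidirectional else 1
        n_in = n_features
        for layer in range(n_layers):
            dirs = []
            for d in range(n_dir):
                cell = _LSTMCell(n_in, hidden, rng, prefix=f"l{layer}d{d}")
                dirs.append(cell)
                self.params.update(cell.params)
            self.cells.append(dirs)
            n_in = hidden * n_dir
        self.params["head.w"] = _glorot(rng, (n_in, 1))
        self.params["head.b"] = np.zeros(1)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[np.ndarray, dict]:
        h = np.asarray(x, dtype=float)
        caches: list[dict] = []
        for layer, dirs in enumerate(self.cells):
            outs, layer_caches = [], []
            for d, cell in enumerate(dirs):
                inp = h if d == 0 else h[:, ::-1]
                hs, cache = cell.forward(inp, self.params)
                if d == 1:
                    hs = hs[:, ::-1]
                outs.append(hs)
                layer_caches.append(cache)
            h = np.concatenate(outs, axis=2) if len(outs) == 2 else outs[0]
            mask = None
            if train and self.dropout > 0 and layer < self.n_layers - 1:
                if rng is None:
                    raise ValueError("training forward pass needs an rng for dropout")
                mask = ((rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)).astype(h.dtype)
                h = h * mask
            caches.append({"cells": layer_caches, "mask": mask})
        pooled = h.mean(axis=1)
        pred = (pooled @ self.params["head.w"] + self.params["head.b"]).ravel()
        return pred, {"layers": caches, "pooled": pooled, "T": h.shape[1]}

    def backward(self, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dpred = dpred.reshape(-1, 1)
        grads["head.w"] = cache["pooled"].T @ dpred
        grads["head.b"] = dpred.sum(axis=0)
        dpooled = dpred @ self.params["head.w"].T
        T = cache["T"]
        dh = np.repeat(dpooled[:, None, :], T, axis=1) / T
        for layer in range(self.n_layers - 1, -1, -1):
            lc = cache["layers"][layer]
            if lc["mask"] is not None:
                dh = dh * lc["mask"]
            dirs = self.cells[layer]
            if len(dirs) == 2:
                H = self.hidden
                dx_f, g_f = dirs[0].backward(dh[:, :, :H], lc["cells"][0], self.params)
                dx_b, g_b = dirs[1].backward(dh[:, ::-1, H:], lc["cells"][1], self.params)
                dh = dx_f + dx_b[:, ::-1]
                grads.update(g_f)
                grads.update(g_b)
            else:
                dh, g = dirs[0].backward(dh, lc["cells"][0], self.params)
                grads.update(g)
        return grads


# ---------------------------------------------------------------------------
# graph convolution over the connectome


def normalized_adjacency(sfnc: np.ndarray) -> np.ndarray:
    """Weighted adjacency from FNC matrices: absolute value, row-normalized.

    Accepts (C, C) or a batch (B, C, C); the unit diagonal acts as a
    self loop.
    """
    a = np.abs(np.asarray(sfnc, dtype=float))
    return a / a.sum(axis=-1, keepdims=True)


class GCNRegressor:
    """Two graph-conv layers (ReLU) + global mean pool + linear head.

    Node features are the rows of the FNC matrix itself; messages are
    passed over the row-normalized absolute FNC as weighted adjacency.
    """

    def __init__(self, n_nodes: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params = {
            "W1": _glorot(rng, (n_nodes, hidden)),
            "b1": np.zeros(hidden),
            "W2": _glorot(rng, (hidden, hidden)),
            "b2": np.zeros(hidden),
            "head.w": _glorot(rng, (hidden, 1)),
            "head.b": np.zeros(1),
        }

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[np.ndarray, dict]:
        x = np.asarray(x, dtype=float)  # (B, C, C) FNC matrices
        a = normalized_adjacency(x)
        p = self.params
        ax = a @ x
        z1 = ax @ p["W1"] + p["b1"]
        h1 = np.maximum(z1, 0.0)
        ah1 = a @ h1
        z2 = ah1 @ p["W2"] + p["b2"]
        h2 = np.maximum(z2, 0.0)
        pooled = h2.mean(axis=1)
        pred = (pooled @ p["head.w"] + p["head.b"]).ravel()
        return pred, {"a": a, "ax": ax, "z1": z1, "h1": h1, "ah1": ah1,
                      "z2": z2, "pooled": pooled, "C": x.shape[1]}

    def backward(self, cache: dict, dpred: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        dpred = dpred.reshape(-1, 1)
        grads = {
            "head.w": cache["pooled"].T @ dpred,
            "head.b": dpred.sum(axis=0),
        }
        dpooled = dpred @ p["head.w"].T
        C = cache["C"]
        dh2 = np.repeat(dpooled[:, None, :], C, axis=1) / C
        dz2 = dh2 * (cache["z2"] > 0)
        grads["W2"] = np.einsum("bcf,bcg->fg", cache["ah1"], dz2)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dh1 = cache["a"].transpose(0, 2, 1) @ (dz2 @ p["W2"].T)
        dz1 = dh1 * (cache["z1"] > 0)
        grads["W1"] = np.einsum("bcf,bcg->fg", cache["ax"], dz1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads
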