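"""Numpy building blocks for the interaction classifier.

Each layer implements ``forward`` (pushing a cache context) and ``backward``
(popping it), so a layer object can appear more than once in a computation
(shared towers) as long as backward calls mirror forwards in reverse order.
Parameter gradients accumulate into ``grads`` until ``zero_grad``.

All math is plain numpy so the arithmetic is auditable and runs identically
on any CPU.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, *shape: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._ctx: list = []

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _acc(self, name: str, g: np.ndarray) -> None:
        if name not in self.grads:
            self.grads[name] = np.zeros_like(self.params[name])
        self.grads[name] += g

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class Conv1D(Layer):
    """1-D convolution with same padding: (B, L, Cin) -> (B, L, Cout)."""

    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, kernel_size: int = 3):
        super().__init__()
        self.k = kernel_size
        self.params = {
            "W": glorot_uniform(rng, kernel_size * c_in, c_out, kernel_size, c_in, c_out),
            "b": np.zeros(c_out),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, _ = x.shape
        pl = (self.k - 1) // 2
        pr = self.k - 1 - pl
        xpad = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        W, b = self.params["W"], self.params["b"]
        out = np.zeros((B, L, W.shape[2]))
        for k in range(self.k):
            out += xpad[:, k : k + L, :] @ W[k]
        out += b
        self._ctx.append((xpad, L, pl))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xpad, L, pl = self._ctx.pop()
        W = self.params["W"]
        dW = np.zeros_like(W)
        dxpad = np.zeros_like(xpad)
        for k in range(self.k):
            seg = xpad[:, k : k + L, :]
            dW[k] = np.einsum("blc,bld->cd", seg, dout)
            dxpad[:, k : k + L, :] += dout @ W[k].T
        self._acc("W", dW)
        self._acc("b", dout.sum(axis=(0, 1)))
        return dxpad[:, pl : pl + L, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mask = x > 0
        self._ctx.append(mask)
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._ctx.pop()


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; remainder dropped."""

    def __init__(self, pool_size: int = 2):
        super().__init__()
        self.pool = pool_size

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, L, C = x.shape
        Lp = L // self.pool
        xt = x[:, : Lp * self.pool, :].reshape(B, Lp, self.pool, C)
        arg = xt.argmax(axis=2)
        out = np.take_along_axis(xt, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._ctx.append((arg, x.shape))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        arg, shape = self._ctx.pop()
        B, L, C = shape
        Lp = dout.shape[1]
        dx = np.zeros((B, Lp, self.pool, C))
        np.put_along_axis(dx, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        full = np.zeros(shape)
        full[:, : Lp * self.pool, :] = dx.reshape(B, Lp * self.pool, C)
        return full


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._ctx.append(None)
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        self._ctx.append(mask)
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._ctx.pop()
        return dout if mask is None else dout * mask


def gru_step(
    x_t: np.ndarray, h_prev: np.ndarray, params: Mapping[str, np.ndarray]
) -> np.ndarray:
    """One GRU step.

    r_t = sigma(W_r x_t + U_r h_{t-1} + b_r)
    z_t = sigma(W_z x_t + U_z h_{t-1} + b_z)
    g_t = tanh(W_g x_t + U_g (r_t * h_{t-1}) + b_g)
    h_t = (1 - z_t) * h_{t-1} + z_t * g_t

    Works on single vectors or on batched (B, ...) arrays.
    """
    r = sigmoid(x_t @ params["Wr"] + h_prev @ params["Ur"] + params["br"])
    z = sigmoid(x_t @ params["Wz"] + h_prev @ params["Uz"] + params["bz"])
    g = np.tanh(x_t @ params["Wg"] + (r * h_prev) @ params["Ug"] + params["bg"])
    return (1.0 - z) * h_prev + z * g


class GRU(Layer):
    """Unidirectional GRU over (B, T, Cin) -> (B, T, H), zero initial state."""

    def __init__(self, rng: np.random.Generator, c_in: int, hidden: int):
        super().__init__()
        self.h = hidden
        p = {}
        for gate in ("r", "z", "g"):
            p[f"W{gate}"] = glorot_uniform(rng, c_in, hidden, c_in, hidden)
            p[f"U{gate}"] = glorot_uniform(rng, hidden, hidden, hidden, hidden)
            p[f"b{gate}"] = np.zeros(hidden)
        self.params = p

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        p = self.params
        h = np.zeros((B, self.h))
        hs = np.empty((B, T, self.h))
        cache = []
        for t in range(T):
            x_t = x[:, t, :]
            r = sigmoid(x_t @ p["Wr"] + h @ p["Ur"] + p["br"])
            z = sigmoid(x_t @ p["Wz"] + h @ p["Uz"] + p["bz"])
            g = np.tanh(x_t @ p["Wg"] + (r * h) @ p["Ug"] + p["bg"])
            h_new = (1.0 - z) * h + z * g
            cache.append((x_t, h, r, z, g))
            h = h_new
            hs[:, t, :] = h
        self._ctx.append(cache)
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._ctx.pop()
        p = self.params
        T = len(cache)
        dx = np.zeros((dhs.shape[0], T, p["Wr"].shape[0]))
        acc = {k: np.zeros_like(v) for k, v in p.items()}
        dh = np.zeros((dhs.shape[0], self.h))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, r, z, g = cache[t]
            dh = dh + dhs[:, t, :]
            dz_pre = dh * (g - h_prev) * z * (1.0 - z)
            dg_pre = dh * z * (1.0 - g * g)
            dh_prev = dh * (1.0 - z)
            acc["Wg"] += x_t.T @ dg_pre
            acc["Ug"] += (r * h_prev).T @ dg_pre
            acc["bg"] += dg_pre.sum(axis=0)
            d_rh = dg_pre @ p["Ug"].T
            dh_prev += d_rh * r
            dr_pre = d_rh * h_prev * r * (1.0 - r)
            acc["Wr"] += x_t.T @ dr_pre
            acc["Ur"] += h_prev.T @ dr_pre
            acc["br"] += dr_pre.sum(axis=0)
            dh_prev += dr_pre @ p["Ur"].T
            acc["Wz"] += x_t.T @ dz_pre
            acc["Uz"] += h_prev.T @ dz_pre
            acc["bz"] += dz_pre.sum(axis=0)
            dh_prev += dz_pre @ p["Uz"].T
            dx[:, t, :] = dr_pre @ p["Wr"].T + dz_pre @ p["Wz"].T + dg_pre @ p["Wg"].T
            dh = dh_prev
        for k, v in acc.items():
            self._acc(k, v)
        return dx


class BiGRU(Layer):
    """Forward and backward GRU passes concatenated per step: (B,T,Cin)->(B,T,2H)."""

    def __init__(self, rng: np.random.Generator, c_in: int, hidden: int):
        super().__init__()
        self.fwd = GRU(rng, c_in, hidden)
        self.bwd = GRU(rng, c_in, hidden)
        # expose children's parameters under prefixed names
        self.params = {
            **{f"fwd_{k}": v for k, v in self.fwd.params.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.params.items()},
        }

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()
        self._sync_grads()

    def _sync_grads(self) -> None:
        self.grads = {
            **{f"fwd_{k}": v for k, v in self.fwd.grads.items()},
            **{f"bwd_{k}": v for k, v in self.bwd.grads.items()},
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        hf = self.fwd.forward(x, train)
        hb = self.bwd.forward(x[:, ::-1, :], train)[:, ::-1, :]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.h
        dxb = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1, :]
        dxf = self.fwd.backward(dout[:, :, :H])
        self._sync_grads()
        return dxf + dxb


def attention_weights(
    states: np.ndarray, params: Mapping[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Additive attention over (.., T, D) states.

    score_t = v . tanh(W h_t + b); weights = softmax(scores); returns
    (weights, pooled) where pooled = sum_t weights_t h_t.
    """
    u = np.tanh(states @ params["W"] + params["b"])
    scores = u @ params["v"]
    s = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(s)
    alpha = e / e.sum(axis=-1, keepdims=True)
    pooled = np.einsum("...t,...td->...d", alpha, states)
    return alpha, pooled


class Attention(Layer):
    """Additive (tanh) attention pooling: (B, T, D) -> (B, D)."""

    def __init__(self, rng: np.random.Generator, dim: int, units: int):
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, dim, units, dim, units),
            "b": np.zeros(units),
            "v": glorot_uniform(rng, units, 1, units),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.params
        u = np.tanh(x @ p["W"] + p["b"])
        scores = u @ p["v"]
        s = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(s)
        alpha = e / e.sum(axis=1, keepdims=True)
        pooled = np.einsum("bt,btd->bd", alpha, x)
        self._ctx.append((x, u, alpha))
        self.last_weights = alpha
        return pooled

    def backward(self, dpooled: np.ndarray) -> np.ndarray:
        x, u, alpha = self._ctx.pop()
        p = self.params
        dalpha = np.einsum("bd,btd->bt", dpooled, x)
        dx = alpha[:, :, None] * dpooled[:, None, :]
        dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        self._acc("v", np.einsum("bta,bt->a", u, dscores))
        du_pre = dscores[:, :, None] * p["v"] * (1.0 - u * u)
        self._acc("W", np.einsum("btd,bta->da", x, du_pre))
        self._acc("b", du_pre.sum(axis=(0, 1)))
        dx += du_pre @ p["W"].T
        return dx


class MeanPool(Layer):
    """Mean over the time axis: (B, T, D) -> (B, D)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._ctx.append(x.shape)
        return x.mean(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, T, D = self._ctx.pop()
        return np.repeat(dout[:, None, :], T, axis=1) / T


class Dense(Layer):
    """Affine map (B, D) -> (B, units)."""

    def __init__(self, rng: np.random.Generator, dim: int, units: int = 1):
        super().__init__()
        self.params = {
            "W": glorot_uniform(rng, dim, units, dim, units),
            "b": np.zeros(units),
        }

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._ctx.append(x)
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._ctx.pop()
        self._acc("W", x.T @ dout)
        self._acc("b", dout.sum(axis=0))
        return dout @ self.params["W"].T


class AMSGrad:
    """AMSGrad variant of Adam: the second-moment estimate is non-decreasing."""

    def __init__(self, layers: list[Layer], lr: float = 3e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = []
        seen: set[int] = set()
        for l in layers:
            if id(l) not in seen:  # shared towers register each layer once
                seen.add(id(l))
                self.layers.append(l)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}
        self.vhat: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                vh = self.vhat.setdefault(key, np.zeros_like(p))
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                np.maximum(vh, v, out=vh)
                mhat = m / (1 - self.b1**self.t)
                vhat_c = vh / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat_c) + self.eps)
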