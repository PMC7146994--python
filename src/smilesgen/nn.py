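"""Minimal NumPy backend for character-level recurrent generators.

Implements exactly what the generator architectures need: LSTM/GRU
layers (optionally bidirectional), dropout, branch merging
(concatenate / average / learnable softmax-weighted average), a dense
softmax head, cross-entropy backpropagation through time and Adam.

Everything is float32 and deterministic given the seeds passed in.
Gate pre-activations for whole sequences are computed with a single
input matmul per layer; only the recurrent term is stepped in time.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

DTYPE = np.float32


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def one_hot(indices: np.ndarray, size: int) -> np.ndarray:
    out = np.zeros(indices.shape + (size,), dtype=DTYPE)
    np.put_along_axis(out, indices[..., None].astype(np.int64), 1.0, axis=-1)
    return out


class Layer:
    """Base class: forward caches whatever backward needs."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(DTYPE)


class LSTM(Layer):
    """Single-direction LSTM. Gate order in the fused weight matrices is
    (i, f, g, o); the forget gate bias starts at 1."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        return_sequences: bool,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        H = hidden_size
        self.params = {
            "Wx": _glorot(rng, input_size, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "b": np.zeros(4 * H, dtype=DTYPE),
        }
        self.params["b"][H : 2 * H] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden_size
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        pre_x = x.reshape(B * T, -1) @ Wx
        pre_x = pre_x.reshape(B, T, 4 * H) + b
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        gates = np.empty((B, T, 4 * H), dtype=DTYPE)
        cs = np.empty((B, T, H), dtype=DTYPE)
        tanh_cs = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            z = pre_x[:, t] + h @ Wh
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            gates[:, t, :H] = i
            gates[:, t, H : 2 * H] = f
            gates[:, t, 2 * H : 3 * H] = g
            gates[:, t, 3 * H :] = o
            cs[:, t] = c
            tanh_cs[:, t] = tc
            hs[:, t] = h
        self._cache = (x, hs, gates, cs, tanh_cs)
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, hs, gates, cs, tanh_cs = self._cache
        B, T, _ = x.shape
        H = self.hidden_size
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        if self.return_sequences:
            dhs = dout.astype(DTYPE)
        else:
            dhs = np.zeros((B, T, H), dtype=DTYPE)
            dhs[:, -1] = dout
        dz_all = np.empty((B, T, 4 * H), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = tanh_cs[:, t]
            dh = dhs[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            c_prev = cs[:, t - 1] if t > 0 else 0.0
            di = dc * g * i * (1.0 - i)
            df = dc * c_prev * f * (1.0 - f)
            dg = dc * i * (1.0 - g * g)
            do = dh * tc * o * (1.0 - o)
            dz = np.concatenate([di, df, dg, do], axis=1)
            dz_all[:, t] = dz
            dh_next = dz @ Wh.T
            dc_next = dc * f
        dz_flat = dz_all.reshape(B * T, 4 * H)
        self.grads["Wx"][...] = x.reshape(B * T, -1).T @ dz_flat
        h_prev = np.concatenate(
            [np.zeros((B, 1, H), dtype=DTYPE), hs[:, :-1]], axis=1
        )
        self.grads["Wh"][...] = h_prev.reshape(B * T, H).T @ dz_flat
        self.grads["b"][...] = dz_flat.sum(axis=0)
        dx = dz_flat @ Wx.T
        return dx.reshape(B, T, -1)


class GRU(Layer):
    """Single-direction GRU (reset gate applied before the candidate
    matmul). Gate order is (z, r) fused; the candidate has its own
    weights."""

    def __init__(
        self,
        input_size: int,
        hidden_size: int,
        return_sequences: bool,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.return_sequences = return_sequences
        H = hidden_size
        self.params = {
            "Wx": _glorot(rng, input_size, 2 * H),
            "Wh": _glorot(rng, H, 2 * H),
            "b": np.zeros(2 * H, dtype=DTYPE),
            "Wxn": _glorot(rng, input_size, H),
            "Whn": _glorot(rng, H, H),
            "bn": np.zeros(H, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden_size
        p = self.params
        pre_x = (x.reshape(B * T, -1) @ p["Wx"]).reshape(B, T, 2 * H) + p["b"]
        pre_n = (x.reshape(B * T, -1) @ p["Wxn"]).reshape(B, T, H) + p["bn"]
        h = np.zeros((B, H), dtype=DTYPE)
        hs = np.empty((B, T, H), dtype=DTYPE)
        zs = np.empty((B, T, H), dtype=DTYPE)
        rs = np.empty((B, T, H), dtype=DTYPE)
        ns = np.empty((B, T, H), dtype=DTYPE)
        hprev = np.empty((B, T, H), dtype=DTYPE)
        for t in range(T):
            hprev[:, t] = h
            zr = pre_x[:, t] + h @ p["Wh"]
            z = sigmoid(zr[:, :H])
            r = sigmoid(zr[:, H:])
            n = np.tanh(pre_n[:, t] + r * (h @ p["Whn"]))
            h = (1.0 - z) * n + z * h
            zs[:, t], rs[:, t], ns[:, t], hs[:, t] = z, r, n, h
        self._cache = (x, hs, zs, rs, ns, hprev)
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, hs, zs, rs, ns, hprev = self._cache
        B, T, _ = x.shape
        H = self.hidden_size
        p = self.params
        if self.return_sequences:
            dhs = dout.astype(DTYPE)
        else:
            dhs = np.zeros((B, T, H), dtype=DTYPE)
            dhs[:, -1] = dout
        dzr_all = np.empty((B, T, 2 * H), dtype=DTYPE)
        dn_pre_all = np.empty((B, T, H), dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        for t in range(T - 1, -1, -1):
            z, r, n = zs[:, t], rs[:, t], ns[:, t]
            h_prev = hprev[:, t]
            dh = dhs[:, t] + dh_next
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n) * z * (1.0 - z)
            dn_pre = dn * (1.0 - n * n)
            hWhn = h_prev @ p["Whn"]
            dr = dn_pre * hWhn * r * (1.0 - r)
            dzr = np.concatenate([dz, dr], axis=1)
            dzr_all[:, t] = dzr
            dn_pre_all[:, t] = dn_pre
            dh_next = (
                dh * z
                + dzr @ p["Wh"].T
                + (dn_pre * r) @ p["Whn"].T
            )
        dzr_flat = dzr_all.reshape(B * T, 2 * H)
        dn_flat = dn_pre_all.reshape(B * T, H)
        x_flat = x.reshape(B * T, -1)
        hp_flat = hprev.reshape(B * T, H)
        self.grads["Wx"][...] = x_flat.T @ dzr_flat
        self.grads["Wh"][...] = hp_flat.T @ dzr_flat
        self.grads["b"][...] = dzr_flat.sum(axis=0)
        self.grads["Wxn"][...] = x_flat.T @ dn_flat
        self.grads["Whn"][...] = hp_flat.T @ (
            dn_flat * rs.reshape(B * T, H)
        )
        self.grads["bn"][...] = dn_flat.sum(axis=0)
        dx = dzr_flat @ p["Wx"].T + dn_flat @ p["Wxn"].T
        return dx.reshape(B, T, -1)


class Bidirectional(Layer):
    """Runs a forward and a reversed copy of a recurrent layer and
    concatenates their features, doubling the output width."""

    def __init__(self, forward_layer: Layer, backward_layer: Layer) -> None:
        super().__init__()
        self.fwd = forward_layer
        self.bwd = backward_layer
        self.return_sequences = forward_layer.return_sequences

    @property
    def params(self):  # type: ignore[override]
        return {
            **{f"fwd.{k}": v for k, v in self.fwd.params.items()},
            **{f"bwd.{k}": v for k, v in self.bwd.params.items()},
        }

    @params.setter
    def params(self, value):  # base-class __init__ assigns {}
        pass

    @property
    def grads(self):  # type: ignore[override]
        return {
            **{f"fwd.{k}": v for k, v in self.fwd.grads.items()},
            **{f"bwd.{k}": v for k, v in self.bwd.grads.items()},
        }

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        yf = self.fwd.forward(x, train)
        yb = self.bwd.forward(x[:, ::-1], train)
        if self.return_sequences:
            yb = yb[:, ::-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.fwd.hidden_size
        df, db = dout[..., :H], dout[..., H:]
        if self.return_sequences:
            db = db[:, ::-1]
        dx = self.fwd.backward(np.ascontiguousarray(df))
        dx = dx + self.bwd.backward(np.ascontiguousarray(db))[:, ::-1]
        return dx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape) < keep
        ).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Dense(Layer):
    def __init__(
        self, input_size: int, output_size: int, rng: np.random.Generator
    ) -> None:
        super().__init__()
        self.params = {
            "W": _glorot(rng, input_size, output_size),
            "b": np.zeros(output_size, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class ConcatenateMerge(Layer):
    def forward_branches(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        self._widths = [x.shape[-1] for x in xs]
        return np.concatenate(xs, axis=-1)

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        splits = np.cumsum(self._widths[:-1])
        return [
            np.ascontiguousarray(d) for d in np.split(dout, splits, axis=-1)
        ]


class AverageMerge(Layer):
    def forward_branches(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        widths = {x.shape[-1] for x in xs}
        if len(widths) != 1:
            raise ValueError("average merge requires equal branch widths")
        self._k = len(xs)
        return np.mean(xs, axis=0)

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        d = dout / self._k
        return [d.copy() for _ in range(self._k)]


class LearnableAverageMerge(Layer):
    """Weighted average with trainable weights w = softmax(logits),
    guaranteeing non-negative weights that sum to one. Equal logits at
    initialization make this start as a plain average."""

    def __init__(self, k: int) -> None:
        super().__init__()
        if k < 1:
            raise ValueError("need at least one branch")
        if k == 1:
            import warnings

            warnings.warn("learnable average over one branch is the identity")
        self.k = k
        self.params = {"logits": np.zeros(k, dtype=DTYPE)}
        self.grads = {"logits": np.zeros(k, dtype=DTYPE)}

    @property
    def weights(self) -> np.ndarray:
        return softmax(self.params["logits"])

    def forward_branches(self, xs: Sequence[np.ndarray]) -> np.ndarray:
        widths = {x.shape[-1] for x in xs}
        if len(widths) != 1:
            raise ValueError(
                "learnable average merge requires equal branch widths"
            )
        self._xs = xs
        w = self.weights
        return sum(w[i] * xs[i] for i in range(self.k))

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        w = self.weights
        dw = np.array(
            [float(np.sum(dout * x)) for x in self._xs], dtype=DTYPE
        )
        # d softmax: dlogits_i = w_i * (dw_i - sum_j w_j dw_j)
        self.grads["logits"][...] = w * (dw - float(np.dot(w, dw)))
        return [w[i] * dout for i in range(self.k)]


class Adam:
    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(
        self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]
    ) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def weights_checksum(params: dict[str, np.ndarray]) -> str:
    """Stable digest of a parameter set, for no-mutation assertions."""
    h = hashlib.sha256()
    for key in sorted(params):
        h.update(key.encode())
        h.update(np.ascontiguousarray(params[key]).tobytes())
    return h.hexdigest()
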