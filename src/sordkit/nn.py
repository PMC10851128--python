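"""Minimal CNN+GRU sequence classifier in pure numpy.

The network maps a window of multichannel sensor samples to a probability
vector over activity classes:

    conv1d(k=5) → ReLU → maxpool(2) → conv1d(k=5) → ReLU → maxpool(2)
    → GRU → softmax head on the final hidden state

Forward pass, backpropagation (including backprop through time for the GRU)
and the Adam optimizer are implemented directly on numpy arrays: the model is
small enough that this trains in seconds-to-minutes on one CPU, and a pure
numpy stack keeps runs bit-reproducible for a fixed seed.

All arrays are float64.  Windows are arranged (batch, length, channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Params = dict[str, np.ndarray]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) → (B, L-k+1, k*C) patch matrix."""
    w = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, P, C, k)
    return np.ascontiguousarray(w.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


def _col2im(dpatches: np.ndarray, length: int, k: int, channels: int) -> np.ndarray:
    """Scatter patch gradients back to the (B, L, C) input."""
    b, p, _ = dpatches.shape
    dp = dpatches.reshape(b, p, k, channels)
    dx = np.zeros((b, length, channels))
    for j in range(k):
        dx[:, j : j + p, :] += dp[:, :, j, :]
    return dx


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping width-2 max pool along axis 1 (odd tail dropped)."""
    t = (x.shape[1] // 2) * 2
    a, b = x[:, 0:t:2, :], x[:, 1:t:2, :]
    take_b = b > a
    return np.where(take_b, b, a), take_b


def _unpool2(dout: np.ndarray, take_b: np.ndarray, length: int) -> np.ndarray:
    dx = np.zeros((dout.shape[0], length, dout.shape[2]))
    t = (length // 2) * 2
    dx[:, 0:t:2, :] = np.where(take_b, 0.0, dout)
    dx[:, 1:t:2, :] = np.where(take_b, dout, 0.0)
    return dx


@dataclass
class CNNGRU:
    """CNN+GRU window classifier with explicit parameters and gradients."""

    n_channels: int
    n_classes: int
    window_length: int
    conv_filters: tuple[int, int] = (32, 64)
    kernel: int = 5
    hidden: int = 64
    params: Params = field(default_factory=dict)

    def __post_init__(self) -> None:
        # length bookkeeping: two valid convs with width-2 pools
        p1 = self.window_length - self.kernel + 1
        if p1 < 2:
            raise ValueError("window too short for the first convolution")
        self._len1 = p1
        q1 = p1 // 2
        p2 = q1 - self.kernel + 1
        if p2 < 2:
            raise ValueError("window too short for the second convolution")
        self._len2 = p2
        self._steps = p2 // 2
        if self._steps < 1:
            raise ValueError("window too short: no timesteps reach the GRU")

    def init_params(self, rng: np.random.Generator) -> None:
        f1, f2 = self.conv_filters
        k, h, c, kk = self.kernel, self.hidden, self.n_channels, self.n_classes

        def glorot(fan_in: int, fan_out: int, shape: tuple[int, ...]) -> np.ndarray:
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=shape)

        self.params = {
            "W1": glorot(k * c, f1, (k * c, f1)),
            "b1": np.zeros(f1),
            "W2": glorot(k * f1, f2, (k * f1, f2)),
            "b2": np.zeros(f2),
            # GRU gate order: [update z | reset r | candidate h]
            "Wg": glorot(f2, 3 * h, (f2, 3 * h)),
            "Ug": glorot(h, 3 * h, (h, 3 * h)),
            "bg": np.zeros(3 * h),
            "Wo": glorot(h, kk, (h, kk)),
            "bo": np.zeros(kk),
        }

    # ------------------------------------------------------------------ forward

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch of windows (B, L, C)."""
        p = self.params
        k = self.kernel
        h = self.hidden

        pat1 = _im2col(x, k)
        z1 = pat1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        pool1, mask1 = _maxpool2(a1)

        pat2 = _im2col(pool1, k)
        z2 = pat2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        pool2, mask2 = _maxpool2(a2)  # (B, T, F2)

        b, t, _ = pool2.shape
        hs = np.zeros((t + 1, b, h))
        zs, rs, cs = [], [], []
        for step in range(t):
            xt = pool2[:, step, :]
            gx = xt @ p["Wg"] + p["bg"]
            gh = hs[step] @ p["Ug"]
            z = _sigmoid(gx[:, :h] + gh[:, :h])
            r = _sigmoid(gx[:, h : 2 * h] + gh[:, h : 2 * h])
            c = np.tanh(gx[:, 2 * h :] + r * gh[:, 2 * h :])
            hs[step + 1] = (1.0 - z) * hs[step] + z * c
            if want_cache:
                zs.append(z)
                rs.append(r)
                cs.append(c)

        logits = hs[t] @ p["Wo"] + p["bo"]
        if not want_cache:
            return logits
        cache = {
            "x": x, "pat1": pat1, "z1": z1, "mask1": mask1, "pool1": pool1,
            "pat2": pat2, "z2": z2, "mask2": mask2, "pool2": pool2,
            "hs": hs, "zs": zs, "rs": rs, "cs": cs,
        }
        return logits, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = np.empty((x.shape[0], self.n_classes))
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = softmax(self.forward(x[i : i + batch_size]))
        return out

    # ----------------------------------------------------------------- backward

    def loss_and_grads(
        self, x: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
    ) -> tuple[float, Params]:
        """Weighted cross-entropy loss and gradients for one minibatch."""
        p = self.params
        k, h = self.kernel, self.hidden
        bsz = x.shape[0]
        if sample_weight is None:
            sample_weight = np.ones(bsz)
        wsum = sample_weight.sum()

        logits, cache = self.forward(x, want_cache=True)
        probs = softmax(logits)
        nll = -np.log(np.clip(probs[np.arange(bsz), y], 1e-300, None))
        loss = float((sample_weight * nll).sum() / wsum)

        dlogits = probs.copy()
        dlogits[np.arange(bsz), y] -= 1.0
        dlogits *= (sample_weight / wsum)[:, None]

        hs, zs, rs, cs = cache["hs"], cache["zs"], cache["rs"], cache["cs"]
        t = len(zs)
        grads: Params = {name: np.zeros_like(arr) for name, arr in p.items()}
        grads["Wo"] = hs[t].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)

        dh = dlogits @ p["Wo"].T
        dpool2 = np.zeros_like(cache["pool2"])
        Ug = p["Ug"]
        for step in range(t - 1, -1, -1):
            z, r, c = zs[step], rs[step], cs[step]
            h_prev = hs[step]
            gh_c = h_prev @ Ug[:, 2 * h :]  # candidate's recurrent pre-activation

            dc = dh * z * (1.0 - c * c)
            dz = dh * (c - h_prev) * z * (1.0 - z)
            dr = dc * gh_c * r * (1.0 - r)
            dh_prev = dh * (1.0 - z)

            dgx = np.concatenate([dz, dr, dc], axis=1)  # (B, 3H)
            xt = cache["pool2"][:, step, :]
            grads["Wg"] += xt.T @ dgx
            grads["bg"] += dgx.sum(axis=0)
            dpool2[:, step, :] = dgx @ p["Wg"].T

            # recurrent matrix: z and r see h_prev directly, candidate sees r*h_prev
            dgh = np.concatenate([dz, dr, dc * r], axis=1)
            grads["Ug"] += h_prev.T @ dgh
            dh_prev += dgh @ Ug.T
            dh = dh_prev

        da2 = _unpool2(dpool2, cache["mask2"], self._len2)
        dz2 = da2 * (cache["z2"] > 0)
        grads["W2"] = np.einsum("bpi,bpj->ij", cache["pat2"], dz2)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dpat2 = dz2 @ p["W2"].T
        dpool1 = _col2im(dpat2, self._len1 // 2, k, self.conv_filters[0])

        da1 = _unpool2(dpool1, cache["mask1"], self._len1)
        dz1 = da1 * (cache["z1"] > 0)
        grads["W1"] = np.einsum("bpi,bpj->ij", cache["pat1"], dz1)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return loss, grads


@dataclass
class Adam:
    """Adam optimizer over a named parameter dict."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: Params = field(default_factory=dict)
    _v: Params = field(default_factory=dict)
    _t: int = 0

    def step(self, params: Params, grads: Params) -> None:
        self._t += 1
        for name, g in grads.items():
            if name not in self._m:
                self._m[name] = np.zeros_like(g)
                self._v[name] = np.zeros_like(g)
            self._m[name] = self.beta1 * self._m[name] + (1 - self.beta1) * g
            self._v[name] = self.beta2 * self._v[name] + (1 - self.beta2) * g * g
            mhat = self._m[name] / (1 - self.beta1**self._t)
            vhat = self._v[name] / (1 - self.beta2**self._t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
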