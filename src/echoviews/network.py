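"""Minimal NumPy neural-network engine for the frame classifier.

Implements exactly the pieces the view classifier needs -- strided 3x3
convolutions (im2col), group/batch normalization, optional weight
standardization, ReLU, average pooling, a linear head, softmax
cross-entropy and an AdamW optimizer with decoupled weight decay.  All
backward passes are written by hand and verified against central finite
differences in the test suite.

The engine is deliberately small: a single fixed topology (four conv blocks
with stride 2, global average pooling, one linear class mapping) known as
the "small CNN" backbone.  It processes frames independently; temporal
aggregation happens outside the network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["SmallCNN", "AdamW", "softmax", "cross_entropy"]

_EPS = 1e-5


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype) -> np.ndarray:
    return (rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)).astype(dtype)


class Conv2d:
    """3x3 convolution, stride s, zero padding 1, optional weight standardization."""

    def __init__(self, cin: int, cout: int, stride: int, rng, dtype,
                 k: int = 3, pad: int = 1, weight_standardization: bool = False):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        self.ws = weight_standardization
        self.params = {
            "W": _he_init(rng, (cout, cin, k, k), cin * k * k, dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def _standardized(self):
        W = self.params["W"]
        flat = W.reshape(self.cout, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        sig = np.sqrt(var + _EPS)
        What = ((flat - mu) / sig).reshape(W.shape)
        return What, flat, mu, sig

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # win: (N, C, Ho, Wo, k, k) -> cols (N*Ho*Wo, C*k*k)
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        if self.ws:
            Wk, self._flat, self._mu, self._sig = self._standardized()
        else:
            Wk = self.params["W"]
        Wm = Wk.reshape(self.cout, -1).T
        out = cols @ Wm + self.params["b"]
        self._cache = (cols, x.shape, Ho, Wo, Wk)
        return out.reshape(N, Ho, Wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, Ho, Wo, Wk = self._cache
        N, C, H, W = xshape
        k, s, p = self.k, self.stride, self.pad
        dm = dout.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        dWflat = (cols.T @ dm).T  # (cout, C*k*k)
        self.grads["b"][...] = dm.sum(axis=0)
        if self.ws:
            # chain through per-filter standardization (layer-norm jacobian)
            What = Wk.reshape(self.cout, -1)
            dWhat = dWflat
            m1 = dWhat.mean(axis=1, keepdims=True)
            m2 = (dWhat * What).mean(axis=1, keepdims=True)
            dW = (dWhat - m1 - What * m2) / self._sig
            self.grads["W"][...] = dW.reshape(self.params["W"].shape)
        else:
            self.grads["W"][...] = dWflat.reshape(self.params["W"].shape)

        dcols = (dm @ Wk.reshape(self.cout, -1)).reshape(N, Ho, Wo, C, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, C, Ho, Wo, k, k)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + H, p:p + W]


class GroupNorm:
    def __init__(self, channels: int, groups: int, dtype):
        if channels % groups:
            raise ValueError("channels must be divisible by groups")
        self.c, self.g = channels, groups
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xg = x.reshape(N, self.g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        sig = np.sqrt(xg.var(axis=2, keepdims=True) + _EPS)
        xhat = ((xg - mu) / sig).reshape(x.shape)
        self._cache = (xhat, sig, x.shape)
        return xhat * self.params["gamma"][:, None, None] + self.params["beta"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, sig, shape = self._cache
        N, C, H, W = shape
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        dxhat = (dout * self.params["gamma"][:, None, None]).reshape(N, self.g, -1)
        xh = xhat.reshape(N, self.g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = (dxhat - m1 - xh * m2) / sig
        return dx.reshape(shape)


class BatchNorm2d:
    def __init__(self, channels: int, dtype, momentum: float = 0.1):
        self.c = channels
        self.momentum = momentum
        self.params = {"gamma": np.ones(channels, dtype=dtype),
                       "beta": np.zeros(channels, dtype=dtype)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        sig = np.sqrt(var + _EPS)
        xhat = (x - mu[:, None, None]) / sig[:, None, None]
        self._cache = (xhat, sig, train)
        return xhat * self.params["gamma"][:, None, None] + self.params["beta"][:, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, sig, train = self._cache
        self.grads["gamma"][...] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.params["gamma"][:, None, None]
        if not train:
            return dxhat / sig[:, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        m1 = dxhat.sum(axis=(0, 2, 3)) / m
        m2 = (dxhat * xhat).sum(axis=(0, 2, 3)) / m
        return (dxhat - m1[:, None, None] - xhat * m2[:, None, None]) / sig[:, None, None]


class Linear:
    def __init__(self, din: int, dout: int, rng, dtype):
        self.params = {"W": _he_init(rng, (din, dout), din, dtype),
                       "b": np.zeros(dout, dtype=dtype)}
        self.grads = {n: np.zeros_like(p) for n, p in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-300)).mean()
    dlogits = p
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), (dlogits / n).astype(logits.dtype)


class SmallCNN:
    """Four-block strided CNN over single-channel frames.

    Topology: input average-pool (factor ``in_pool``) -> four blocks of
    [3x3 conv stride 2 -> norm -> ReLU] with channel widths
    (D/8, D/4, D/2, D) -> global average pooling (the D-dimensional
    penultimate features, non-negative post-ReLU) -> linear map to
    ``n_out`` class logits.  Input spatial size is free (>= 32 after the
    input pool); the default 224x224 input yields 56 -> 28 -> 14 -> 7 -> 4
    feature grids.
    """

    def __init__(self, n_out: int, embedding_dim: int = 128,
                 norm: str = "group_norm", weight_standardization: bool = False,
                 in_pool: int = 4, seed: int = 0, dtype=np.float32):
        if embedding_dim < 8 or embedding_dim % 8:
            raise ValueError("embedding_dim must be a multiple of 8, >= 8")
        if norm not in ("group_norm", "batch_norm"):
            raise ValueError("norm must be 'group_norm' or 'batch_norm'")
        rng = np.random.default_rng(seed)
        self.n_out = n_out
        self.embedding_dim = embedding_dim
        self.norm = norm
        self.in_pool = in_pool
        self.dtype = dtype
        D = embedding_dim
        widths = [D // 8, D // 4, D // 2, D]
        self.convs: list[Conv2d] = []
        self.norms: list[GroupNorm | BatchNorm2d] = []
        cin = 1
        for w in widths:
            self.convs.append(Conv2d(cin, w, stride=2, rng=rng, dtype=dtype,
                                     weight_standardization=weight_standardization))
            if norm == "group_norm":
                self.norms.append(GroupNorm(w, groups=max(1, w // 8), dtype=dtype))
            else:
                self.norms.append(BatchNorm2d(w, dtype=dtype))
            cin = w
        self.head = Linear(D, n_out, rng, dtype)

    # -- parameter plumbing -------------------------------------------------
    def _modules(self):
        mods = {}
        for i, (c, nm) in enumerate(zip(self.convs, self.norms)):
            mods[f"conv{i}"] = c
            mods[f"norm{i}"] = nm
        mods["head"] = self.head
        return mods

    def parameters(self) -> dict[str, np.ndarray]:
        return {f"{mn}.{pn}": p for mn, m in self._modules().items()
                for pn, p in m.params.items()}

    def gradients(self) -> dict[str, np.ndarray]:
        return {f"{mn}.{pn}": g for mn, m in self._modules().items()
                for pn, g in m.grads.items()}

    def state_dict(self) -> dict[str, np.ndarray]:
        sd = dict(self.parameters())
        for mn, m in self._modules().items():
            if isinstance(m, BatchNorm2d):
                sd[f"{mn}.running_mean"] = m.running_mean
                sd[f"{mn}.running_var"] = m.running_var
        return sd

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for mn, m in self._modules().items():
            for pn in m.params:
                m.params[pn][...] = sd[f"{mn}.{pn}"]
            if isinstance(m, BatchNorm2d):
                m.running_mean[...] = sd[f"{mn}.running_mean"]
                m.running_var[...] = sd[f"{mn}.running_var"]

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """Run frames through the network.

        ``x`` is (N, H, W) or (N, 1, H, W) in [0, 1]; returns per-frame
        logits (N, n_out) and penultimate features (N, D).  Frames are
        processed independently, so batching never changes outputs beyond
        floating-point reordering.
        """
        if x.ndim == 3:
            x = x[:, None]
        x = x.astype(self.dtype, copy=False)
        f = self.in_pool
        N, C, H, W = x.shape
        if H % f or W % f:
            raise ValueError(f"input size must be divisible by in_pool={f}")
        x = x.reshape(N, C, H // f, f, W // f, f).mean(axis=(3, 5))
        relu_outs = []
        for conv, nm in zip(self.convs, self.norms):
            x = conv.forward(x)
            x = nm.forward(x, train) if isinstance(nm, BatchNorm2d) else nm.forward(x)
            x = np.maximum(x, 0.0)
            relu_outs.append(x)
        self._relu_outs = relu_outs
        feats = x.mean(axis=(2, 3))
        self._feats_hw = x.shape[2] * x.shape[3]
        logits = self.head.forward(feats)
        return logits, feats

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dfeats = self.head.backward(dlogits)
        outs = self._relu_outs
        h = outs[-1]
        dx = np.broadcast_to(dfeats[:, :, None, None] / self._feats_hw, h.shape)
        dx = dx.astype(h.dtype).copy()
        dx[h <= 0] = 0.0
        for i in range(len(self.convs) - 1, -1, -1):
            dx = self.norms[i].backward(dx)
            dx = self.convs[i].backward(dx)
            if i > 0:
                dx[outs[i - 1] <= 0] = 0.0
        return None


class AdamW:
    """Adam with decoupled weight decay (applied to every parameter)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.0, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {n: np.zeros_like(p) for n, p in params.items()}
        self.v = {n: np.zeros_like(p) for n, p in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for n, p in self.params.items():
            g = grads[n]
            self.m[n] = b1 * self.m[n] + (1 - b1) * g
            self.v[n] = b2 * self.v[n] + (1 - b2) * (g * g)
            mhat = self.m[n] / c1
            vhat = self.v[n] / c2
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)
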