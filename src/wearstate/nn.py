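"""NumPy implementation of the multichannel network: forward, backprop, optimizers.

The model is small (~130k parameters over inputs of at most 15 features),
so plain vectorized NumPy is entirely adequate on one CPU.  Convolutions
are valid (no padding), stride 1, computed via sliding windows and
``einsum``; dropout is the inverted form, active only during training;
initialization is Glorot-uniform from a caller-supplied seeded generator,
making whole training runs bit-reproducible.

Optimizers implement the update rules of SGD, RMSprop and Adam with the
time-decayed learning rate ``lr_t = lr / (1 + decay * t)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .network import ModelSpec, forward_shapes

__all__ = ["MultichannelCNN", "SGD", "RMSprop", "Adam", "make_optimizer", "softmax"]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (n, L, c), W (k, c, f) -> (n, L-k+1, f)."""
    k = W.shape[0]
    win = sliding_window_view(x, k, axis=1)  # (n, L_out, c, k)
    return np.einsum("nlck,kcf->nlf", win, W) + b


def _conv_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray):
    k = W.shape[0]
    win = sliding_window_view(x, k, axis=1)
    dW = np.einsum("nlck,nlf->kcf", win, dout)
    db = dout.sum(axis=(0, 1))
    dx = np.zeros_like(x)
    L_out = dout.shape[1]
    for i in range(k):
        dx[:, i:i + L_out, :] += np.einsum("nlf,cf->nlc", dout, W[i])
    return dW, db, dx


class MultichannelCNN:
    """Trainable realization of a :class:`~wearstate.network.ModelSpec`.

    Parameters live in ``self.params`` (name -> array).  ``forward`` takes
    a dict of per-channel inputs ``{channel: (n, x) array}`` and returns
    class probabilities; with ``train=True`` dropout is applied using the
    generator given at construction, and a cache for ``backward`` is kept.
    """

    def __init__(self, spec: ModelSpec, seed: int | np.random.Generator = 0):
        self.spec = spec
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        shapes = forward_shapes(spec)
        self._flat: dict[str, int] = {}
        for ch, x in spec.channel_features.items():
            conv = [l for l in spec.branches[ch] if l.kind == "conv1d"]
            k = conv[0].kernel
            f1, f2 = conv[0].units, conv[1].units
            flat = next(s for s in shapes["branches"][ch] if isinstance(s, int))
            self._flat[ch] = flat
            self.params[f"{ch}/conv1/W"] = _glorot(self.rng, (k, 1, f1), k * 1, k * f1)
            self.params[f"{ch}/conv1/b"] = np.zeros(f1)
            self.params[f"{ch}/conv2/W"] = _glorot(self.rng, (k, f1, f2), k * f1, k * f2)
            self.params[f"{ch}/conv2/b"] = np.zeros(f2)
            self.params[f"{ch}/dense1/W"] = _glorot(self.rng, (flat, 64), flat, 64)
            self.params[f"{ch}/dense1/b"] = np.zeros(64)
            self.params[f"{ch}/dense2/W"] = _glorot(self.rng, (64, 32), 64, 32)
            self.params[f"{ch}/dense2/b"] = np.zeros(32)
        concat = 32 * len(spec.channel_features)
        self.params["trunk/dense/W"] = _glorot(self.rng, (concat, 32), concat, 32)
        self.params["trunk/dense/b"] = np.zeros(32)
        self.params["trunk/out/W"] = _glorot(self.rng, (32, 5), 32, 5)
        self.params["trunk/out/b"] = np.zeros(5)

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward -----------------------------------------------------------

    def _branch_forward(self, ch: str, x: np.ndarray, train: bool, cache: dict | None):
        P = self.params
        rate = self.spec.dropout_rate
        x3 = x[:, :, None]
        z1 = _conv_forward(x3, P[f"{ch}/conv1/W"], P[f"{ch}/conv1/b"])
        a1 = np.maximum(z1, 0)
        z2 = _conv_forward(a1, P[f"{ch}/conv2/W"], P[f"{ch}/conv2/b"])
        a2 = np.maximum(z2, 0)
        flat = a2.reshape(len(x), -1)
        if train and rate > 0:
            m1 = (self.rng.random(flat.shape) >= rate) / (1 - rate)
            flat = flat * m1
        z3 = flat @ P[f"{ch}/dense1/W"] + P[f"{ch}/dense1/b"]
        a3 = np.maximum(z3, 0)
        if train and rate > 0:
            m2 = (self.rng.random(a3.shape) >= rate) / (1 - rate)
            a3d = a3 * m2
        else:
            a3d = a3
        z4 = a3d @ P[f"{ch}/dense2/W"] + P[f"{ch}/dense2/b"]
        a4 = np.maximum(z4, 0)
        if cache is not None:
            cache[ch] = {
                "x3": x3, "z1": z1, "a1": a1, "z2": z2, "a2": a2,
                "flat": flat, "z3": z3, "a3d": a3d, "z4": z4,
                "m1": m1 if train and rate > 0 else None,
                "m2": m2 if train and rate > 0 else None,
            }
        return a4

    def branch_outputs(self, xs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        """Pre-concatenation (dense-32) activations per branch, eval mode."""
        return {ch: self._branch_forward(ch, np.asarray(xs[ch], dtype=np.float64), False, None)
                for ch in self.spec.channel_features}

    def forward(self, xs: dict[str, np.ndarray], train: bool = False):
        """Class probabilities (n, 5); also returns the backprop cache."""
        P = self.params
        cache: dict = {"train": train, "branches": {}}
        outs = []
        for ch in self.spec.channel_features:
            outs.append(self._branch_forward(ch, np.asarray(xs[ch], dtype=np.float64),
                                             train, cache["branches"]))
        concat = np.hstack(outs)
        zt = concat @ P["trunk/dense/W"] + P["trunk/dense/b"]
        at = np.maximum(zt, 0)
        logits = at @ P["trunk/out/W"] + P["trunk/out/b"]
        probs = softmax(logits)
        cache.update(concat=concat, zt=zt, at=at, probs=probs)
        return probs, cache

    def predict_proba(self, xs: dict[str, np.ndarray]) -> np.ndarray:
        return self.forward(xs, train=False)[0]

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, y_onehot: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of mean categorical cross-entropy w.r.t. every parameter."""
        P = self.params
        n = len(y_onehot)
        g: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / n
        g["trunk/out/W"] = cache["at"].T @ dlogits
        g["trunk/out/b"] = dlogits.sum(axis=0)
        dat = dlogits @ P["trunk/out/W"].T
        dzt = dat * (cache["zt"] > 0)
        g["trunk/dense/W"] = cache["concat"].T @ dzt
        g["trunk/dense/b"] = dzt.sum(axis=0)
        dconcat = dzt @ P["trunk/dense/W"].T
        off = 0
        for ch in self.spec.channel_features:
            c = cache["branches"][ch]
            da4 = dconcat[:, off:off + 32]
            off += 32
            dz4 = da4 * (c["z4"] > 0)
            g[f"{ch}/dense2/W"] = c["a3d"].T @ dz4
            g[f"{ch}/dense2/b"] = dz4.sum(axis=0)
            da3d = dz4 @ P[f"{ch}/dense2/W"].T
            if c["m2"] is not None:
                da3d = da3d * c["m2"]
            dz3 = da3d * (c["z3"] > 0)
            g[f"{ch}/dense1/W"] = c["flat"].T @ dz3
            g[f"{ch}/dense1/b"] = dz3.sum(axis=0)
            dflat = dz3 @ P[f"{ch}/dense1/W"].T
            if c["m1"] is not None:
                dflat = dflat * c["m1"]
            da2 = dflat.reshape(c["a2"].shape)
            dz2 = da2 * (c["z2"] > 0)
            dW2, db2, da1 = _conv_backward(c["a1"], P[f"{ch}/conv2/W"], dz2)
            g[f"{ch}/conv2/W"], g[f"{ch}/conv2/b"] = dW2, db2
            dz1 = da1 * (c["z1"] > 0)
            dW1, db1, _ = _conv_backward(c["x3"], P[f"{ch}/conv1/W"], dz1)
            g[f"{ch}/conv1/W"], g[f"{ch}/conv1/b"] = dW1, db1
        return g

    # -- (de)serialization -------------------------------------------------

    def save(self, path) -> None:
        """Weights to .npz alongside the JSON model spec (same stem)."""
        from pathlib import Path

        path = Path(path)
        np.savez(path, **self.params)
        self.spec.to_json(path.with_suffix(".json"))

    @classmethod
    def load(cls, path) -> "MultichannelCNN":
        from pathlib import Path

        path = Path(path)
        spec = ModelSpec.from_json(path.with_suffix(".json"))
        net = cls(spec, seed=0)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as z:
            for k in net.params:
                net.params[k] = z[k]
        return net


class _Optimizer:
    def __init__(self, lr: float, decay: float = 0.0):
        self.lr, self.decay, self.t = lr, decay, 0

    def _lr_t(self) -> float:
        return self.lr / (1.0 + self.decay * self.t)

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        lr = self._lr_t()
        self.t += 1
        self._update(params, grads, lr)


class SGD(_Optimizer):
    def _update(self, params, grads, lr):
        for k in params:
            params[k] -= lr * grads[k]


class RMSprop(_Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-7, decay: float = 0.0):
        super().__init__(lr, decay)
        self.rho, self.eps = rho, eps
        self.v: dict[str, np.ndarray] = {}

    def _update(self, params, grads, lr):
        for k in params:
            v = self.v.setdefault(k, np.zeros_like(params[k]))
            v *= self.rho
            v += (1 - self.rho) * grads[k] ** 2
            params[k] -= lr * grads[k] / (np.sqrt(v) + self.eps)


class Adam(_Optimizer):
    def __init__(self, lr: float, beta_1: float = 0.9, beta_2: float = 0.999,
                 eps: float = 1e-7, decay: float = 0.0):
        super().__init__(lr, decay)
        self.b1, self.b2, self.eps = beta_1, beta_2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def _update(self, params, grads, lr):
        t = self.t  # already incremented to 1-based by step()
        for k in params:
            m = self.m.setdefault(k, np.zeros_like(params[k]))
            v = self.v.setdefault(k, np.zeros_like(params[k]))
            m *= self.b1
            m += (1 - self.b1) * grads[k]
            v *= self.b2
            v += (1 - self.b2) * grads[k] ** 2
            mhat = m / (1 - self.b1**t)
            vhat = v / (1 - self.b2**t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def make_optimizer(name: str, lr: float, beta_1: float = 0.9, beta_2: float = 0.999,
                   decay: float = 0.0) -> _Optimizer:
    """Factory over {sgd, rmsprop, adam}; betas apply to Adam only."""
    name = name.lower()
    if name == "sgd":
        return SGD(lr, decay=decay)
    if name == "rmsprop":
        return RMSprop(lr, decay=decay)
    if name == "adam":
        return Adam(lr, beta_1=beta_1, beta_2=beta_2, decay=decay)
    raise ValueError(f"unknown optimizer {name!r}")
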