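"""Minimal NumPy implementation of the two connectome-CNN branches.

The architectures are small and fixed, so forward and backward passes are
written out explicitly rather than through a general autodiff graph:

static branch (input 1 x R x R):
    conv 32 filters, kernel 1 x R  -> (32, R, 1)
    BN, LeakyReLU
    conv 64 filters, kernel R x 1  -> (64, 1, 1)
    BN, LeakyReLU
    conv 16 filters, kernel 1 x 1  -> (16, 1, 1)
    BN, LeakyReLU, flatten, dropout
    attention: dense 16->8, ReLU, dense 8->16, sigmoid; features = gate * input
    head: dense 16->2 (softmax cross-entropy; used only to fit parameters)

dynamic branch (input Q x R x R): prepends a channel-compression conv with a
single 1 x 1 filter over the Q frequency channels, BN, LeakyReLU, then the
same stack.

With kernels spanning whole rows/columns the convolutions reduce to dense
contractions (einsum), which keeps the implementation exact and fast on CPU.
Training uses Adam on the softmax cross-entropy of the auxiliary head.  All
randomness (init, shuffling, dropout) flows from one numpy Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BranchNet", "train_branch"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _BatchNorm:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, n_channels: int):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.dgamma = np.zeros(n_channels)
        self.dbeta = np.zeros(n_channels)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool, channel_axis: int = 1) -> np.ndarray:
        axes = tuple(a for a in range(x.ndim) if a != channel_axis)
        shape = [1] * x.ndim
        shape[channel_axis] = -1
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[channel_axis]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mu
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * unbiased
        else:
            mu = self.running_mean
            var = self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu.reshape(shape)) * inv_std.reshape(shape)
        out = self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)
        if train:
            self._cache = (xhat, inv_std, axes, shape, x.size // x.shape[channel_axis])
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape, n = self._cache
        self.dgamma += (dout * xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma.reshape(shape)
        sum_dxhat = dxhat.sum(axis=axes, keepdims=True)
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=axes, keepdims=True)
        return (inv_std.reshape(shape) / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)

    def params(self) -> dict[str, np.ndarray]:
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self) -> dict[str, np.ndarray]:
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self) -> dict[str, np.ndarray]:
        return {
            "gamma": self.gamma, "beta": self.beta,
            "running_mean": self.running_mean, "running_var": self.running_var,
        }

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.gamma = np.array(state["gamma"])
        self.beta = np.array(state["beta"])
        self.running_mean = np.array(state["running_mean"])
        self.running_var = np.array(state["running_var"])


class BranchNet:
    """One CNN feature-extraction branch (static or dynamic)."""

    N_FEATURES = 16

    def __init__(
        self,
        kind: str,
        n_roi: int,
        n_channels: int = 1,
        *,
        dropout: float = 0.5,
        leaky_slope: float = 0.01,
        rng: np.random.Generator | int | None = 0,
    ):
        if kind not in ("static", "dynamic"):
            raise ValueError(f"kind must be 'static' or 'dynamic', got {kind!r}")
        if n_roi < 2:
            raise ValueError("n_roi must be >= 2")
        if kind == "static" and n_channels != 1:
            raise ValueError("static branch takes a single input channel")
        if kind == "dynamic" and n_channels < 1:
            raise ValueError("dynamic branch needs >= 1 frequency channels")
        self.kind = kind
        self.n_roi = n_roi
        self.n_channels = n_channels
        self.dropout = dropout
        self.leaky_slope = leaky_slope
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

        def uniform(shape, fan_in, scale=1.0):
            bound = scale / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        # The channel-compression and first row-convolution kernels are read
        # back as band/region importance after training, so they start at a
        # tenth of the usual fan-in bound: trained magnitudes then reflect
        # accumulated learning rather than the random draw (Adam's step sizes
        # are invariant to init scale, and the following BN renormalizes, so
        # optimization is unaffected).
        interp_scale = 0.1
        r, q = n_roi, n_channels
        self.W: dict[str, np.ndarray] = {}
        if kind == "dynamic":
            self.W["Wc"] = uniform((q,), q, interp_scale)  # compression, one 1x1 filter
            self.W["bc"] = uniform((1,), q)
            self.bn0 = _BatchNorm(1)
        self.W["W1"] = uniform((32, r), r, interp_scale)   # 32 filters, kernel 1 x R
        self.W["b1"] = uniform((32,), r)
        self.bn1 = _BatchNorm(32)
        self.W["W2"] = uniform((64, 32, r), 32 * r)  # 64 filters, kernel R x 1
        self.W["b2"] = uniform((64,), 32 * r)
        self.bn2 = _BatchNorm(64)
        self.W["W3"] = uniform((16, 64), 64)      # 16 filters, kernel 1 x 1
        self.W["b3"] = uniform((16,), 64)
        self.bn3 = _BatchNorm(16)
        self.W["Wa1"] = uniform((8, 16), 16)      # attention hidden
        self.W["ba1"] = uniform((8,), 16)
        self.W["Wa2"] = uniform((16, 8), 8)       # attention gate
        self.W["ba2"] = uniform((16,), 8)
        self.W["Wh"] = uniform((2, 16), 16)       # auxiliary 2-class head
        self.W["bh"] = uniform((2,), 16)
        self.G: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in self.W.items()}
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        self._adam_t = 0

    # ----------------------------------------------------------------- forward
    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "static":
            if x.ndim == 2:
                x = x[None]
            if x.ndim != 3 or x.shape[1] != self.n_roi or x.shape[2] != self.n_roi:
                raise ValueError(
                    f"static branch expects (B, {self.n_roi}, {self.n_roi}), got {x.shape}"
                )
        else:
            if x.ndim == 3:
                x = x[None]
            expected = (self.n_channels, self.n_roi, self.n_roi)
            if x.ndim != 4 or x.shape[1:] != expected:
                raise ValueError(
                    f"dynamic branch expects (B, {expected[0]}, {expected[1]}, "
                    f"{expected[2]}), got {x.shape}"
                )
        return x

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        drop_rng: np.random.Generator | None = None,
    ) -> dict[str, np.ndarray]:
        """Run the branch; returns activations including 'features', 'gate', 'logits'."""
        x = self._validate_input(x)
        W, slope = self.W, self.leaky_slope
        cache: dict[str, np.ndarray] = {"x": x}

        if self.kind == "dynamic":
            comp = np.einsum("bqrc,q->brc", x, W["Wc"]) + W["bc"][0]
            comp_bn = self.bn0.forward(comp[:, None], train)[:, 0]  # channel axis of size 1
            cache["comp"], cache["comp_bn"] = comp, comp_bn
            maps = _leaky(comp_bn, slope)
        else:
            maps = x
        cache["maps"] = maps

        h1 = np.einsum("brj,fj->bfr", maps, W["W1"]) + W["b1"][None, :, None]
        h1_bn = self.bn1.forward(h1, train)
        a1 = _leaky(h1_bn, slope)
        cache["h1"], cache["h1_bn"], cache["a1"] = h1, h1_bn, a1

        h2 = np.einsum("bfr,gfr->bg", a1, W["W2"]) + W["b2"]
        h2_bn = self.bn2.forward(h2, train)
        a2 = _leaky(h2_bn, slope)
        cache["h2"], cache["h2_bn"], cache["a2"] = h2, h2_bn, a2

        h3 = a2 @ W["W3"].T + W["b3"]
        h3_bn = self.bn3.forward(h3, train)
        a3 = _leaky(h3_bn, slope)
        cache["h3"], cache["h3_bn"], cache["a3"] = h3, h3_bn, a3

        if train and self.dropout > 0:
            if drop_rng is None:
                raise ValueError("training forward pass needs a dropout RNG")
            mask = (drop_rng.random(a3.shape) >= self.dropout) / (1.0 - self.dropout)
        else:
            mask = np.ones_like(a3)
        z = a3 * mask
        cache["mask"], cache["z"] = mask, z

        att_pre1 = z @ W["Wa1"].T + W["ba1"]
        att_h = np.maximum(att_pre1, 0.0)
        att_pre2 = att_h @ W["Wa2"].T + W["ba2"]
        gate = _sigmoid(att_pre2)
        features = gate * z
        cache["att_pre1"], cache["att_h"] = att_pre1, att_h
        cache["gate"], cache["features"] = gate, features

        cache["logits"] = features @ W["Wh"].T + W["bh"]
        return cache

    # ---------------------------------------------------------------- backward
    def zero_grad(self) -> None:
        for g in self.G.values():
            g[...] = 0.0
        for bn in self._bns():
            bn.dgamma[...] = 0.0
            bn.dbeta[...] = 0.0

    def _bns(self) -> list[_BatchNorm]:
        bns = [self.bn1, self.bn2, self.bn3]
        if self.kind == "dynamic":
            bns.insert(0, self.bn0)
        return bns

    def loss_and_grads(
        self,
        x: np.ndarray,
        y: np.ndarray,
        drop_rng: np.random.Generator | None = None,
        train: bool = True,
    ) -> float:
        """Softmax cross-entropy of the auxiliary head; accumulates gradients."""
        cache = self.forward(x, train=train, drop_rng=drop_rng)
        logits = cache["logits"]
        y = np.asarray(y, dtype=int)
        b = logits.shape[0]
        shifted = logits - logits.max(axis=1, keepdims=True)
        log_probs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        loss = -log_probs[np.arange(b), y].mean()
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        probs = np.exp(log_probs)
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        self._backward(dlogits, cache)
        return float(loss)

    def _backward(self, dlogits: np.ndarray, cache: dict[str, np.ndarray]) -> None:
        W, G, slope = self.W, self.G, self.leaky_slope
        z, gate = cache["z"], cache["gate"]

        G["Wh"] += dlogits.T @ cache["features"]
        G["bh"] += dlogits.sum(axis=0)
        dfeat = dlogits @ W["Wh"]

        dgate = dfeat * z
        dz = dfeat * gate
        datt2 = dgate * gate * (1.0 - gate)
        G["Wa2"] += datt2.T @ cache["att_h"]
        G["ba2"] += datt2.sum(axis=0)
        datt_h = datt2 @ W["Wa2"]
        datt1 = datt_h * (cache["att_pre1"] > 0)
        G["Wa1"] += datt1.T @ z
        G["ba1"] += datt1.sum(axis=0)
        dz += datt1 @ W["Wa1"]

        da3 = dz * cache["mask"]
        dh3_bn = da3 * _leaky_grad(cache["h3_bn"], slope)
        dh3 = self.bn3.backward(dh3_bn)
        G["W3"] += dh3.T @ cache["a2"]
        G["b3"] += dh3.sum(axis=0)
        da2 = dh3 @ W["W3"]

        dh2_bn = da2 * _leaky_grad(cache["h2_bn"], slope)
        dh2 = self.bn2.backward(dh2_bn)
        G["W2"] += np.einsum("bg,bfr->gfr", dh2, cache["a1"])
        G["b2"] += dh2.sum(axis=0)
        da1 = np.einsum("bg,gfr->bfr", dh2, W["W2"])

        dh1_bn = da1 * _leaky_grad(cache["h1_bn"], slope)
        dh1 = self.bn1.backward(dh1_bn)
        G["W1"] += np.einsum("bfr,brj->fj", dh1, cache["maps"])
        G["b1"] += dh1.sum(axis=(0, 2))
        if self.kind == "dynamic":
            dmaps = np.einsum("bfr,fj->brj", dh1, W["W1"])
            dcomp_bn = dmaps * _leaky_grad(cache["comp_bn"], slope)
            dcomp = self.bn0.backward(dcomp_bn[:, None])[:, 0]
            G["Wc"] += np.einsum("brc,bqrc->q", dcomp, cache["x"])
            G["bc"] += dcomp.sum(keepdims=True).reshape(1)

    # -------------------------------------------------------------------- adam
    def adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        params, grads = self._all_params()
        if self._adam is None:
            self._adam = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in params.items()}
        self._adam_t += 1
        t = self._adam_t
        for key, p in params.items():
            g = grads[key]
            m, v = self._adam[key]
            m[...] = beta1 * m + (1 - beta1) * g
            v[...] = beta2 * v + (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def _all_params(self) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
        params = dict(self.W)
        grads = dict(self.G)
        for i, bn in enumerate(self._bns()):
            tag = f"bn{i}"
            for name, arr in bn.params().items():
                params[f"{tag}.{name}"] = arr
            for name, arr in bn.grads().items():
                grads[f"{tag}.{name}"] = arr
        return params, grads

    # ------------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.W.items()}
        for i, bn in enumerate(self._bns()):
            for name, arr in bn.state().items():
                state[f"bn{i}.{name}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.W:
            self.W[k] = np.array(state[k])
        self.G = {k: np.zeros_like(v) for k, v in self.W.items()}
        for i, bn in enumerate(self._bns()):
            bn.load_state({name: state[f"bn{i}.{name}"] for name in
                           ("gamma", "beta", "running_mean", "running_var")})


def train_branch(
    net: BranchNet,
    x: np.ndarray,
    y: np.ndarray,
    *,
    learning_rate: float = 1e-4,
    max_epochs: int = 50,
    batch_size: int = 8,
    seed: int = 0,
) -> list[float]:
    """Train the auxiliary head with Adam; returns the per-epoch mean loss trace."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires both classes to be present")
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    trace: list[float] = []
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            net.zero_grad()
            try:
                loss = net.loss_and_grads(x[idx], y[idx], drop_rng=rng)
            except FloatingPointError as exc:
                raise FloatingPointError(f"epoch {epoch}: {exc}") from exc
            net.adam_step(learning_rate)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace
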