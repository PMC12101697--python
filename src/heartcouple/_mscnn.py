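"""Minimal numpy implementation of the multiscale-kernel 1-D CNN.

The network treats the selected coupling-feature vector as a 1-D sequence.
Parallel branches convolve it with kernels of different sizes (a 1-wide
branch is always present); each branch stacks two convolutions with a ReLU
between them. Branch outputs are concatenated along the channel axis, then
batch-normalized, rectified and max-pooled, and a small fully connected
head produces class probabilities through softmax.

Everything (forward, backward, Adam) is plain numpy with explicit
gradients, which keeps training bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class _Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1-D convolution with 'same' zero padding. x: (B,C,L), w: (F,C,k)."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C, L, k)
    return np.einsum("fck,bclk->bfl", w, win) + b[None, :, None]


def _conv_same_backward(
    x: np.ndarray, w: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _conv_same w.r.t. (x, w, b) given upstream grad g (B,F,L)."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
    win = sliding_window_view(xp, k, axis=2)
    gw = np.einsum("bfl,bclk->fck", g, win)
    gb = g.sum(axis=(0, 2))
    gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
    gwin = sliding_window_view(gp, k, axis=2)  # (B, F, L, k)
    gx = np.einsum("fck,bflk->bcl", w[:, :, ::-1], gwin)
    return gx, gw, gb


class MultiScaleCNN:
    """Multiscale-kernel 1-D CNN over a feature vector of length ``n_features``."""

    def __init__(self, n_features: int, n_classes: int, cfg, rng_seed: int | None = None):
        ks = list(cfg.kernel_sizes)
        if 1 not in ks:
            raise ValueError("kernel_sizes must include 1")
        if len(ks) < 2:
            raise ValueError("need at least 2 kernel sizes")
        if any(k % 2 == 0 for k in ks):
            raise ValueError("kernel sizes must be odd (same-padding convolutions)")
        if max(ks) > n_features:
            raise ValueError(
                f"kernel size {max(ks)} exceeds input length {n_features}"
            )
        if cfg.conv_layers_per_branch != 2:
            raise ValueError("each branch has exactly two convolutional layers")
        self.cfg = cfg
        self.n_features = n_features
        self.n_classes = n_classes
        self.kernel_sizes = ks
        f = cfg.filters_per_branch
        seed = cfg.seed if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.branches = []
        for k in ks:
            w1 = _Param(he((f, 1, k), 1 * k))
            b1 = _Param(np.zeros(f))
            w2 = _Param(he((f, f, k), f * k))
            b2 = _Param(np.zeros(f))
            self.branches.append((w1, b1, w2, b2))
        c_total = f * len(ks)
        self.gamma = _Param(np.ones(c_total))
        self.beta = _Param(np.zeros(c_total))
        self.running_mean = np.zeros(c_total)
        self.running_var = np.ones(c_total)
        self.bn_momentum = 0.1
        self.bn_eps = 1e-5
        self.pool = cfg.pool_size
        l_pooled = n_features // self.pool
        if l_pooled < 1:
            raise ValueError("pool_size too large for input length")
        flat = c_total * l_pooled
        self.fc1_w = _Param(he((cfg.fc_units, flat), flat))
        self.fc1_b = _Param(np.zeros(cfg.fc_units))
        self.fc2_w = _Param(he((n_classes, cfg.fc_units), cfg.fc_units))
        self.fc2_b = _Param(np.zeros(n_classes))
        self._step = 0

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list[_Param]:
        ps: list[_Param] = []
        for w1, b1, w2, b2 in self.branches:
            ps += [w1, b1, w2, b2]
        ps += [self.gamma, self.beta, self.fc1_w, self.fc1_b, self.fc2_w, self.fc2_b]
        return ps

    # -- forward -----------------------------------------------------------
    def _forward(self, x2d: np.ndarray, train: bool):
        x = np.asarray(x2d, dtype=float)[:, None, :]  # (B, 1, L)
        cache: dict = {"x": x}
        outs = []
        for idx, (w1, b1, w2, b2) in enumerate(self.branches):
            z1 = _conv_same(x, w1.value, b1.value)
            a1 = np.maximum(z1, 0.0)
            z2 = _conv_same(a1, w2.value, b2.value)
            cache[f"z1_{idx}"] = z1
            cache[f"a1_{idx}"] = a1
            outs.append(z2)
        concat = np.concatenate(outs, axis=1)  # (B, C, L)
        cache["concat"] = concat

        if train:
            mu = concat.mean(axis=(0, 2))
            var = concat.var(axis=(0, 2))
            self.running_mean = (1 - self.bn_momentum) * self.running_mean + self.bn_momentum * mu
            self.running_var = (1 - self.bn_momentum) * self.running_var + self.bn_momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.bn_eps)
        xhat = (concat - mu[None, :, None]) * ivar[None, :, None]
        bn = self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]
        cache.update(xhat=xhat, ivar=ivar, mu=mu)

        act = np.maximum(bn, 0.0)
        cache["bn"] = bn
        b_sz, c, length = act.shape
        l_pool = length // self.pool
        pooled_in = act[:, :, : l_pool * self.pool].reshape(b_sz, c, l_pool, self.pool)
        pooled = pooled_in.max(axis=3)
        cache["pool_argmax"] = pooled_in.argmax(axis=3)
        cache["act_shape"] = act.shape

        flat = pooled.reshape(b_sz, -1)
        h = flat @ self.fc1_w.value.T + self.fc1_b.value
        hr = np.maximum(h, 0.0)
        logits = hr @ self.fc2_w.value.T + self.fc2_b.value
        cache.update(flat=flat, h=h, hr=hr)
        return logits, cache

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, x2d: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(x2d, train=False)
        return self._softmax(logits)

    def predict(self, x2d: np.ndarray) -> np.ndarray:
        return self.predict_proba(x2d).argmax(axis=1)

    # -- backward ----------------------------------------------------------
    def _backward(self, cache: dict, probs: np.ndarray, y: np.ndarray) -> None:
        b_sz = probs.shape[0]
        g_logits = probs.copy()
        g_logits[np.arange(b_sz), y] -= 1.0
        g_logits /= b_sz

        self.fc2_w.grad = g_logits.T @ cache["hr"]
        self.fc2_b.grad = g_logits.sum(axis=0)
        g_hr = g_logits @ self.fc2_w.value
        g_h = g_hr * (cache["h"] > 0)
        self.fc1_w.grad = g_h.T @ cache["flat"]
        self.fc1_b.grad = g_h.sum(axis=0)
        g_flat = g_h @ self.fc1_w.value

        b2, c, length = cache["act_shape"]
        l_pool = length // self.pool
        g_pooled = g_flat.reshape(b2, c, l_pool)
        g_act = np.zeros((b2, c, l_pool, self.pool))
        idx = cache["pool_argmax"]
        bi, ci, li = np.meshgrid(
            np.arange(b2), np.arange(c), np.arange(l_pool), indexing="ij"
        )
        g_act[bi, ci, li, idx] = g_pooled
        g_act_full = np.zeros(cache["act_shape"])
        g_act_full[:, :, : l_pool * self.pool] = g_act.reshape(b2, c, l_pool * self.pool)

        g_bn = g_act_full * (cache["bn"] > 0)
        xhat, ivar = cache["xhat"], cache["ivar"]
        self.gamma.grad = (g_bn * xhat).sum(axis=(0, 2))
        self.beta.grad = g_bn.sum(axis=(0, 2))
        g_xhat = g_bn * self.gamma.value[None, :, None]
        n_bn = b2 * length
        g_concat = (
            ivar[None, :, None]
            / n_bn
            * (
                n_bn * g_xhat
                - g_xhat.sum(axis=(0, 2), keepdims=True)
                - xhat * (g_xhat * xhat).sum(axis=(0, 2), keepdims=True)
            )
        )

        f = self.cfg.filters_per_branch
        for idx_b, (w1, b1, w2, b2p) in enumerate(self.branches):
            g_z2 = g_concat[:, idx_b * f : (idx_b + 1) * f, :]
            a1 = cache[f"a1_{idx_b}"]
            g_a1, w2.grad, b2p.grad = _conv_same_backward(a1, w2.value, g_z2)
            g_z1 = g_a1 * (cache[f"z1_{idx_b}"] > 0)
            _, w1.grad, b1.grad = _conv_same_backward(cache["x"], w1.value, g_z1)

    # -- optimisation ------------------------------------------------------
    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> None:
        self._step += 1
        t = self._step
        for p in self.parameters():
            p.m = beta1 * p.m + (1 - beta1) * p.grad
            p.v = beta2 * p.v + (1 - beta2) * p.grad**2
            m_hat = p.m / (1 - beta1**t)
            v_hat = p.v / (1 - beta2**t)
            p.value -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def train_step(self, xb: np.ndarray, yb: np.ndarray, lr: float) -> float:
        logits, cache = self._forward(xb, train=True)
        probs = self._softmax(logits)
        loss = float(-np.log(probs[np.arange(len(yb)), yb] + 1e-12).mean())
        self._backward(cache, probs, yb)
        self._adam_step(lr)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float,
        seed: int,
    ) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss history."""
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        history: list[float] = []
        for _ in range(epochs):
            perm = rng.permutation(n)
            losses = []
            start = 0
            while start < n:
                stop = min(start + batch_size, n)
                # avoid a trailing batch of one sample (degenerate batch norm)
                if n - stop == 1 and stop - start > 1:
                    stop = n
                batch = perm[start:stop]
                losses.append(self.train_step(x[batch], y[batch], lr))
                start = stop
            history.append(float(np.mean(losses)))
        return history
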