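"""Network building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Minimal parameter container with nesting."""

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix=""):
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield prefix + name, v
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, sd):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(sd)
        if missing:
            raise KeyError(f"state dict mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != sd[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data[...] = sd[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng, shape, scale):
    return Tensor(
        (rng.standard_normal(shape) * scale).astype(np.float32), requires_grad=True
    )


class Conv2d(Module):
    """3x3/1x1 'same' convolution, He-style init."""

    def __init__(self, in_ch, out_ch, ksize, rng):
        fan_in = in_ch * ksize * ksize
        self.weight = _param(rng, (out_ch, in_ch, ksize, ksize), np.sqrt(2.0 / fan_in))
        self.bias = Tensor(np.zeros((1, out_ch, 1, 1), np.float32), requires_grad=True)

    def forward(self, x):
        return ad.conv2d(x, self.weight) + self.bias


class Linear(Module):
    def __init__(self, in_f, out_f, rng, zero_init=False):
        scale = 0.0 if zero_init else np.sqrt(1.0 / in_f)
        self.weight = _param(rng, (in_f, out_f), scale)
        self.bias = Tensor(np.zeros((1, out_f), np.float32), requires_grad=True)

    def forward(self, x):
        return ad.matmul(x, self.weight) + self.bias


class GroupNorm(Module):
    def __init__(self, channels, groups=8, eps=1e-5):
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), np.float32), requires_grad=True)

    def forward(self, x):
        b, c, h, w = x.shape
        g = self.groups
        r = ad.reshape(x, (b, g, c // g, h, w))
        mu = ad.mean(r, axis=(2, 3, 4), keepdims=True)
        var = ad.mean(ad.power(r + (-1.0) * mu, 2.0), axis=(2, 3, 4), keepdims=True)
        r = (r + (-1.0) * mu) * ad.power(var + self.eps, -0.5)
        return ad.reshape(r, (b, c, h, w)) * self.gamma + self.beta


def instance_norm(x, eps=1e-5):
    """Per-sample, per-channel normalization to zero mean / unit variance."""
    mu = ad.mean(x, axis=(2, 3), keepdims=True)
    var = ad.mean(ad.power(x + (-1.0) * mu, 2.0), axis=(2, 3), keepdims=True)
    return (x + (-1.0) * mu) * ad.power(var + eps, -0.5)


class CIN(Module):
    """Conditional instance normalization: affine scale/shift from a latent.

    The latent vector drives a learned linear map producing per-channel
    (scale, shift); scale is parameterized as 1 + delta. Weights start small
    but nonzero so the stochastic path is live from initialization.
    """

    def __init__(self, channels, latent_dim, rng):
        self.channels = channels
        self.latent_dim = latent_dim
        self.to_scale = Linear(latent_dim, channels, rng)
        self.to_shift = Linear(latent_dim, channels, rng)
        self.to_scale.weight.data *= 0.2
        self.to_shift.weight.data *= 0.2

    def forward(self, x, z):
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"latent length {z.shape[1]} != expected {self.latent_dim}"
            )
        h = instance_norm(x)
        b = x.shape[0]
        scale = 1.0 + ad.reshape(self.to_scale(z), (b, self.channels, 1, 1))
        shift = ad.reshape(self.to_shift(z), (b, self.channels, 1, 1))
        return h * scale + shift


def time_embedding(t, dim):
    """Sinusoidal embedding of integer step indices; returns (B, dim) array."""
    t = np.asarray(t, np.float32).reshape(-1, 1)
    half = dim // 2
    freqs = np.exp(-np.log(10000.0) * np.arange(half, dtype=np.float32) / max(half - 1, 1))
    ang = t * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)


class Adam:
    def __init__(self, params, lr=2e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
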