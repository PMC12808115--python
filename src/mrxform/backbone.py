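"""Shared encoder-decoder ("U-Net") backbone.

One network family serves the deterministic baseline, the cGAN generator,
the NCSN score network, and the DDPM denoiser, so model comparisons are not
confounded by architecture. Optional conditioning paths: a sinusoidal time
embedding injected additively at every level (diffusion models), and a
latent vector injected through conditional instance normalization (cGAN).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import CIN, Conv2d, GroupNorm, Linear, Module, time_embedding


@dataclass
class BackboneConfig:
    in_channels: int = 1
    out_channels: int = 1
    base_width: int = 16
    depth: int = 2
    time_conditioning: bool = False
    latent_dim: int | None = None
    image_size: int = 32
    time_embed_dim: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.image_size % (2 ** self.depth):
            raise ValueError(
                f"image_size {self.image_size} not divisible by 2^depth={2 ** self.depth}"
            )


class _Block(Module):
    """conv -> norm -> SiLU (norm is GroupNorm, or CIN when a latent is used)."""

    def __init__(self, in_ch, out_ch, cfg: BackboneConfig, rng):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)
        self.use_cin = cfg.latent_dim is not None
        self.norm = (
            CIN(out_ch, cfg.latent_dim, rng) if self.use_cin else GroupNorm(out_ch)
        )
        self.time_proj = (
            Linear(cfg.time_embed_dim, out_ch, rng) if cfg.time_conditioning else None
        )

    def forward(self, x, temb=None, z=None):
        h = self.conv(x)
        if self.time_proj is not None and temb is not None:
            b = h.shape[0]
            h = h + ad.reshape(self.time_proj(temb), (b, h.shape[1], 1, 1))
        h = self.norm(h, z) if self.use_cin else self.norm(h)
        return ad.silu(h)


class UNet(Module):
    def __init__(self, cfg: BackboneConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.base_width
        widths = [w * (2 ** i) for i in range(cfg.depth + 1)]

        if cfg.time_conditioning:
            self.temb_mlp1 = Linear(cfg.time_embed_dim, cfg.time_embed_dim, rng)
            self.temb_mlp2 = Linear(cfg.time_embed_dim, cfg.time_embed_dim, rng)

        self.enc = []
        in_ch = cfg.in_channels
        for d in range(cfg.depth):
            self.enc.append(_Block(in_ch, widths[d], cfg, rng))
            in_ch = widths[d]
        self.mid = _Block(widths[cfg.depth - 1], widths[cfg.depth], cfg, rng)
        self.mid2 = _Block(widths[cfg.depth], widths[cfg.depth], cfg, rng)
        self.dec = []
        for d in reversed(range(cfg.depth)):
            # input: upsampled deeper features + skip
            self.dec.append(_Block(widths[d + 1] + widths[d], widths[d], cfg, rng))
        self.out_conv = Conv2d(widths[0], cfg.out_channels, 1, rng)
        # small output head keeps untrained outputs near zero without
        # killing gradient or conditioning paths
        self.out_conv.weight.data *= 0.05

    def forward(self, x, t=None, z=None):
        """x: (B, in_channels, H, W); t: (B,) int steps; z: (B, latent_dim)."""
        cfg = self.cfg
        if t is not None and not cfg.time_conditioning:
            raise ValueError("time index supplied but time_conditioning=False")
        if z is not None and cfg.latent_dim is None:
            raise ValueError("latent supplied but latent_dim is not set")
        if cfg.latent_dim is not None and z is None:
            raise ValueError("backbone built with latent_dim requires z")
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, np.float32))
        if z is not None and not isinstance(z, Tensor):
            z = Tensor(np.asarray(z, np.float32))

        temb = None
        if cfg.time_conditioning:
            if t is None:
                raise ValueError("time-conditioned backbone requires t")
            temb = Tensor(time_embedding(t, cfg.time_embed_dim))
            temb = ad.silu(self.temb_mlp1(temb))
            temb = self.temb_mlp2(temb)

        skips = []
        h = x
        for blk in self.enc:
            h = blk(h, temb, z)
            skips.append(h)
            h = ad.avg_pool2(h)
        h = self.mid(h, temb, z)
        h = self.mid2(h, temb, z)
        for blk, skip in zip(self.dec, reversed(skips)):
            h = ad.upsample2(h)
            h = ad.concat([h, skip], axis=1)
            h = blk(h, temb, z)
        return self.out_conv(h)


def build_backbone(cfg: BackboneConfig) -> UNet:
    return UNet(cfg)


def cin_inject(features, latent, cin: CIN):
    """Apply conditional instance normalization with a given CIN layer."""
    return cin(features, latent)


def save_checkpoint(path, net: UNet, extra: dict | None = None):
    meta = {"config": asdict(net.cfg), "extra": extra or {}}
    arrays = {k.replace(".", "__"): v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[UNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = BackboneConfig(**meta["config"])
        net = UNet(cfg)
        sd = {k.replace("__", "."): z[k] for k in z.files if k != "__meta__"}
        net.load_state_dict(sd)
    return net, meta["extra"]
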