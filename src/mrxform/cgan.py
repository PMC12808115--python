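"""Conditional Wasserstein GAN with gradient penalty.

Generator g(x, z) maps an input-contrast slice plus a Gaussian latent
vector (injected through conditional instance normalization) to a
target-contrast slice. Critic d(x, y) scores joint pairs; it is trained to
maximize E[d(x,y)] - E[d(x,y_g)] under a unit-gradient-norm penalty on
random interpolates, and the generator purely adversarially (no pixel
reconstruction term). Multiple latent draws per input give the sample
ensemble used for uncertainty maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, UNet, build_backbone
from .data_io import PairedSliceDataset, Volume
from .ensemble_uq import Ensemble, summarize
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Adam, Conv2d, Linear, Module


@dataclass
class CganConfig:
    latent_dim: int = 128
    gp_weight: float = 10.0
    critic_steps: int = 5
    lr: float = 2e-4
    betas: tuple = (0.0, 0.9)
    batch_size: int = 16
    gen_steps: int = 300
    base_width: int = 16
    depth: int = 2
    critic_width: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.gp_weight < 0:
            raise ValueError("gradient-penalty weight must be >= 0")
        if self.critic_steps < 1:
            raise ValueError("critic_steps must be >= 1")


class Critic(Module):
    """Conv critic on concatenated (x, y) pairs; no normalization layers."""

    def __init__(self, width, image_size, rng):
        self.c1 = Conv2d(2, width, 3, rng)
        self.c2 = Conv2d(width, 2 * width, 3, rng)
        self.c3 = Conv2d(2 * width, 2 * width, 3, rng)
        self.head = Linear(2 * width, 1, rng)

    def forward(self, x, y):
        h = ad.concat([x, y], axis=1)
        h = ad.silu(self.c1(h))
        h = ad.avg_pool2(h)
        h = ad.silu(self.c2(h))
        h = ad.avg_pool2(h)
        h = ad.silu(self.c3(h))
        h = ad.mean(h, axis=(2, 3))  # (B, C)
        return self.head(h)  # (B, 1)


@dataclass
class CganState:
    generator: UNet
    critic: Critic
    cfg: CganConfig
    gen_loss_history: list = field(default_factory=list)
    critic_loss_history: list = field(default_factory=list)
    wasserstein_history: list = field(default_factory=list)


def gradient_penalty(d, x, y_real, y_fake, rng: np.random.Generator):
    """E[(||d d(x, y_interp)/d y_interp|| - 1)^2] over per-sample interpolates."""
    b = y_real.shape[0]
    eps = rng.random((b, 1, 1, 1)).astype(np.float32)
    y_hat = Tensor(eps * y_real + (1.0 - eps) * y_fake, requires_grad=True)
    scores = d(Tensor(x), y_hat)
    g = ad.grad(ad.sum_(scores), y_hat, create_graph=True)
    norms = ad.power(ad.sum_(ad.power(g, 2.0), axis=(1, 2, 3)) + 1e-12, 0.5)
    return ad.mean(ad.power(norms - 1.0, 2.0))


def critic_loss(d, g, x, y, z, gp_weight, rng: np.random.Generator):
    """-(E[d(x,y)] - E[d(x,y_g)]) + lambda * gradient penalty.

    Gradient descent on this quantity performs the critic's max step.
    ``g`` may be a generator network or a precomputed fake batch.
    """
    if gp_weight < 0:
        raise ValueError("gradient-penalty weight must be >= 0")
    if callable(g):
        with ad.no_grad():
            y_fake = g(x, z=z).data
    else:
        y_fake = np.asarray(g, np.float32)
    xt = Tensor(x)
    real = ad.mean(d(xt, Tensor(y)))
    fake = ad.mean(d(xt, Tensor(y_fake)))
    loss = -1.0 * (real - fake)
    if gp_weight > 0:
        loss = loss + gp_weight * gradient_penalty(d, x, y, y_fake, rng)
    return loss


def generator_loss(d, g, x, z):
    """-E[d(x, g(x,z))]; the real-data term has zero generator gradient."""
    y_fake = g(x, z=z)
    return -1.0 * ad.mean(d(Tensor(x), y_fake))


def wasserstein_estimate(d, x, y_real, y_fake):
    with ad.no_grad():
        xt = Tensor(x)
        return float(ad.mean(d(xt, Tensor(y_real))).item() - ad.mean(d(xt, Tensor(y_fake))).item())


def train_cgan(data: PairedSliceDataset, cfg: CganConfig | None = None) -> CganState:
    if len(data) == 0:
        raise ValueError("empty training dataset")
    cfg = cfg or CganConfig()
    h, w = data.slice_shape
    rng = np.random.default_rng(cfg.seed)
    gen = build_backbone(
        BackboneConfig(
            in_channels=1,
            out_channels=1,
            base_width=cfg.base_width,
            depth=cfg.depth,
            latent_dim=cfg.latent_dim,
            image_size=h,
            seed=cfg.seed,
        )
    )
    critic = Critic(cfg.critic_width, h, np.random.default_rng(cfg.seed + 1))
    opt_g = Adam(gen.parameters(), lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(critic.parameters(), lr=cfg.lr, betas=cfg.betas)
    x_all, y_all = data.arrays()
    n = len(x_all)
    state = CganState(generator=gen, critic=critic, cfg=cfg)

    def draw(batch):
        take = rng.integers(0, n, size=batch)
        z = rng.standard_normal((batch, cfg.latent_dim)).astype(np.float32)
        return x_all[take], y_all[take], z

    for step in range(cfg.gen_steps):
        for _ in range(cfg.critic_steps):
            x, y, z = draw(cfg.batch_size)
            dl = critic_loss(critic, gen, x, y, z, cfg.gp_weight, rng)
            grads = ad.grad(dl, critic.parameters())
            opt_d.step(grads)
        if not np.isfinite(dl.item()):
            raise FloatingPointError(f"critic loss diverged (NaN/Inf) at generator step {step}")
        x, y, z = draw(cfg.batch_size)
        gl = generator_loss(critic, gen, x, z)
        grads = ad.grad(gl, gen.parameters())
        opt_g.step(grads)
        if not np.isfinite(gl.item()):
            raise FloatingPointError(f"generator loss diverged (NaN/Inf) at step {step}")
        state.gen_loss_history.append(gl.item())
        state.critic_loss_history.append(dl.item())
        with ad.no_grad():
            y_fake = gen(x, z=Tensor(z)).data
        state.wasserstein_history.append(wasserstein_estimate(critic, x, y, y_fake))
    return state


def sample_cgan(state: CganState, input_volume: Volume, n: int = 20, seed: int = 0,
                z_batch: np.ndarray | None = None) -> Ensemble:
    """n transformed volumes, one per independent latent draw."""
    if n < 1:
        raise ValueError("n must be >= 1")
    gen = state.generator
    rng = np.random.default_rng(seed)
    if z_batch is None:
        z_batch = rng.standard_normal((n, state.cfg.latent_dim)).astype(np.float32)
    x = input_volume.data[:, None].astype(np.float32)
    n_slices = x.shape[0]
    # one forward for all n latent draws: tile slices, repeat each z per slice
    x_rep = np.tile(x, (n, 1, 1, 1))
    z_rep = np.repeat(z_batch, n_slices, axis=0)
    with ad.no_grad():
        out = gen(x_rep, z=Tensor(z_rep)).data[:, 0]
    samples = np.clip(out.reshape(n, n_slices, x.shape[2], x.shape[3]), 0.0, 1.0)
    return summarize(samples, model_tag="cgan", input_ref=input_volume.subject_id)
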