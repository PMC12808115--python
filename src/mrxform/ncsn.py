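"""Conditional noise-conditional score network.

Variance-exploding forward process y_t = y_0 + sqrt(beta_t) eps; a
time-conditioned network learns the score of the noised conditional
distribution via denoising score matching, and sampling runs annealed
Langevin dynamics from t=T down to 1, starting at N(0, beta_T I).

The network predicts a unit-scale residual and the score is recovered as
net(y_t, x, t) / sqrt(beta_t); with the beta_t weighting in the loss this
makes every noise level contribute at the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, UNet, build_backbone
from .data_io import PairedSliceDataset, Volume
from .ensemble_uq import Ensemble, summarize
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Adam
from .schedules import LangevinConfig, NoiseSchedule, ncsn_geometric


def ncsn_noise(y0, t, schedule: NoiseSchedule, eps):
    """Forward noising: y_t = y_0 + sqrt(beta_t) * eps."""
    t = schedule.check_t(t)
    beta = schedule.beta[np.asarray(t) - 1]
    beta = np.reshape(beta, (-1,) + (1,) * (np.ndim(y0) - 1)) if np.ndim(t) else beta
    return np.asarray(y0) + np.sqrt(beta) * np.asarray(eps)


def ncsn_loss(score_fn, x, y0, schedule: NoiseSchedule, rng: np.random.Generator,
              t=None, eps=None):
    """Monte-Carlo denoising-score-matching loss.

    One uniformly sampled step per example; the per-example contribution is
    (beta_t / 2) * || s(y_t, x, t) + (y_t - y_0)/beta_t ||^2, an unbiased
    estimator of the beta-weighted sum over all T steps (up to the fixed
    1/T convention).
    """
    x = np.asarray(x, np.float32)
    y0 = np.asarray(y0, np.float32)
    b = y0.shape[0]
    if b == 0:
        raise ValueError("empty batch")
    if t is None:
        t = rng.integers(1, schedule.T + 1, size=b)
    if eps is None:
        eps = rng.standard_normal(y0.shape).astype(np.float32)
    beta = schedule.beta[np.asarray(t) - 1].astype(np.float32)
    bshape = (b,) + (1,) * (y0.ndim - 1)
    yt = y0 + np.sqrt(beta).reshape(bshape) * eps
    s = score_fn(yt, x, t)
    if not isinstance(s, Tensor):
        s = Tensor(np.asarray(s, np.float32))
    resid = s + Tensor((yt - y0) / beta.reshape(bshape))
    per = ad.sum_(ad.power(resid, 2.0), axis=tuple(range(1, y0.ndim)))
    return 0.5 * ad.mean(per * Tensor(beta))


@dataclass
class NcsnConfig:
    T: int = 100
    sigma2_min: float = 1e-4
    sigma2_max: float = 1.0
    lr: float = 2e-4
    batch_size: int = 16
    steps: int = 400
    base_width: int = 16
    depth: int = 2
    seed: int = 0


@dataclass
class NcsnState:
    net: UNet
    schedule: NoiseSchedule
    cfg: NcsnConfig
    loss_history: list = field(default_factory=list)

    def score(self, yt, x, t):
        """Score function: network output scaled by 1/sqrt(beta_t)."""
        beta = self.schedule.beta[np.asarray(t) - 1].astype(np.float32)
        inp = np.concatenate([np.asarray(yt, np.float32), np.asarray(x, np.float32)], axis=1)
        out = self.net(inp, t=t)
        scale = (1.0 / np.sqrt(beta)).reshape((-1, 1, 1, 1))
        return out * Tensor(scale)


def train_ncsn(data: PairedSliceDataset, cfg: NcsnConfig | None = None) -> NcsnState:
    if len(data) == 0:
        raise ValueError("empty training dataset")
    cfg = cfg or NcsnConfig()
    h, w = data.slice_shape
    schedule = ncsn_geometric(cfg.T, cfg.sigma2_min, cfg.sigma2_max)
    net = build_backbone(
        BackboneConfig(
            in_channels=2, out_channels=1, base_width=cfg.base_width, depth=cfg.depth,
            time_conditioning=True, image_size=h, seed=cfg.seed,
        )
    )
    state = NcsnState(net=net, schedule=schedule, cfg=cfg)
    opt = Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    x_all, y_all = data.arrays()
    n = len(x_all)
    for step in range(cfg.steps):
        take = rng.integers(0, n, size=min(cfg.batch_size, n))
        loss = ncsn_loss(state.score, x_all[take], y_all[take], schedule, rng)
        grads = ad.grad(loss, net.parameters())
        opt.step(grads)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"training diverged at step {step}")
        state.loss_history.append(loss.item())
    return state


def langevin_chain(score_fn, x, schedule: NoiseSchedule, lcfg: LangevinConfig,
                   rng: np.random.Generator, shape):
    """Annealed Langevin MC, one step per noise level from t=T down to 1."""
    gamma = lcfg.gamma(schedule)
    y = rng.standard_normal(shape).astype(np.float32) * np.sqrt(schedule.beta[-1])
    for t in range(schedule.T, 0, -1):
        g = gamma[t - 1]
        tvec = np.full(shape[0], t)
        s = score_fn(y, x, tvec)
        s = s.data if isinstance(s, Tensor) else np.asarray(s)
        y = y + g * s + np.sqrt(2.0 * g) * rng.standard_normal(shape).astype(np.float32)
    return y


def ncsn_sample(state_or_score, input_volume: Volume, lcfg: LangevinConfig | None = None,
                schedule: NoiseSchedule | None = None, n: int = 20, seed: int = 0) -> Ensemble:
    """n independent Langevin chains per slice, restacked into volumes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(state_or_score, NcsnState):
        score_fn = state_or_score.score
        schedule = schedule or state_or_score.schedule
    else:
        score_fn = state_or_score
        if schedule is None:
            raise ValueError("schedule required with a bare score function")
    lcfg = lcfg or LangevinConfig()
    rng = np.random.default_rng(seed)
    x = input_volume.data[:, None].astype(np.float32)
    n_slices, _, h, w = x.shape
    # batch all chains for all slices together
    x_rep = np.repeat(x, n, axis=0)  # (n_slices*n, 1, H, W)
    with ad.no_grad():
        y = langevin_chain(score_fn, x_rep, schedule, lcfg, rng, x_rep.shape)
    samples = y[:, 0].reshape(n_slices, n, h, w).transpose(1, 0, 2, 3)
    return summarize(samples, model_tag="ncsn", input_ref=input_volume.subject_id)
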