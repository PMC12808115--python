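"""Conditional denoising diffusion probabilistic model.

Variance-preserving forward process y_t = sqrt(alpha_bar_t) y_0 +
sqrt(1 - alpha_bar_t) eps with a linearly increasing beta schedule; the
network predicts the injected noise (epsilon-prediction loss). Reverse
noise scales beta_tilde(t) are learned as a log-space interpolation
between beta_t and the forward-posterior variance, trained by a small
variational term added to the epsilon loss (hybrid objective) with the
mean path stop-gradiented. Sampling is ancestral from N(0, I), with no
noise injected at the final step. The mean image of a sample ensemble
occasionally carries isolated outlier pixels; `repair_outliers` replaces
them with the pixel-wise median using a robust std-image threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, UNet, build_backbone
from .data_io import PairedSliceDataset, Volume
from .ensemble_uq import Ensemble, summarize
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Adam
from .schedules import NoiseSchedule, ddpm_linear


def ddpm_noise(y0, t, schedule: NoiseSchedule, eps):
    """Forward noising: y_t = sqrt(alpha_bar_t) y0 + sqrt(1-alpha_bar_t) eps."""
    t = schedule.check_t(t)
    ab = schedule.alpha_bar[np.asarray(t) - 1]
    shape = (-1,) + (1,) * (np.ndim(y0) - 1)
    if np.ndim(t):
        ab = ab.reshape(shape)
    return np.sqrt(ab) * np.asarray(y0) + np.sqrt(1.0 - ab) * np.asarray(eps)


def posterior_variance(schedule: NoiseSchedule) -> np.ndarray:
    """Forward-posterior variances beta_post_t = (1-abar_{t-1})/(1-abar_t) beta_t."""
    ab = schedule.alpha_bar
    ab_prev = np.concatenate([[1.0], ab[:-1]])
    return (1.0 - ab_prev) / (1.0 - ab) * schedule.beta


@dataclass
class DdpmConfig:
    """beta_min/beta_max default to the reference linear schedule
    (1e-4..0.02 at T=1000) rescaled by 1000/T so that alpha_bar_T stays
    near zero — otherwise ancestral sampling's N(0, I) start would not
    match the forward terminal distribution at small T."""

    T: int = 100
    beta_min: float | None = None
    beta_max: float | None = None
    hybrid_loss_weight: float = 0.001
    lr: float = 2e-4
    batch_size: int = 16
    steps: int = 400
    base_width: int = 16
    depth: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.hybrid_loss_weight < 0:
            raise ValueError("hybrid loss weight must be >= 0")


@dataclass
class DdpmState:
    net: UNet
    schedule: NoiseSchedule
    cfg: DdpmConfig
    # unconstrained interpolation parameter; sigmoid -> v in (0,1)
    logvar_interp: Tensor = None
    loss_history: list = field(default_factory=list)

    def eta(self, yt, x, t):
        inp = np.concatenate([np.asarray(yt, np.float32), np.asarray(x, np.float32)], axis=1)
        return self.net(inp, t=t)

    def beta_tilde(self) -> np.ndarray:
        """Learned reverse variances: log-space interpolation."""
        v = 1.0 / (1.0 + np.exp(-self.logvar_interp.data))
        bpost = np.maximum(posterior_variance(self.schedule), 1e-20)
        return np.exp(v * np.log(self.schedule.beta) + (1.0 - v) * np.log(bpost))


def ddpm_loss(eta_fn, x, y0, schedule: NoiseSchedule, rng: np.random.Generator,
              hybrid_loss_weight: float = 0.0, logvar_interp: Tensor | None = None,
              t=None, eps=None):
    """Hybrid objective: epsilon-prediction MSE plus weighted variational term.

    Returns (loss, eps_term, vlb_term); one sampled step per example. The
    per-example epsilon contribution is ||eta(y_t,x,t) - eps||^2 / 2. The
    variational term is the KL of the reverse Gaussian at the sampled step
    with the mean path stop-gradiented, training only the learned
    log-variance interpolation.
    """
    x = np.asarray(x, np.float32)
    y0 = np.asarray(y0, np.float32)
    b = y0.shape[0]
    if b == 0:
        raise ValueError("empty batch")
    if t is None:
        t = rng.integers(1, schedule.T + 1, size=b)
    t = np.asarray(t)
    if eps is None:
        eps = rng.standard_normal(y0.shape).astype(np.float32)
    yt = ddpm_noise(y0, t, schedule, eps).astype(np.float32)
    out = eta_fn(yt, x, t)
    if not isinstance(out, Tensor):
        out = Tensor(np.asarray(out, np.float32))
    resid = out + (-1.0) * Tensor(eps)
    eps_term = 0.5 * ad.mean(ad.sum_(ad.power(resid, 2.0), axis=tuple(range(1, y0.ndim))))

    vlb_term = Tensor(np.float64(0.0))
    if hybrid_loss_weight > 0 and logvar_interp is not None:
        alpha = schedule.alpha[t - 1]
        abar = schedule.alpha_bar[t - 1]
        beta = schedule.beta[t - 1]
        bpost = np.maximum(posterior_variance(schedule)[t - 1], 1e-20)
        abar_prev = np.where(t > 1, schedule.alpha_bar[np.maximum(t - 2, 0)], 1.0)
        shp = (b,) + (1,) * (y0.ndim - 1)
        # posterior mean of q(y_{t-1} | y_t, y_0)
        mu_q = (np.sqrt(abar_prev) * beta / (1 - abar)).reshape(shp) * y0 + (
            np.sqrt(alpha) * (1 - abar_prev) / (1 - abar)
        ).reshape(shp) * yt
        # model mean with stop-grad on the epsilon prediction
        eta_det = out.data
        mu_p = (1.0 / np.sqrt(alpha)).reshape(shp) * (
            yt - ((1 - alpha) / np.sqrt(1 - abar)).reshape(shp) * eta_det
        )
        dmu2 = ((mu_q - mu_p) ** 2).mean(axis=tuple(range(1, y0.ndim)))
        vsel = ad.sigmoid(ad.getitem(logvar_interp, t - 1))
        log_sigma_p2 = vsel * np.log(beta) + (1.0 - vsel) * np.log(bpost)
        sigma_p2 = ad.exp(log_sigma_p2)
        keep = (t > 1).astype(np.float64)  # step 1 adds no reverse noise
        kl = 0.5 * (log_sigma_p2 - np.log(bpost)) + (
            Tensor(bpost + dmu2) * ad.power(sigma_p2, -1.0) * 0.5
        ) + (-0.5)
        vlb_term = ad.mean(kl * Tensor(keep))
    loss = eps_term + hybrid_loss_weight * vlb_term
    return loss, eps_term, vlb_term


def train_ddpm(data: PairedSliceDataset, cfg: DdpmConfig | None = None) -> DdpmState:
    if len(data) == 0:
        raise ValueError("empty training dataset")
    cfg = cfg or DdpmConfig()
    h, w = data.slice_shape
    bmin = cfg.beta_min if cfg.beta_min is not None else min(0.1 / cfg.T, 0.5)
    bmax = cfg.beta_max if cfg.beta_max is not None else min(20.0 / cfg.T, 0.999)
    schedule = ddpm_linear(cfg.T, bmin, bmax)
    net = build_backbone(
        BackboneConfig(
            in_channels=2, out_channels=1, base_width=cfg.base_width, depth=cfg.depth,
            time_conditioning=True, image_size=h, seed=cfg.seed,
        )
    )
    logvar = Tensor(np.zeros(cfg.T, np.float64), requires_grad=True)
    state = DdpmState(net=net, schedule=schedule, cfg=cfg, logvar_interp=logvar)
    params = net.parameters() + [logvar]
    opt = Adam(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    x_all, y_all = data.arrays()
    n = len(x_all)
    for step in range(cfg.steps):
        take = rng.integers(0, n, size=min(cfg.batch_size, n))
        loss, _, _ = ddpm_loss(
            state.eta, x_all[take], y_all[take], schedule, rng,
            cfg.hybrid_loss_weight, logvar,
        )
        grads = ad.grad(loss, params)
        opt.step(grads)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"training diverged at step {step}")
        state.loss_history.append(loss.item())
    return state


def reverse_step_mean(y_t, eps_pred, t: int, schedule: NoiseSchedule, clip_x0=None):
    """Deterministic part of one reverse step:
    (y_t - (1-alpha_t)/sqrt(1-alpha_bar_t) * eps_pred) / sqrt(alpha_t).

    With ``clip_x0=(lo, hi)`` the implied clean image
    x0 = (y_t - sqrt(1-alpha_bar_t) eps_pred)/sqrt(alpha_bar_t) is clipped
    to the data range before forming the posterior mean — algebraically
    identical whenever x0 is already in range, and the standard numerical
    guard against reverse-chain blow-up when the denoiser errs at high t.
    """
    schedule.check_t(t)
    alpha = schedule.alpha[t - 1]
    abar = schedule.alpha_bar[t - 1]
    y_t = np.asarray(y_t)
    eps_pred = np.asarray(eps_pred)
    if clip_x0 is None:
        return (y_t - (1 - alpha) / np.sqrt(1 - abar) * eps_pred) / np.sqrt(alpha)
    x0 = (y_t - np.sqrt(1 - abar) * eps_pred) / np.sqrt(abar)
    x0 = np.clip(x0, clip_x0[0], clip_x0[1])
    abar_prev = schedule.alpha_bar[t - 2] if t > 1 else 1.0
    beta = schedule.beta[t - 1]
    c0 = np.sqrt(abar_prev) * beta / (1 - abar)
    c1 = np.sqrt(alpha) * (1 - abar_prev) / (1 - abar)
    return c0 * x0 + c1 * y_t


def ancestral_chain(eta_fn, x, schedule: NoiseSchedule, beta_tilde, rng, shape,
                    clip_x0=(0.0, 1.0)):
    """Reverse diffusion t=T..1; no noise injected at the final step."""
    y = rng.standard_normal(shape).astype(np.float32)
    for t in range(schedule.T, 0, -1):
        tvec = np.full(shape[0], t)
        e = eta_fn(y, x, tvec)
        e = e.data if isinstance(e, Tensor) else np.asarray(e)
        y = reverse_step_mean(y, e, t, schedule, clip_x0=clip_x0).astype(np.float32)
        if t > 1:
            y = y + np.sqrt(beta_tilde[t - 1]) * rng.standard_normal(shape).astype(np.float32)
    return y


def ddpm_sample(state_or_eta, input_volume: Volume, schedule: NoiseSchedule | None = None,
                n: int = 20, seed: int = 0, beta_tilde=None, repair: bool = False) -> Ensemble:
    """n ancestral-sampling volumes; optional std-outlier repair of the mean."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(state_or_eta, DdpmState):
        eta_fn = state_or_eta.eta
        schedule = schedule or state_or_eta.schedule
        if beta_tilde is None:
            beta_tilde = state_or_eta.beta_tilde()
    else:
        eta_fn = state_or_eta
        if schedule is None:
            raise ValueError("schedule required with a bare denoiser function")
        if beta_tilde is None:
            beta_tilde = posterior_variance(schedule)
    rng = np.random.default_rng(seed)
    x = input_volume.data[:, None].astype(np.float32)
    n_slices, _, h, w = x.shape
    x_rep = np.repeat(x, n, axis=0)
    with ad.no_grad():
        y = ancestral_chain(eta_fn, x_rep, schedule, beta_tilde, rng, x_rep.shape)
    samples = y[:, 0].reshape(n_slices, n, h, w).transpose(1, 0, 2, 3)
    ens = summarize(samples, model_tag="ddpm", input_ref=input_volume.subject_id)
    if repair:
        ens = repair_outliers(ens, input_volume.mask)
    return ens


def repair_outliers(ens: Ensemble, mask=None, mad_factor: float = 5.0) -> Ensemble:
    """Replace the mean with the pixel-wise median where the std image is an outlier.

    A pixel is flagged when std > median(std) + mad_factor * MAD(std),
    both computed within the mask (or everywhere if no mask). Idempotent:
    the flag set depends only on the (unchanged) std image.
    """
    if ens.n < 3:
        raise ValueError("outlier repair needs n >= 3 samples")
    region = np.ones_like(ens.std, bool) if mask is None else np.asarray(mask, bool)
    vals = ens.std[region]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thresh = med + mad_factor * mad
    flagged = (ens.std > thresh) & region
    mean = ens.mean.copy()
    mean[flagged] = ens.median[flagged]
    return dataclasses.replace(ens, mean=mean, repaired_pixels=flagged)
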