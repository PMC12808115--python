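"""Deterministic baseline: train an encoder-decoder with mean-squared error.

For one input the trained network generates a single transformed image; it
is the point of comparison for the probabilistic models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import BackboneConfig, UNet, build_backbone
from .data_io import PairedSliceDataset, Volume
from .nn import autodiff as ad
from .nn.layers import Adam


@dataclass
class TrainConfig:
    lr: float = 2e-4
    batch_size: int = 16
    steps: int = 300
    seed: int = 0
    loss: str = "mse"  # "mae" available but not the default


@dataclass
class TrainState:
    net: UNet
    cfg: TrainConfig
    loss_history: list = field(default_factory=list)


def direct_loss(net, x, y, kind="mse"):
    """(1/2N) sum |y - f(x)|^2 over the batch (N = number of images)."""
    pred = net(x)
    diff = pred - ad.Tensor(y)
    if kind == "mae":
        return ad.mean(ad.sum_(ad.power(ad.power(diff, 2.0) + 1e-12, 0.5), axis=(1, 2, 3)))
    return 0.5 * ad.mean(ad.sum_(ad.power(diff, 2.0), axis=(1, 2, 3)))


def train_direct(data: PairedSliceDataset, cfg: TrainConfig | None = None,
                 backbone_cfg: BackboneConfig | None = None) -> TrainState:
    if len(data) == 0:
        raise ValueError("empty training dataset")
    cfg = cfg or TrainConfig()
    h, w = data.slice_shape
    bcfg = backbone_cfg or BackboneConfig(in_channels=1, out_channels=1, image_size=h, seed=cfg.seed)
    net = build_backbone(bcfg)
    opt = Adam(net.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    x_all, y_all = data.arrays()
    state = TrainState(net=net, cfg=cfg)
    n = len(x_all)
    for step in range(cfg.steps):
        take = rng.integers(0, n, size=min(cfg.batch_size, n))
        loss = direct_loss(net, x_all[take], y_all[take], cfg.loss)
        grads = ad.grad(loss, net.parameters())
        opt.step(grads)
        if not np.isfinite(loss.item()):
            raise FloatingPointError(f"training diverged at step {step}")
        state.loss_history.append(loss.item())
    return state


def infer_direct(state: TrainState, input_volume: Volume) -> Volume:
    """Slice-wise application, restacked; output clipped to [0,1]."""
    net = state.net
    sz = net.cfg.image_size
    if input_volume.shape[1] != sz or input_volume.shape[2] != sz:
        raise ValueError(
            f"input slices {input_volume.shape[1:]} do not match training size {sz}"
        )
    x = input_volume.data[:, None].astype(np.float32)
    with ad.no_grad():
        pred = net(x).data[:, 0]
    pred = np.clip(pred, 0.0, 1.0).astype(np.float32)
    return Volume(
        data=pred,
        mask=input_volume.mask,
        contrast="predicted",
        subject_id=input_volume.subject_id,
        normalized=True,
    )
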