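"""Noise-variance schedules shared by the score-based samplers.

Two families: a geometric variance-exploding schedule for the score
network (noise added on top of the clean image, variance beta_t growing
with t), and a linear variance-preserving schedule for the denoising
diffusion model (image scaled by sqrt(alpha_bar) with complementary
noise). Step indices are 1-based, matching the forward-process notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NoiseSchedule", "LangevinConfig", "ncsn_geometric", "ddpm_linear"]


@dataclass
class NoiseSchedule:
    kind: str
    T: int
    beta: np.ndarray  # beta[t-1] = variance at step t
    alpha: np.ndarray | None = None
    alpha_bar: np.ndarray | None = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, np.float64)
        if len(self.beta) != self.T:
            raise ValueError("beta length must equal T")
        if np.any(np.diff(self.beta) <= 0):
            raise ValueError("beta must be strictly increasing in t")
        if self.kind == "ddpm_linear":
            if np.any((self.beta <= 0) | (self.beta >= 1)):
                raise ValueError("ddpm betas must lie in (0,1)")
            self.alpha = 1.0 - self.beta
            self.alpha_bar = np.cumprod(self.alpha)

    def check_t(self, t):
        t = np.asarray(t)
        if np.any((t < 1) | (t > self.T)):
            raise ValueError(f"step index out of range 1..{self.T}")
        return t


def ncsn_geometric(T: int = 100, sigma2_min: float = 1e-4, sigma2_max: float = 1.0) -> NoiseSchedule:
    """Geometric sequence of variances from sigma2_min up to sigma2_max."""
    beta = np.geomspace(sigma2_min, sigma2_max, T)
    return NoiseSchedule(kind="ncsn_geometric", T=T, beta=beta)


def ddpm_linear(T: int = 100, beta_min: float = 1e-4, beta_max: float = 0.02) -> NoiseSchedule:
    beta = np.linspace(beta_min, beta_max, T)
    return NoiseSchedule(kind="ddpm_linear", T=T, beta=beta)


@dataclass
class LangevinConfig:
    """Annealed Langevin sampler settings; step size gamma_t = lambda_gamma * beta_t / beta_1.

    With the analytic score of a Gaussian at level t scaling as 1/beta_t,
    the per-step contraction is lambda_gamma / beta_1, so stability requires
    lambda_gamma < 2 beta_1; the default keeps it well inside that bound.
    """

    lambda_gamma: float | None = None
    seed: int = 0

    def gamma(self, schedule: NoiseSchedule) -> np.ndarray:
        lam = self.lambda_gamma
        if lam is None:
            lam = 0.3 * schedule.beta[0]
        if lam <= 0:
            raise ValueError("lambda_gamma must be > 0")
        return lam * schedule.beta / schedule.beta[0]
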