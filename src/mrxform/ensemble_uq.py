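"""Ensemble summaries and uncertainty quantification.

An ensemble is the set of n transformed volumes a generative model
produces for one input. The pixel-wise mean is the point prediction, the
pixel-wise standard deviation (population convention, divide by n) the
uncertainty map. sigma_hat — the std image averaged over brain voxels —
is the scalar uncertainty score used for OOD detection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Ensemble",
    "UncertaintyScore",
    "CoverageCurve",
    "summarize",
    "sigma_hat",
    "coverage_curve",
    "pixel_distribution_report",
]


@dataclass
class Ensemble:
    samples: np.ndarray  # (n, slices, H, W)
    mean: np.ndarray
    std: np.ndarray
    median: np.ndarray
    n: int
    model_tag: str = ""
    input_ref: str = ""
    repaired_pixels: np.ndarray | None = None


@dataclass
class UncertaintyScore:
    subject_id: str
    sigma_hat: float
    label: str = "ID"  # "ID" or the corruption kind
    model_tag: str = ""


@dataclass
class CoverageCurve:
    confidence_levels: np.ndarray
    empirical_coverage: np.ndarray


def summarize(samples, model_tag="", input_ref="") -> Ensemble:
    """Pixel-wise mean, population (1/n) standard deviation, and median."""
    samples = np.asarray(samples, np.float64)
    if samples.ndim != 4:
        raise ValueError("samples must be (n, slices, H, W)")
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    mean = samples.mean(axis=0)
    std = samples.std(axis=0, ddof=0)
    median = np.median(samples, axis=0)
    return Ensemble(
        samples=samples,
        mean=mean,
        std=std,
        median=median,
        n=samples.shape[0],
        model_tag=model_tag,
        input_ref=input_ref,
    )


def sigma_hat(ens: Ensemble, mask, label="ID") -> UncertaintyScore:
    """Mean of the std image over mask voxels, as a scalar subject score."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    return UncertaintyScore(
        subject_id=ens.input_ref,
        sigma_hat=float(ens.std[mask].mean()),
        label=label,
        model_tag=ens.model_tag,
    )


def coverage_curve(ensembles_and_targets, levels=None, masks=None) -> CoverageCurve:
    """Empirical coverage of central predictive intervals vs nominal level.

    For each pixel, the interval at confidence c is the central empirical
    [(1-c)/2, (1+c)/2] quantile range of the sample values (linear
    interpolation); coverage is the fraction of masked pixels whose target
    value falls inside, averaged over subjects.
    """
    if levels is None:
        levels = np.linspace(0.05, 0.95, 19)
    levels = np.asarray(levels, float)
    if np.any((levels <= 0) | (levels >= 1)):
        raise ValueError("confidence levels must lie in (0,1)")
    per_subject = []
    for i, (ens, target) in enumerate(ensembles_and_targets):
        if ens.n < 2:
            raise ValueError("coverage needs ensembles with n >= 2")
        tgt = np.asarray(target, np.float64)
        mask = None if masks is None else np.asarray(masks[i], bool)
        flat_samples = ens.samples.reshape(ens.n, -1)
        flat_tgt = tgt.reshape(-1)
        if mask is not None:
            sel = mask.reshape(-1)
            flat_samples = flat_samples[:, sel]
            flat_tgt = flat_tgt[sel]
        lo_q = (1.0 - levels) / 2.0
        hi_q = (1.0 + levels) / 2.0
        lo = np.quantile(flat_samples, lo_q, axis=0)
        hi = np.quantile(flat_samples, hi_q, axis=0)
        inside = (flat_tgt[None, :] >= lo) & (flat_tgt[None, :] <= hi)
        per_subject.append(inside.mean(axis=1))
    cov = np.mean(per_subject, axis=0)
    return CoverageCurve(confidence_levels=levels, empirical_coverage=cov)


def pixel_distribution_report(
    ens: Ensemble, alpha: float = 0.05, mask=None, max_pixels: int = 2000, seed: int = 0
) -> dict:
    """Per-pixel normality test and cumulants over the sample axis.

    Shapiro-Wilk is run on a random subsample of masked pixels for
    tractability; kappa_1..kappa_4 are the mean, variance, third central
    moment, and excess fourth moment (E[(X-mu)^4] - 3 sigma^4).
    """
    if ens.n < 8:
        raise ValueError("normality test needs n >= 8 samples")
    flat = ens.samples.reshape(ens.n, -1)
    if mask is not None:
        flat = flat[:, np.asarray(mask, bool).reshape(-1)]
    npix = flat.shape[1]
    rng = np.random.default_rng(seed)
    sel = rng.choice(npix, size=min(max_pixels, npix), replace=False)
    sub = flat[:, sel]

    pvals = np.empty(sub.shape[1])
    for j in range(sub.shape[1]):
        col = sub[:, j]
        if np.ptp(col) == 0:
            pvals[j] = 1.0  # constant: no evidence against normality
        else:
            pvals[j] = stats.shapiro(col).pvalue
    mu = sub.mean(axis=0)
    centered = sub - mu
    k2 = (centered ** 2).mean(axis=0)
    k3 = (centered ** 3).mean(axis=0)
    k4 = (centered ** 4).mean(axis=0) - 3.0 * k2 ** 2
    return {
        "pvalues": pvals,
        "reject_fraction": float((pvals < alpha).mean()),
        "normal_fraction": float((pvals >= alpha).mean()),
        "kappa1": mu,
        "kappa2": k2,
        "kappa3": k3,
        "kappa4": k4,
        "alpha": alpha,
    }
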