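"""Image-similarity metrics on normalized volumes, plus model comparison.

SSIM is computed over the full 3D volume (uniform window, K1=0.01,
K2=0.03, data range 1) so slice-to-slice inconsistencies are penalized;
BSSIM applies SSIM to Sobel edge-magnitude maps; SCSSIM compares the
consecutive-slice SSIM profiles of two volumes; the perceptual distance
follows the LPIPS layer-sum form with a pluggable feature extractor.
SSIM-family scores are reported as percentages. Model comparison uses
pairwise one-sided Wilcoxon signed-rank tests over per-subject values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ssim3d",
    "ssim2d",
    "psnr",
    "bssim",
    "scssim",
    "lpips_distance",
    "FeatureExtractor",
    "IdentityExtractor",
    "RandomConvExtractor",
    "compare_models",
    "wilcoxon_one_sided",
]

SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_WIN = 7
PSNR_INF = float("inf")


def _as_vol(a):
    a = np.asarray(a.data if hasattr(a, "data") and not isinstance(a, np.ndarray) else a, np.float64)
    return a


def _ssim_mean(x, y, win):
    """Mean local SSIM with a uniform window, unbiased covariance normalization."""
    ndim = x.ndim
    np_win = win ** ndim
    cov_norm = np_win / (np_win - 1.0)
    uf = lambda arr: ndimage.uniform_filter(arr, size=win)
    ux, uy = uf(x), uf(y)
    uxx, uyy, uxy = uf(x * x), uf(y * y), uf(x * y)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    c1 = (SSIM_K1 * 1.0) ** 2
    c2 = (SSIM_K2 * 1.0) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (win - 1) // 2
    sl = tuple(slice(pad, d - pad) for d in s.shape)
    return float(s[sl].mean())


def _window_for(shape, win=SSIM_WIN):
    m = min(shape)
    if m < win:
        win = m if m % 2 == 1 else m - 1
    if win < 3:
        raise ValueError("volume too small for SSIM window")
    return win


def ssim3d(a, b, win=None) -> float:
    """3D structural similarity of two normalized volumes, as a percentage."""
    x, y = _as_vol(a), _as_vol(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    w = win or _window_for(x.shape)
    return 100.0 * _ssim_mean(x, y, w)


def ssim2d(a, b, win=None) -> float:
    """2D structural similarity of two slices, in [0, 1] (not percent)."""
    x, y = np.asarray(a, np.float64), np.asarray(b, np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    w = win or _window_for(x.shape)
    return _ssim_mean(x, y, w)


def masked_ssim3d(a, b, mask, win=None) -> float:
    """SSIM restricted to a region: both volumes zeroed outside the mask."""
    x, y = _as_vol(a).copy(), _as_vol(b).copy()
    mask = np.asarray(mask, bool)
    x[~mask] = 0.0
    y[~mask] = 0.0
    return ssim3d(x, y, win=win)


def psnr(a, b, peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE) in dB; identical inputs give an inf sentinel."""
    x, y = _as_vol(a), _as_vol(b)
    mse = float(((x - y) ** 2).mean())
    if mse == 0.0:
        return PSNR_INF
    return 10.0 * np.log10(peak * peak / mse)


def _sobel_magnitude(vol):
    """Slice-wise 2D Sobel gradient magnitude of a (slice, row, col) volume."""
    out = np.empty_like(vol)
    for k in range(vol.shape[0]):
        gx = ndimage.sobel(vol[k], axis=0)
        gy = ndimage.sobel(vol[k], axis=1)
        out[k] = np.hypot(gx, gy)
    return out


def bssim(a, b, win=None) -> float:
    """SSIM between Sobel edge maps, jointly renormalized, as a percentage."""
    x, y = _as_vol(a), _as_vol(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    ex, ey = _sobel_magnitude(x), _sobel_magnitude(y)
    lo = min(ex.min(), ey.min())
    hi = max(ex.max(), ey.max())
    if hi > lo:
        ex = (ex - lo) / (hi - lo)
        ey = (ey - lo) / (hi - lo)
    return ssim3d(ex, ey, win=win)


def scssim(a, b, win=None) -> float:
    """Slice-consistency SSIM: 100 * (1 - mean |delta profile|).

    The profile of a volume is the sequence of 2D SSIM values between
    consecutive axial slices; the metric compares the two profiles.
    """
    x, y = _as_vol(a), _as_vol(b)
    if x.shape[0] != y.shape[0]:
        raise ValueError("volumes must have equal slice counts")
    n = x.shape[0]
    if n < 2:
        raise ValueError("SCSSIM needs at least 2 slices")
    w = win or _window_for(x.shape[1:])
    diffs = [
        abs(ssim2d(x[i], x[i + 1], win=w) - ssim2d(y[i], y[i + 1], win=w))
        for i in range(n - 1)
    ]
    return 100.0 * (1.0 - float(np.mean(diffs)))


# --------------------------------------------------------------------------
# perceptual distance
# --------------------------------------------------------------------------

class FeatureExtractor:
    """Layered feature maps phi_l with per-layer channel weights w_l."""

    def features(self, img2d) -> list:
        raise NotImplementedError

    def weights(self) -> list:
        raise NotImplementedError


class IdentityExtractor(FeatureExtractor):
    """Single layer, identity features, unit weight: the distance reduces to
    the mean squared pixel difference."""

    def features(self, img2d):
        return [np.asarray(img2d, np.float64)[None, :, :]]

    def weights(self):
        return [np.ones(1)]


class RandomConvExtractor(FeatureExtractor):
    """Fixed-seed random convolutional pyramid with channel-unit-normalized
    features; requires no pretrained weights. Pretrained extractors can be
    plugged in through the same interface."""

    def __init__(self, seed: int = 0, widths=(8, 16, 16)):
        rng = np.random.default_rng(seed)
        self.kernels = []
        in_ch = 1
        for wdt in widths:
            k = rng.standard_normal((wdt, in_ch, 3, 3)) / np.sqrt(in_ch * 9)
            self.kernels.append(k)
            in_ch = wdt
        self._w = [np.ones(wdt) / wdt for wdt in widths]

    def features(self, img2d):
        h = np.asarray(img2d, np.float64)[None, :, :]
        feats = []
        for li, k in enumerate(self.kernels):
            out = np.stack([
                sum(ndimage.correlate(h[c], k[o, c], mode="constant") for c in range(h.shape[0]))
                for o in range(k.shape[0])
            ])
            h = np.maximum(out, 0.0)
            norm = np.sqrt((h ** 2).sum(axis=0, keepdims=True)) + 1e-10
            feats.append(h / norm)
            if li < len(self.kernels) - 1:
                hh, ww = h.shape[1] // 2 * 2, h.shape[2] // 2 * 2
                h = h[:, :hh, :ww].reshape(h.shape[0], hh // 2, 2, ww // 2, 2).mean(axis=(2, 4))
        return feats

    def weights(self):
        return self._w


def lpips_slice(a2d, b2d, fx: FeatureExtractor) -> float:
    """Layer sum of spatially averaged weighted squared feature differences."""
    fa, fb = fx.features(a2d), fx.features(b2d)
    ws = fx.weights()
    total = 0.0
    for pa, pb, w in zip(fa, fb, ws):
        if pa.shape != pb.shape:
            raise ValueError("feature map shape mismatch between inputs")
        d = w[:, None, None] * (pa - pb)
        hl, wl = pa.shape[1], pa.shape[2]
        total += float((d ** 2).sum(axis=0).sum() / (hl * wl))
    return total


def lpips_distance(a, b, fx: FeatureExtractor | None = None) -> float:
    """Perceptual distance per slice, averaged over the volume; 0 = match."""
    x, y = _as_vol(a), _as_vol(b)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    fx = fx or RandomConvExtractor()
    return float(np.mean([lpips_slice(x[k], y[k], fx) for k in range(x.shape[0])]))


# --------------------------------------------------------------------------
# statistical model comparison
# --------------------------------------------------------------------------

def wilcoxon_one_sided(a, b) -> float:
    """p-value for the one-sided hypothesis that paired a > b.

    Zero differences are dropped (standard signed-rank practice); if every
    difference is zero there is no evidence either way and p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("unpaired values: arrays must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(a, b, alternative="greater", zero_method="wilcox").pvalue)


def compare_models(report, metric: str, models=None, alpha: float = 0.05,
                   higher_is_better: bool | None = None):
    """Pairwise one-sided signed-rank tests and the resulting best set.

    ``report`` is a DataFrame with columns (subject_id, model, <metric>).
    A model belongs to the best set iff no other model is significantly
    better than it at level alpha. Returns (pairwise p-value dict, best set).
    """
    if higher_is_better is None:
        higher_is_better = metric != "lpips"
    models = models or sorted(report["model"].unique())
    pivot = report.pivot_table(index="subject_id", columns="model", values=metric)
    pivot = pivot.dropna()
    pvals = {}
    for m1 in models:
        for m2 in models:
            if m1 == m2:
                continue
            a, b = pivot[m1].to_numpy(), pivot[m2].to_numpy()
            if not higher_is_better:
                a, b = -a, -b
            pvals[(m1, m2)] = wilcoxon_one_sided(a, b)  # H1: m1 better than m2
    best = set(models)
    for m in models:
        if any(pvals[(other, m)] < alpha for other in models if other != m):
            best.discard(m)
    return pvals, best
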