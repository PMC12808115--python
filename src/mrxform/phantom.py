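"""Synthetic paired multi-contrast brain phantoms and OOD-corrupted variants.

Each subject is a stack of axial slices built from nested ellipses: an
outer gray-matter shell, a white-matter interior, two CSF "ventricles" and
a few deep-gray ("subcortical") blobs — geometry chosen so that the
ventricle/subcortical boundaries that matter for boundary-similarity
metrics exist in every phantom. The same tissue label map is rendered under
several contrast profiles (per-class mean intensities), so the map from
one contrast to another is an exact per-class function of the shared
anatomy, up to per-subject intensity jitter, a smooth multiplicative bias
field, and additive Gaussian noise. Noise is Gaussian rather than Rician:
a deliberate simplification that keeps the variance checks analytic.

Corruptions emulate out-of-distribution inputs: RF-zipper stripes (dashed
bright lines), reconstruction ghosting (attenuated shifted copy), low SNR,
a hyperintense tumor blob (visible only in the target contrast), and small
white-matter lesions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .data_io import Volume, minmax_normalize

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "PhantomSubject",
    "CORRUPTION_KINDS",
    "DEFAULT_SEVERITY",
    "generate_subject",
    "corrupt",
    "generate_cohort",
]

TISSUE_CLASSES = ("background", "csf", "gray", "white", "subcortical")
TUMOR_LABEL = 5
LESION_LABEL = 6

CORRUPTION_KINDS = ("zipper", "ghosting", "low_snr", "tumor", "lesion")

# severities used for cohort generation; the source artifacts are described
# qualitatively ("strong" zipper, "low SNR"), so these are fixed here once
DEFAULT_SEVERITY = {
    "zipper": 1.0,
    "ghosting": 1.0,
    "low_snr": 4.0,
    "tumor": 1.0,
    "lesion": 1.0,
}

DEFAULT_PROFILES = {
    "t1": {"background": 0.0, "csf": 0.15, "gray": 0.55, "white": 0.85, "subcortical": 0.70},
    "t2": {"background": 0.0, "csf": 0.95, "gray": 0.55, "white": 0.30, "subcortical": 0.45},
}


@dataclass
class PhantomSpec:
    image_size: int = 32
    n_slices: int = 8
    tissue_classes: tuple = TISSUE_CLASSES
    contrast_profiles: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROFILES.items()})
    intensity_jitter_sd: float = 0.02
    bias_field_amplitude: float = 0.1
    noise_sd: float = 0.015
    geometry_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 16 or self.n_slices < 1:
            raise ValueError("invalid phantom spec: image_size >= 16 and n_slices >= 1 required")
        for name, prof in self.contrast_profiles.items():
            if prof.get("background", 0.0) != 0.0:
                raise ValueError(f"contrast '{name}' must assign background mean 0")
            for cls, m in prof.items():
                if not (0.0 <= m <= 1.0):
                    raise ValueError(f"class mean out of [0,1]: {name}/{cls}={m}")
        for v, nm in [
            (self.intensity_jitter_sd, "intensity_jitter_sd"),
            (self.bias_field_amplitude, "bias_field_amplitude"),
            (self.noise_sd, "noise_sd"),
            (self.geometry_jitter, "geometry_jitter"),
        ]:
            if v < 0:
                raise ValueError(f"{nm} must be >= 0")


@dataclass
class CorruptionSpec:
    kind: str = "none"
    severity: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("none",) + CORRUPTION_KINDS:
            raise ValueError(f"unknown corruption kind '{self.kind}'")
        if self.severity < 0:
            raise ValueError("severity must be >= 0")


@dataclass
class PhantomSubject:
    subject_id: str
    tissue_map: np.ndarray
    volumes: dict  # contrast name -> Volume
    mask: np.ndarray
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    spec: PhantomSpec | None = None


def _ellipse(rr, cc, center, radii):
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _make_tissue_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n, sz = spec.n_slices, spec.image_size
    gj = spec.geometry_jitter
    c0 = sz / 2.0

    def jit(x):
        return x * (1.0 + gj * rng.standard_normal())

    brain_r = (jit(0.42 * sz), jit(0.38 * sz))
    inner_scale = jit(0.72)
    vent_dx = jit(0.10 * sz)
    vent_r = (jit(0.16 * sz), jit(0.05 * sz))
    n_blobs = int(rng.integers(2, 5))
    blob_centers = [
        (
            c0 + jit(0.16 * sz) * np.sign(rng.standard_normal()),
            c0 + (0.18 + 0.08 * rng.random()) * sz * (1 if b % 2 else -1),
        )
        for b in range(n_blobs)
    ]
    blob_r = [max(1.5, jit(0.06 * sz)) for _ in range(n_blobs)]
    z0 = (n - 1) / 2.0
    rz = jit(0.62 * n)

    rr, cc = np.mgrid[0:sz, 0:sz].astype(float)
    tmap = np.zeros((n, sz, sz), np.int16)
    for k in range(n):
        s = 1.0 - ((k - z0) / rz) ** 2
        if s <= 0.05:
            s = 0.05
        s = np.sqrt(s)
        brain = _ellipse(rr, cc, (c0, c0), (brain_r[0] * s, brain_r[1] * s))
        white = _ellipse(rr, cc, (c0, c0), (brain_r[0] * s * inner_scale, brain_r[1] * s * inner_scale))
        sl = np.zeros((sz, sz), np.int16)
        sl[brain] = 2  # gray shell
        sl[white] = 3
        # ventricles only where the slice is near the middle of the stack
        if s > 0.5:
            for sgn in (-1, 1):
                vent = _ellipse(rr, cc, (c0, c0 + sgn * vent_dx), (vent_r[0] * s, max(vent_r[1] * s, 1.2)))
                sl[vent & white] = 1
            for (bc, br) in zip(blob_centers, blob_r):
                blob = _ellipse(rr, cc, bc, (br * s, br * s))
                sl[blob & (sl == 3)] = 4
        tmap[k] = sl
    return tmap


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """exp of a random low-order 2D polynomial; multiplicative and positive."""
    sz = spec.image_size
    a = spec.bias_field_amplitude
    if a == 0:
        return np.ones((sz, sz), np.float32)
    u = np.linspace(-1, 1, sz)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    terms = [uu, vv, uu * vv, uu ** 2, vv ** 2]
    coef = rng.uniform(-1, 1, size=len(terms))
    poly = sum(c * t for c, t in zip(coef, terms))
    poly *= a / max(np.abs(poly).max(), 1e-9)
    return np.exp(poly).astype(np.float32)


def generate_subject(spec: PhantomSpec, subject_seed: int) -> PhantomSubject:
    """Render one multi-contrast subject from a shared tissue label map."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(int(subject_seed),)))
    tmap = _make_tissue_map(spec, rng)
    mask = tmap != 0
    bias = _bias_field(spec, rng)
    # per-subject per-class jitter, shared across contrasts so one contrast
    # stays an exact per-class function of another
    jitter = rng.standard_normal(len(spec.tissue_classes)) * spec.intensity_jitter_sd
    jitter[0] = 0.0

    volumes = {}
    for cname, prof in spec.contrast_profiles.items():
        lut = np.zeros(max(TUMOR_LABEL, LESION_LABEL) + 1, np.float32)
        for i, cls in enumerate(spec.tissue_classes):
            lut[i] = np.clip(prof[cls] + jitter[i], 0.0, 1.0)
        img = lut[tmap]
        img = img * bias[None, :, :]
        img[~mask] = 0.0
        if spec.noise_sd > 0:
            img = img + rng.standard_normal(img.shape).astype(np.float32) * spec.noise_sd
        img = np.clip(img, 0.0, 1.0)
        v = Volume(data=img, mask=mask, contrast=cname, subject_id=f"s{subject_seed:04d}")
        volumes[cname] = minmax_normalize(v)
    return PhantomSubject(
        subject_id=f"s{subject_seed:04d}",
        tissue_map=tmap,
        volumes=volumes,
        mask=mask,
        corruption=CorruptionSpec(kind="none"),
        spec=spec,
    )


def _renormalize(subject: PhantomSubject):
    for c, v in subject.volumes.items():
        v.data = np.clip(v.data, 0.0, 1.0)
        subject.volumes[c] = minmax_normalize(v)


def corrupt(subject: PhantomSubject, c: CorruptionSpec) -> PhantomSubject:
    """Apply one corruption operator; identity when kind='none'."""
    if subject.corruption.kind != "none":
        raise ValueError("subject already corrupted")
    if c.kind == "none":
        return subject
    rng = np.random.default_rng(c.seed)
    out = PhantomSubject(
        subject_id=subject.subject_id,
        tissue_map=subject.tissue_map.copy(),
        volumes={k: dataclasses.replace(v, data=v.data.copy()) for k, v in subject.volumes.items()},
        mask=subject.mask.copy(),
        corruption=c,
        spec=subject.spec,
    )
    contrasts = list(out.volumes)
    input_contrast, target_contrast = contrasts[0], contrasts[-1]
    n, sz = out.tissue_map.shape[0], out.tissue_map.shape[1]

    if c.kind == "zipper":
        amp = 0.6 * c.severity
        stripe = np.zeros((sz, sz), np.float32)
        phase = int(rng.integers(0, 8))
        for r in range((phase % 8), sz, 8):
            dash = (np.arange(sz) // 4 + int(rng.integers(0, 2))) % 2 == 0
            stripe[r, dash] = amp
        for v in out.volumes.values():
            v.data = v.data + stripe[None, :, :]
    elif c.kind == "ghosting":
        shift = max(2, sz // 4)
        w = 0.35 * c.severity
        for v in out.volumes.values():
            v.data = v.data + w * np.roll(v.data, shift, axis=1)
    elif c.kind == "low_snr":
        base = subject.spec.noise_sd if subject.spec is not None else 0.02
        base = max(base, 0.01)
        extra = base * c.severity
        for v in out.volumes.values():
            v.data = v.data + rng.standard_normal(v.data.shape).astype(np.float32) * extra
    elif c.kind == "tumor":
        _insert_tumor(out, rng, c.severity, input_contrast, target_contrast)
    elif c.kind == "lesion":
        _insert_lesions(out, rng, c.severity, input_contrast, target_contrast)
    else:  # pragma: no cover - CorruptionSpec already validates
        raise ValueError(f"unknown corruption kind '{c.kind}'")
    _renormalize(out)
    return out


def tumor_min_area(image_size: int) -> int:
    """Minimum in-plane area (pixels) of an inserted tumor's largest slice."""
    r = max(2.5, 0.09 * image_size)
    return int(np.floor(0.8 * np.pi * r * r))


def _insert_tumor(sub: PhantomSubject, rng, severity, input_contrast, target_contrast):
    n, sz = sub.tissue_map.shape[0], sub.tissue_map.shape[1]
    r = max(2.5, 0.09 * sz) * max(severity, 0.5)
    # place inside white matter of the central slice
    k0 = n // 2
    white = np.argwhere(sub.tissue_map[k0] == 3)
    if len(white) == 0:
        white = np.argwhere(sub.mask[k0])
    center = white[rng.integers(len(white))]
    rr, cc = np.mgrid[0:sz, 0:sz].astype(float)
    for k in range(max(0, k0 - 1), min(n, k0 + 2)):
        s = 1.0 if k == k0 else 0.7
        blob = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= (r * s) ** 2
        blob &= sub.mask[k]
        sub.tissue_map[k][blob] = TUMOR_LABEL
        # hyperintense in the target contrast, isointense (untouched) in the input
        tv = sub.volumes[target_contrast]
        tv.data[k][blob] = 0.98


def _insert_lesions(sub: PhantomSubject, rng, severity, input_contrast, target_contrast):
    n_foci = int(2 + min(3, round(severity)))
    n, sz = sub.tissue_map.shape[0], sub.tissue_map.shape[1]
    rr, cc = np.mgrid[0:sz, 0:sz].astype(float)
    placed = 0
    for _ in range(50):
        if placed >= n_foci:
            break
        k = int(rng.integers(0, n))
        white = np.argwhere(sub.tissue_map[k] == 3)
        if len(white) == 0:
            continue
        center = white[rng.integers(len(white))]
        rad = 1.0 + rng.random()
        blob = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= rad ** 2
        blob &= sub.tissue_map[k] == 3
        if not blob.any():
            continue
        sub.tissue_map[k][blob] = LESION_LABEL
        sub.volumes[target_contrast].data[k][blob] += 0.35
        sub.volumes[input_contrast].data[k][blob] += 0.10
        placed += 1


def generate_cohort(spec: PhantomSpec, n_id: int, n_ood_per_kind: int) -> list:
    """n_id clean subjects plus n_ood_per_kind per corruption kind.

    Subject seeds are disjoint across the cohort; corruption labels are kept
    on each subject for downstream OOD evaluation.
    """
    if n_id < 0 or n_ood_per_kind < 0:
        raise ValueError("counts must be >= 0")
    cohort = [generate_subject(spec, i) for i in range(n_id)]
    seed = n_id
    for kind in CORRUPTION_KINDS:
        for _ in range(n_ood_per_kind):
            base = generate_subject(spec, seed)
            cspec = CorruptionSpec(kind=kind, severity=DEFAULT_SEVERITY[kind], seed=seed)
            cohort.append(corrupt(base, cspec))
            seed += 1
    return cohort
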