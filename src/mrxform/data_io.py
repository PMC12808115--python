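"""Volume containers, normalization, NIfTI I/O, slice pairing and splits.

Conventions shared across the package: volumes are (slice, row, col)
float32 arrays, axial slicing along axis 0, 0-based slice indexing.
Intensities are min-max normalized per volume to [0, 1] before any model
sees them; masks are binary with the same shape as the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "PairedSliceDataset",
    "minmax_normalize",
    "make_paired_dataset",
    "read_volume",
    "write_volume",
]


@dataclass
class Volume:
    """A single-contrast 3D image with optional mask and metadata."""

    data: np.ndarray
    mask: np.ndarray | None = None
    contrast: str = ""
    subject_id: str = ""
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data, np.float32)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D (slice, row, col)")
        if self.mask is not None:
            self.mask = np.asarray(self.mask)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must equal data shape")
            self.mask = (self.mask != 0)

    @property
    def shape(self):
        return self.data.shape

    @property
    def n_slices(self):
        return self.data.shape[0]


def minmax_normalize(v: Volume) -> Volume:
    """Affine map of intensities to [0, 1]; a constant volume maps to zeros."""
    data = v.data
    if not np.isfinite(data).all():
        raise ValueError("volume contains NaN or Inf")
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        out = (data - lo) / (hi - lo)
    else:
        out = np.zeros_like(data)
    return replace(v, data=out.astype(np.float32), normalized=True)


@dataclass
class PairedSliceDataset:
    """Aligned (input, target) 2D slice pairs consumed by the trainers."""

    pairs: list = field(default_factory=list)  # (x_slice, y_slice, subject_id, slice_idx)
    slice_shape: tuple = ()
    split: str = "train"
    input_contrast: str = ""
    target_contrast: str = ""

    def __len__(self):
        return len(self.pairs)

    def subjects(self):
        return sorted({sid for _, _, sid, _ in self.pairs})

    def arrays(self):
        """Stack all pairs to (N, 1, H, W) float32 input/target arrays."""
        x = np.stack([p[0] for p in self.pairs])[:, None].astype(np.float32)
        y = np.stack([p[1] for p in self.pairs])[:, None].astype(np.float32)
        return x, y

    def batches(self, batch_size, rng: np.random.Generator):
        idx = rng.permutation(len(self.pairs))
        x, y = self.arrays()
        for s in range(0, len(idx), batch_size):
            take = idx[s : s + batch_size]
            yield x[take], y[take]


def make_paired_dataset(
    subjects,
    input_contrast: str,
    target_contrast: str,
    split_fractions=(0.6, 0.2, 0.2),
    seed: int = 0,
) -> dict:
    """Subject-level split into train/val/test paired-slice datasets.

    A subject's slices never straddle splits; the subject order is shuffled
    with a seeded generator before splitting, so the split is reproducible.
    """
    for s in subjects:
        for c in (input_contrast, target_contrast):
            if c not in s.volumes:
                raise KeyError(f"subject {s.subject_id} lacks contrast '{c}'")
    fr = np.asarray(split_fractions, float)
    if fr.min() < 0 or not np.isclose(fr.sum(), 1.0):
        raise ValueError("split fractions must be nonnegative and sum to 1")

    order = list(subjects)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    n = len(order)
    n_train = int(round(fr[0] * n))
    n_val = int(round(fr[1] * n))
    groups = {
        "train": order[:n_train],
        "val": order[n_train : n_train + n_val],
        "test": order[n_train + n_val :],
    }
    out = {}
    for split, group in groups.items():
        ds = PairedSliceDataset(
            split=split, input_contrast=input_contrast, target_contrast=target_contrast
        )
        for s in group:
            xv, yv = s.volumes[input_contrast], s.volumes[target_contrast]
            for i in range(xv.n_slices):
                ds.pairs.append((xv.data[i], yv.data[i], s.subject_id, i))
        if ds.pairs:
            ds.slice_shape = ds.pairs[0][0].shape
        out[split] = ds
    return out


def write_volume(v: Volume, path):
    path = str(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"unsupported volume format: {path} (expected .nii/.nii.gz)")
    img = nib.Nifti1Image(v.data.astype(np.float32), affine=np.eye(4))
    nib.save(img, path)


def read_volume(path, contrast="", subject_id="") -> Volume:
    path = str(path)
    if not (path.endswith(".nii") or path.endswith(".nii.gz")):
        raise ValueError(f"unsupported volume format: {path} (expected .nii/.nii.gz)")
    try:
        img = nib.load(path)
    except Exception as e:  # noqa: BLE001
        raise IOError(f"cannot read volume {path}: {e}") from e
    data = np.asarray(img.get_fdata(), np.float32)
    return Volume(data=data, contrast=contrast, subject_id=subject_id)
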