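"""Volume containers, NIfTI I/O, preprocessing and online augmentation.

The preprocessing chain mirrors standard multi-organ practice: CT
intensities are clipped to [-350, 350] HU (MRI is left unclipped), the
field of view is optionally cropped to the labeled organs (or to a
body-intensity box when no labels exist), the volume is resampled to a
fixed grid, and intensities are min-max normalized to [0, 1].  Online
augmentation applies an in-plane rotation (±30°), shear (±0.1 rad) and a
gamma contrast adjustment (γ ∈ [1.5, 2]); geometric transforms hit image
and label identically (labels via nearest neighbour), gamma hits the
image only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume", "LabelMap", "preprocess", "augment", "normalize_minmax",
           "save_volume", "load_volume", "save_label", "load_label",
           "CT_CLIP_RANGE"]

CT_CLIP_RANGE = (-350.0, 350.0)
DEFAULT_CLASS_NAMES = ("background", "liver", "right_kidney", "left_kidney", "spleen")


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm per axis) and a modality tag."""
    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "synthetic-A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {self.values.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")

    def validate_finite(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("volume contains non-finite voxels")


@dataclass
class LabelMap:
    """Integer organ labels aligned voxel-for-voxel with a Volume."""
    labels: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3D label grid, got shape {self.labels.shape}")


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant volume maps to all zeros (warned)."""
    vmin, vmax = float(values.min()), float(values.max())
    if vmax <= vmin:
        warnings.warn("degenerate intensity range (max == min); returning zeros",
                      stacklevel=2)
        return np.zeros_like(values, dtype=np.float32)
    return ((values - vmin) / (vmax - vmin)).astype(np.float32)


def _resample(arr: np.ndarray, target: tuple[int, int, int], order: int) -> np.ndarray:
    """Resample to an exact target shape by centre-aligned grid sampling."""
    if tuple(arr.shape) == tuple(target):
        return arr.copy()
    coords = np.meshgrid(*[(np.arange(t) + 0.5) * (n / t) - 0.5
                           for n, t in zip(arr.shape, target)], indexing="ij")
    out = ndimage.map_coordinates(arr.astype(np.float32), np.stack(coords),
                                  order=order, mode="nearest")
    if order == 0:
        return out.astype(arr.dtype)
    return out


def _foreground_bbox(mask: np.ndarray, margin: int, shape) -> tuple[slice, ...]:
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - margin, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + margin, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def preprocess(volume: Volume, label: LabelMap | None,
               target_dims: tuple[int, int, int],
               *, crop: bool = False, crop_margin: int = 2
               ) -> tuple[Volume, LabelMap | None]:
    """Clip (CT only) -> optional crop -> resample -> normalize.

    Cropping uses the union bounding box of foreground labels plus
    ``crop_margin`` voxels; without labels, a body box thresholded at the
    mean intensity.  Labels are resampled with nearest neighbour so no new
    class values appear.
    """
    volume.validate_finite()
    vals = volume.values.astype(np.float32)
    if volume.modality.upper() == "CT":
        vals = np.clip(vals, *CT_CLIP_RANGE)
    lab = None if label is None else label.labels
    if lab is not None and lab.shape != vals.shape:
        raise ValueError(f"label shape {lab.shape} != volume shape {vals.shape}")
    if crop:
        if lab is not None and (lab > 0).any():
            box = _foreground_bbox(lab > 0, crop_margin, vals.shape)
        else:
            body = vals > vals.mean()
            box = (_foreground_bbox(body, crop_margin, vals.shape)
                   if body.any() else tuple(slice(None) for _ in range(3)))
        vals = vals[box]
        lab = None if lab is None else lab[box]
    vals = _resample(vals, target_dims, order=1)
    if lab is not None:
        lab = _resample(lab, target_dims, order=0)
    vals = normalize_minmax(vals)
    out_label = None if lab is None else LabelMap(
        lab, label.class_names if label else DEFAULT_CLASS_NAMES)
    return Volume(vals, volume.spacing_mm, volume.modality), out_label


def augment(volume: Volume, label: LabelMap | None = None,
            seed: int | None = None, *,
            rotation_deg: float | None = None,
            shear_rad: float | None = None,
            gamma: float | None = None,
            prob: float = 0.5) -> tuple[Volume, LabelMap | None]:
    """Random in-plane rotation/shear plus gamma contrast, deterministic per seed.

    Each transform fires independently with probability ``prob`` (randomized
    transforms are probabilistic, so clean volumes also appear in training);
    when it fires, parameters follow the training recipe: rotation
    U(-30°, 30°), shear U(-0.1, 0.1) rad, gamma U(1.5, 2).  Explicit keyword
    values override both the coin flip and the draw (useful for tests and for
    degenerate identity checks).  Geometric transforms are restricted to the
    first two (in-plane) axes, the slice axis being far coarser.
    """
    rng = np.random.default_rng(seed)
    if rotation_deg is None:
        rotation_deg = rng.uniform(-30.0, 30.0) if rng.random() < prob else 0.0
    if shear_rad is None:
        shear_rad = rng.uniform(-0.1, 0.1) if rng.random() < prob else 0.0
    if gamma is None:
        gamma = rng.uniform(1.5, 2.0) if rng.random() < prob else 1.0

    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    sh = np.array([[1.0, np.tan(shear_rad)], [0.0, 1.0]])
    m2 = rot @ sh
    m3 = np.eye(3)
    m3[:2, :2] = m2
    center = (np.asarray(volume.values.shape) - 1) / 2.0
    offset = center - m3 @ center

    vals = ndimage.affine_transform(volume.values.astype(np.float32), m3,
                                    offset=offset, order=1, mode="nearest")
    vals = np.clip(vals, 0.0, 1.0) ** np.float32(gamma)
    vals = np.clip(vals, 0.0, 1.0).astype(np.float32)
    out_vol = Volume(vals, volume.spacing_mm, volume.modality)
    if label is None:
        return out_vol, None
    lab = ndimage.affine_transform(label.labels, m3, offset=offset, order=0,
                                   mode="constant", cval=0,
                                   output=label.labels.dtype)
    return out_vol, LabelMap(lab, label.class_names)


# ----------------------------------------------------------------- NIfTI I/O

def _affine(spacing_mm) -> np.ndarray:
    return np.diag(list(spacing_mm) + [1.0])


def save_volume(volume: Volume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.spacing_mm)),
             str(path))


def load_volume(path: str | Path, modality: str = "synthetic-A") -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float32), spacing, modality)


def save_label(label: LabelMap, spacing_mm, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(label.labels.astype(np.int16), _affine(spacing_mm)),
             str(path))


def load_label(path: str | Path,
               class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES) -> LabelMap:
    img = nib.load(str(path))
    return LabelMap(np.asarray(img.dataobj, dtype=np.int16), class_names)
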