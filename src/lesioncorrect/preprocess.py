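"""Intensity and geometric preprocessing.

Covers the gamma intensity transform applied to secondary-network inputs,
ROI extraction (32x32 crop at a component centroid, upsampled to 64x64),
small-angle rotation augmentation of lesion-rich slices, and the two-phase
oversampling schedule that pre-trains on slices with many tiny lesions
before training on all slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .phantom import LabelMask, SlicePair

__all__ = [
    "ROIPatch",
    "OversampleSchedule",
    "gamma_transform",
    "normalize_roi",
    "extract_roi",
    "augment_rotations",
    "build_oversample_schedule",
]

#: permitted rotation magnitudes in degrees (either direction)
ROTATION_BAND = (5.0, 10.0)


@dataclass(frozen=True)
class ROIPatch:
    """A gamma-transformed T1 patch centred on a lesion-instance centroid."""

    pixels: np.ndarray
    source_centroid: tuple[float, float]
    source_slice_id: str = ""
    true_class: int | None = None

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise ValueError("ROI pixels must be a 2-D grid")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("ROI pixels must lie in [0, 1]")


@dataclass(frozen=True)
class OversampleSchedule:
    """Two-phase training schedule: lesion-rich slices first, then all.

    ``phase1_indices`` (slices whose lesion count exceeds the threshold) are
    used for pre-training; ``phase2_indices`` is every training slice.
    """

    phase1_indices: tuple[int, ...]
    phase2_indices: tuple[int, ...]
    lesion_count_threshold: int

    def __post_init__(self):
        if not set(self.phase1_indices) <= set(self.phase2_indices):
            raise ValueError("phase1 indices must be a subset of phase2 indices")


def gamma_transform(image: np.ndarray, gamma: float = 1.5) -> np.ndarray:
    """Pixelwise power-law mapping ``out = in ** gamma`` on [0, 1] intensities.

    With gamma > 1 low intensities are compressed relative to high ones,
    which sharpens the dark-lesion-vs-tissue contrast in T1 ROIs.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    img = np.asarray(image, dtype=np.float64)
    if img.size and (img.min() < 0.0 or img.max() > 1.0):
        raise ValueError("gamma_transform expects intensities in [0, 1]")
    return img ** gamma


def normalize_roi(raw_patch: np.ndarray) -> np.ndarray:
    """Min-max stretch a patch to [0, 1]; a constant patch maps to all zeros."""
    patch = np.asarray(raw_patch, dtype=np.float64)
    if patch.size == 0:
        raise ValueError("patch is empty")
    lo, hi = patch.min(), patch.max()
    if hi == lo:
        return np.zeros_like(patch)
    return (patch - lo) / (hi - lo)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def extract_roi(t1: np.ndarray, centroid: tuple[float, float], crop_size: int = 32,
                out_size: int = 64, gamma: float = 1.5, interpolation: str = "bilinear",
                slice_id: str = "", true_class: int | None = None) -> ROIPatch:
    """Extract, upsample, normalize and gamma-transform a centroid-centred ROI.

    A ``crop_size`` square window is centred on the rounded centroid
    (zero-padded where it exits the image), upsampled to ``out_size``
    (bilinear by default, ``"nearest"`` available), min-max normalized, then
    gamma-transformed — in that order, so the power transform acts on [0, 1].
    """
    img = np.asarray(t1, dtype=np.float64)
    r, c = centroid
    if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
        raise ValueError(f"centroid {centroid} outside image of shape {img.shape}")
    ri, ci = _round_half_away(float(r)), _round_half_away(float(c))
    half = crop_size // 2
    crop = np.zeros((crop_size, crop_size), dtype=np.float64)
    r0, c0 = ri - half, ci - half
    rs, re = max(r0, 0), min(r0 + crop_size, img.shape[0])
    cs, ce = max(c0, 0), min(c0 + crop_size, img.shape[1])
    crop[rs - r0:re - r0, cs - c0:ce - c0] = img[rs:re, cs:ce]
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    up = resize(crop, (out_size, out_size), order=order, anti_aliasing=False, preserve_range=True)
    out = gamma_transform(np.clip(normalize_roi(up), 0.0, 1.0), gamma)
    return ROIPatch(pixels=out, source_centroid=(float(r), float(c)),
                    source_slice_id=slice_id, true_class=true_class)


def _check_angle(angle: float) -> None:
    lo, hi = ROTATION_BAND
    if not (lo <= abs(angle) <= hi):
        raise ValueError(
            f"rotation angle {angle} outside the permitted bands ±[{lo}, {hi}] degrees"
        )


def augment_rotations(pair: SlicePair, mask: LabelMask, angles_degrees=None,
                      rng: np.random.Generator | None = None,
                      n_angles: int = 2) -> list[tuple[SlicePair, LabelMask]]:
    """Small-angle rotated copies of a slice pair and its mask.

    Angles must come from [5, 10] or [-10, -5] degrees (clockwise or
    counterclockwise). Images rotate with bilinear interpolation, masks with
    nearest-neighbour so labels stay in {0, 1, 2}; regions rotated in from
    outside the frame fill with 0.
    If ``angles_degrees`` is None, ``n_angles`` angles are drawn from the
    permitted bands (alternating direction) using ``rng``.
    """
    if angles_degrees is None:
        if rng is None:
            raise ValueError("need rng when angles are not given")
        lo, hi = ROTATION_BAND
        angles_degrees = [
            float(rng.uniform(lo, hi)) * (1 if k % 2 == 0 else -1) for k in range(n_angles)
        ]
    out = []
    for angle in angles_degrees:
        _check_angle(angle)
        t2 = np.clip(ndimage.rotate(pair.t2, angle, reshape=False, order=1, cval=0.0), 0.0, 1.0)
        t1 = np.clip(ndimage.rotate(pair.t1, angle, reshape=False, order=1, cval=0.0), 0.0, 1.0)
        lab = ndimage.rotate(mask.labels, angle, reshape=False, order=0, cval=0)
        out.append(
            (
                SlicePair(t2=t2, t1=t1, patient_id=pair.patient_id,
                          slice_id=f"{pair.slice_id}_rot{angle:+.1f}"),
                LabelMask(labels=lab.astype(mask.labels.dtype)),
            )
        )
    return out


def build_oversample_schedule(lesion_counts, threshold: int = 5) -> OversampleSchedule:
    """Build the two-phase schedule from per-slice lesion counts.

    Phase 1 contains the indices of slices with strictly more than
    ``threshold`` lesions; phase 2 contains every slice. Raises when no slice
    exceeds the threshold (lower it, or skip pre-training).
    """
    counts = np.asarray(lesion_counts)
    if counts.ndim != 1 or (counts < 0).any():
        raise ValueError("lesion_counts must be a 1-D array of nonnegative integers")
    phase1 = tuple(int(i) for i in np.nonzero(counts > threshold)[0])
    if not phase1:
        raise ValueError(f"no slice has more than {threshold} lesions; lower the threshold")
    return OversampleSchedule(
        phase1_indices=phase1,
        phase2_indices=tuple(range(len(counts))),
        lesion_count_threshold=int(threshold),
    )
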