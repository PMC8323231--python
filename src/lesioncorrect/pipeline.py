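"""The segmentation-correction cascade.

Binary segmentation on T2 -> connected-component instance extraction ->
per-instance classification on the co-registered T1 ROI -> label correction
into a semantic (background/FCI/LACI) mask. The correction step only ever
relabels instances; it never changes the segmented geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import FCI, LACI, SlicePair

__all__ = [
    "LesionInstance",
    "SemanticMask",
    "extract_components",
    "classify_instance",
    "correct_segmentation",
    "run_inference",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class LesionInstance:
    """One connected lesion component.

    ``pixels`` is an (n, 2) array of (row, col) coordinates; ``centroid`` is
    the arithmetic mean of the member coordinates (real-valued); ``bbox`` is
    (min_row, min_col, max_row, max_col) inclusive.
    """

    pixels: np.ndarray
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    predicted_class: int | None = None
    score: float | None = None
    true_class: int | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.pixels.T)] = True
        return m


@dataclass(frozen=True)
class SemanticMask:
    """Corrected per-pixel class mask in {0, 1, 2}."""

    labels: np.ndarray

    def __post_init__(self):
        bad = set(np.unique(self.labels)) - {0, FCI, LACI}
        if bad:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(bad)}")

    @property
    def binary(self) -> np.ndarray:
        return self.labels > 0


def extract_components(binary_mask: np.ndarray, connectivity: int = 8) -> list[LesionInstance]:
    """Extract connected foreground components as lesion instances.

    Components are returned in deterministic row-major order of their
    bounding-box origin. Centroids are arithmetic means of member pixel
    coordinates. An empty mask yields an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(binary_mask)
    if mask.ndim != 2:
        raise ValueError("binary mask must be 2-D")
    mask = mask.astype(bool)
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    instances = []
    for obj_slice, lab in zip(ndimage.find_objects(labeled, n), range(1, n + 1)):
        rows, cols = np.nonzero(labeled[obj_slice] == lab)
        rows = rows + obj_slice[0].start
        cols = cols + obj_slice[1].start
        pixels = np.column_stack([rows, cols])
        instances.append(
            LesionInstance(
                pixels=pixels,
                centroid=(float(rows.mean()), float(cols.mean())),
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())),
            )
        )
    instances.sort(key=lambda i: (i.bbox[0], i.bbox[1]))
    return instances


def classify_instance(instance: LesionInstance, t1: np.ndarray, secondary,
                      threshold: float = 0.5, crop_size: int = 32, out_size: int = 64,
                      gamma: float = 1.5) -> tuple[int, float]:
    """Classify one instance from its T1 ROI; strict ``score > threshold`` -> LACI.

    A score exactly at the threshold resolves to FCI (deterministic tie-break).
    Returns ``(class, score)`` where class is 1 (FCI) or 2 (LACI) and score is
    the secondary network's P(LACI).
    """
    from .preprocess import extract_roi

    patch = extract_roi(t1, instance.centroid, crop_size=crop_size, out_size=out_size, gamma=gamma)
    score = float(secondary.predict_proba(patch.pixels[None, None])[0])
    cls = LACI if score > threshold else FCI
    return cls, score


def correct_segmentation(binary_mask: np.ndarray, instances: list[LesionInstance]) -> SemanticMask:
    """Relabel each instance by its predicted class; geometry is preserved.

    Raises if the instances do not exactly cover the mask foreground or carry
    no predicted class.
    """
    mask = np.asarray(binary_mask).astype(bool)
    labels = np.zeros(mask.shape, dtype=np.uint8)
    covered = np.zeros(mask.shape, dtype=bool)
    for inst in instances:
        if inst.predicted_class not in (FCI, LACI):
            raise ValueError("every instance needs a predicted_class in {1, 2}")
        idx = tuple(inst.pixels.T)
        if covered[idx].any():
            raise ValueError("instances overlap")
        covered[idx] = True
        labels[idx] = inst.predicted_class
    if not np.array_equal(covered, mask):
        raise ValueError("instances do not cover the mask foreground exactly")
    return SemanticMask(labels=labels)


def run_inference(pair: SlicePair, primary, secondary, cls_threshold: float = 0.5,
                  connectivity: int = 8, min_lesion_px: int = 0,
                  gamma: float = 1.5) -> tuple[SemanticMask, list[LesionInstance]]:
    """Run the full two-stage cascade on one slice pair.

    The primary network segments the T2 image; argmax over the class channels
    yields the binary lesion mask, with softmax ties resolving to background
    (class 0 wins ties via argmax's first-index rule). Each connected
    component is then scored on its T1 ROI by the secondary network and the
    mask is relabeled accordingly. Slices with no predicted components return
    an all-zero mask without invoking the secondary network.
    """
    probs = primary.predict_proba(pair.t2[None, None])[0]  # (n_classes, H, W)
    binary = probs.argmax(axis=0) > 0
    instances = extract_components(binary, connectivity=connectivity)
    if min_lesion_px > 0:
        instances = [i for i in instances if i.n_pixels >= min_lesion_px]
        binary = np.zeros_like(binary)
        for inst in instances:
            binary[tuple(inst.pixels.T)] = True
    if not instances:
        return SemanticMask(labels=np.zeros(binary.shape, dtype=np.uint8)), []
    for inst in instances:
        inst.predicted_class, inst.score = classify_instance(
            inst, pair.t1, secondary, threshold=cls_threshold, gamma=gamma
        )
    return correct_segmentation(binary, instances), instances
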