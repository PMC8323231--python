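"""Seeded synthetic T2/T1 FLAIR phantom slices with planted tiny lesions.

The generator emulates the contrast semantics of the two lesion classes on
the two modalities: both focal cerebral ischemia (FCI) and lacunar infarcts
(LACI) are bright on T2 FLAIR, while on T1 FLAIR an FCI is isointense with
surrounding white matter and a LACI is dark. Lesions are planted as small
non-overlapping disks inside an elliptical "brain", so the ground-truth
instance masks are exact by construction.

Patient mix defaults follow a 113-patient clinical cohort composition of
30 LACI / 68 FCI / 37 healthy patients; both the mix and every intensity
level are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FCI",
    "LACI",
    "PhantomConfig",
    "SlicePair",
    "LabelMask",
    "PhantomRecord",
    "generate_slice",
    "generate_dataset",
]

FCI = 1  #: label value for focal cerebral ischemia
LACI = 2  #: label value for lacunar infarction

#: cohort composition used for dataset defaults: 37 of 113 patients healthy,
#: and 30 of the 98 diseased patients have lacunar infarcts
HEALTHY_PATIENT_FRACTION = 37 / 113
LACI_PATIENT_FRACTION = 30 / 98


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic slice pair.

    Intensities are normalized to [0, 1]. ``class_mix`` is the probability
    that an individual planted lesion is a LACI rather than an FCI; the
    default reflects the cohort's lesion-image ratio (70 LACI vs 191 FCI).
    """

    image_size: int = 128
    lesion_radius_range: tuple[int, int] = (1, 4)
    lesion_count_range: tuple[int, int] = (1, 12)
    class_mix: float = 70 / 261
    background_level: float = 0.05
    brain_level: float = 0.40
    t2_lesion_level: float = 0.90
    t1_fci_level: float = 0.40
    t1_laci_level: float = 0.10
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        levels = {
            "background_level": self.background_level,
            "brain_level": self.brain_level,
            "t2_lesion_level": self.t2_lesion_level,
            "t1_fci_level": self.t1_fci_level,
            "t1_laci_level": self.t1_laci_level,
        }
        for name, v in levels.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.t1_laci_level >= self.brain_level:
            raise ValueError("t1_laci_level must be below brain_level (LACI is dark on T1)")
        if self.t2_lesion_level <= self.brain_level:
            raise ValueError("t2_lesion_level must exceed brain_level (lesions are bright on T2)")
        margin = max(2.0 * self.noise_sd, 0.05)
        if abs(self.t1_fci_level - self.brain_level) >= margin:
            raise ValueError("t1_fci_level must be isointense with brain_level (within noise margin)")
        lo, hi = self.lesion_radius_range
        if not (isinstance(lo, (int, np.integer)) and isinstance(hi, (int, np.integer))) or lo > hi or lo < 1:
            raise ValueError("lesion_radius_range must be a nonempty integer interval with lo >= 1")
        lo, hi = self.lesion_count_range
        if lo > hi or lo < 0:
            raise ValueError("lesion_count_range must be a nonempty interval of counts >= 0")
        if not 0.0 <= self.class_mix <= 1.0:
            raise ValueError("class_mix must be a probability")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.image_size < 16:
            raise ValueError("image_size too small")


@dataclass(frozen=True)
class SlicePair:
    """Co-registered T2 and T1 FLAIR intensity grids for one slice."""

    t2: np.ndarray
    t1: np.ndarray
    patient_id: str = "P000"
    slice_id: str = "S000"

    def __post_init__(self):
        if self.t2.shape != self.t1.shape:
            raise ValueError("t2 and t1 must have identical shapes")


@dataclass(frozen=True)
class LabelMask:
    """Per-pixel class mask: 0 background, 1 FCI, 2 LACI."""

    labels: np.ndarray

    def __post_init__(self):
        bad = set(np.unique(self.labels)) - {0, FCI, LACI}
        if bad:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(bad)}")

    @property
    def binary(self) -> np.ndarray:
        """Boolean lesion-vs-background view."""
        return self.labels > 0


@dataclass(frozen=True)
class PhantomRecord:
    """One generated slice: image pair, mask, and exact instances."""

    pair: SlicePair
    mask: LabelMask
    instances: list


def _brain_ellipse(size: int) -> np.ndarray:
    r = np.arange(size)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    cy = cx = (size - 1) / 2.0
    a, b = 0.44 * size, 0.38 * size  # semi-axes (rows, cols)
    return ((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2 <= 1.0


def _disk(center: tuple[int, int], radius: int, size: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _place_lesions(config: PhantomConfig, n: int, brain: np.ndarray, rng: np.random.Generator,
                   max_attempts_per_lesion: int = 200):
    """Sample non-overlapping disk centres/radii fully inside the brain."""
    size = config.image_size
    placed: list[tuple[int, int, int]] = []  # (row, col, radius)
    attempts = 0
    budget = max_attempts_per_lesion * max(n, 1)
    while len(placed) < n:
        if attempts >= budget:
            raise RuntimeError(
                f"could not place {n} non-overlapping lesions after {budget} attempts; "
                "configuration too dense"
            )
        attempts += 1
        radius = int(rng.integers(config.lesion_radius_range[0], config.lesion_radius_range[1] + 1))
        row = int(rng.integers(radius, size - radius))
        col = int(rng.integers(radius, size - radius))
        disk = _disk((row, col), radius, size)
        if not brain[disk].all():
            continue
        # keep a >=2 px gap so instances stay separate under 8-connectivity
        if any((row - r) ** 2 + (col - c) ** 2 <= (radius + rad + 2) ** 2 for r, c, rad in placed):
            continue
        placed.append((row, col, radius))
    return placed


def generate_slice(config: PhantomConfig, rng: np.random.Generator | int | None = None,
                   patient_id: str = "P000", slice_id: str = "S000",
                   lesion_classes: np.ndarray | None = None):
    """Generate one slice pair with planted lesions and exact ground truth.

    Parameters
    ----------
    config
        Validated phantom configuration.
    rng
        NumPy generator or seed; defaults to ``config.seed``.
    lesion_classes
        Optional explicit class per lesion (values in {1, 2}); by default each
        lesion is LACI with probability ``config.class_mix``.

    Returns
    -------
    (SlicePair, LabelMask, list of LesionInstance)
    """
    from .pipeline import extract_components  # local import to avoid a cycle

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    size = config.image_size
    brain = _brain_ellipse(size)
    t2 = np.where(brain, config.brain_level, config.background_level).astype(np.float64)
    t1 = t2.copy()
    labels = np.zeros((size, size), dtype=np.uint8)

    n = int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
    placed = _place_lesions(config, n, brain, rng)
    if lesion_classes is not None:
        classes = np.asarray(lesion_classes, dtype=int)
        if classes.shape != (n,) or not np.isin(classes, [FCI, LACI]).all():
            raise ValueError(f"lesion_classes must contain {n} values in {{1, 2}}")
    else:
        classes = np.where(rng.random(n) < config.class_mix, LACI, FCI)
    for (row, col, radius), cls in zip(placed, classes):
        disk = _disk((row, col), radius, size)
        t2[disk] = config.t2_lesion_level
        t1[disk] = config.t1_laci_level if cls == LACI else config.t1_fci_level
        labels[disk] = cls

    if config.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, config.noise_sd, t2.shape)
        t1 = t1 + rng.normal(0.0, config.noise_sd, t1.shape)
    t2 = np.clip(t2, 0.0, 1.0)
    t1 = np.clip(t1, 0.0, 1.0)

    pair = SlicePair(t2=t2, t1=t1, patient_id=patient_id, slice_id=slice_id)
    mask = LabelMask(labels=labels)
    instances = extract_components(mask.binary, connectivity=8)
    for inst in instances:
        vals = labels[tuple(inst.pixels.T)]
        inst.true_class = int(vals[0])
    return pair, mask, instances


def generate_dataset(config: PhantomConfig, n_patients: int, slices_per_patient: int,
                     healthy_fraction: float = HEALTHY_PATIENT_FRACTION,
                     rng: np.random.Generator | int | None = None,
                     laci_patient_fraction: float = LACI_PATIENT_FRACTION,
                     laci_lesion_purity: float = 0.7,
                     patient_types: list[str] | None = None) -> list[PhantomRecord]:
    """Generate a patient-structured dataset of slice pairs.

    Each patient is healthy with probability ``healthy_fraction`` (all their
    slices lesion-free); diseased patients are LACI patients with probability
    ``laci_patient_fraction``, otherwise FCI patients. FCI patients carry only
    FCI lesions; a LACI patient's lesions are LACI with probability
    ``laci_lesion_purity`` (mixed pathology occurs clinically: FCI and LACI
    can share a slice). ``patient_types`` (values from
    ``{"healthy", "fci", "laci"}``) overrides the random type draw with fixed
    quotas — useful for small benchmark cohorts where every cross-validation
    fold must contain both lesion classes. Reproducible from the generator
    state.
    """
    if n_patients < 5:
        raise ValueError("need at least 5 patients for five-fold cross-validation")
    if slices_per_patient < 1:
        raise ValueError("slices_per_patient must be positive")
    if patient_types is not None:
        patient_types = list(patient_types)
        if len(patient_types) != n_patients or not set(patient_types) <= {"healthy", "fci", "laci"}:
            raise ValueError("patient_types must give one of healthy/fci/laci per patient")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    records: list[PhantomRecord] = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        if patient_types is not None:
            healthy = patient_types[p] == "healthy"
            laci_patient = patient_types[p] == "laci"
        else:
            healthy = rng.random() < healthy_fraction
            laci_patient = (not healthy) and (rng.random() < laci_patient_fraction)
        for s in range(slices_per_patient):
            sid = f"{pid}_S{s:03d}"
            if healthy:
                cfg = replace(config, lesion_count_range=(0, 0))
                pair, mask, inst = generate_slice(cfg, rng, patient_id=pid, slice_id=sid)
            else:
                n = int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
                cfg = replace(config, lesion_count_range=(n, n))
                if laci_patient:
                    classes = np.where(rng.random(n) < laci_lesion_purity, LACI, FCI)
                else:
                    classes = np.full(n, FCI)
                pair, mask, inst = generate_slice(cfg, rng, patient_id=pid, slice_id=sid,
                                                  lesion_classes=classes)
            records.append(PhantomRecord(pair=pair, mask=mask, instances=inst))
    return records
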