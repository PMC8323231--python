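"""File formats and run configuration.

Slices are stored one per file: images as 16-bit grayscale PNG or
single-slice NIfTI, label masks as 8-bit PNG with values {0, 1, 2}. A
dataset is a directory with an index CSV (``patient_id, slice_id, t2_path,
t1_path, mask_path``), which keeps patient-level cross-validation trivial.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .evaluation import EvalConfig
from .networks import PrimaryNetSpec, SecondaryNetSpec
from .phantom import LabelMask, PhantomConfig, PhantomRecord, SlicePair
from .pipeline import SemanticMask, extract_components
from .training import TrainConfig

__all__ = [
    "RunConfig",
    "read_slice_pair",
    "write_slice_pair",
    "write_semantic_mask",
    "read_mask",
    "save_dataset",
    "load_dataset",
    "save_weights",
    "load_weights",
]


def _read_gray(path: Path) -> np.ndarray:
    """Read one grayscale slice (PNG or NIfTI) scaled to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".nii",) or path.name.endswith(".nii.gz"):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
    else:
        data = iio.imread(path)
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D slice, got shape {data.shape}")
    data = data.astype(np.float64)
    lo, hi = data.min(), data.max()
    return np.zeros_like(data) if hi == lo else (data - lo) / (hi - lo)


def read_slice_pair(t2_path, t1_path, patient_id: str = "P000", slice_id: str = "S000") -> SlicePair:
    """Load co-registered T2/T1 slices; each is min-max scaled to [0, 1]."""
    t2 = _read_gray(Path(t2_path))
    t1 = _read_gray(Path(t1_path))
    if t2.shape != t1.shape:
        raise ValueError(f"shape mismatch: t2 {t2.shape} vs t1 {t1.shape}")
    return SlicePair(t2=t2, t1=t1, patient_id=patient_id, slice_id=slice_id)


def write_slice_pair(pair: SlicePair, t2_path, t1_path) -> None:
    """Write both modalities as 16-bit grayscale PNGs."""
    for img, path in ((pair.t2, t2_path), (pair.t1, t1_path)):
        arr = np.clip(np.round(np.asarray(img) * 65535), 0, 65535).astype(np.uint16)
        iio.imwrite(Path(path), arr)


def write_semantic_mask(mask, path) -> None:
    """Write a {0,1,2} label mask as an 8-bit PNG; round-trips losslessly."""
    labels = np.asarray(mask.labels if hasattr(mask, "labels") else mask)
    if set(np.unique(labels)) - {0, 1, 2}:
        raise ValueError("mask values must lie in {0, 1, 2}")
    iio.imwrite(Path(path), labels.astype(np.uint8))


def read_mask(path) -> LabelMask:
    labels = iio.imread(Path(path))
    return LabelMask(labels=labels.astype(np.uint8))


def save_dataset(records: list[PhantomRecord], out_dir) -> Path:
    """Write slices + masks + the index CSV; returns the index path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        sid = rec.pair.slice_id
        t2p, t1p, mp = out / f"{sid}_t2.png", out / f"{sid}_t1.png", out / f"{sid}_mask.png"
        write_slice_pair(rec.pair, t2p, t1p)
        write_semantic_mask(rec.mask, mp)
        rows.append(
            dict(patient_id=rec.pair.patient_id, slice_id=sid,
                 t2_path=t2p.name, t1_path=t1p.name, mask_path=mp.name)
        )
    index = out / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def load_dataset(index_csv) -> list[PhantomRecord]:
    """Load a dataset from its index CSV (paths relative to the index)."""
    index_csv = Path(index_csv)
    base = index_csv.parent
    df = pd.read_csv(index_csv)
    records = []
    for row in df.itertuples(index=False):
        pair = read_slice_pair(base / row.t2_path, base / row.t1_path,
                               patient_id=str(row.patient_id), slice_id=str(row.slice_id))
        mask = read_mask(base / row.mask_path)
        instances = extract_components(mask.binary, connectivity=8)
        for inst in instances:
            inst.true_class = int(mask.labels[tuple(inst.pixels.T)][0])
        records.append(PhantomRecord(pair=pair, mask=mask, instances=instances))
    return records


def save_weights(net, path) -> None:
    """Serialize a network's state dict as an .npz archive."""
    np.savez_compressed(Path(path), **net.state_dict())


def load_weights(net, path) -> None:
    with np.load(Path(path)) as data:
        net.load_state_dict(dict(data))


@dataclass
class RunConfig:
    """One document merging every stage's configuration.

    Serialized as YAML with one section per component; unknown sections or
    keys are rejected on load, and component invariants are validated.
    """

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    primary: PrimaryNetSpec = field(default_factory=PrimaryNetSpec)
    secondary: SecondaryNetSpec = field(default_factory=SecondaryNetSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)

    _SECTIONS = {
        "phantom": PhantomConfig,
        "primary": PrimaryNetSpec,
        "secondary": SecondaryNetSpec,
        "training": TrainConfig,
        "evaluation": EvalConfig,
    }

    def validate(self) -> None:
        self.phantom.validate()
        self.primary.validate()
        self.secondary.validate()
        self.training.validate()
        self.evaluation.validate()

    def to_yaml(self, path) -> None:
        doc = {name: asdict(getattr(self, name)) for name in self._SECTIONS}
        for section in doc.values():
            for k, v in section.items():
                if isinstance(v, tuple):
                    section[k] = list(v)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError("config root must be a mapping")
        unknown = set(doc) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, klass in cls._SECTIONS.items():
            section = doc.get(name, {})
            allowed = {f.name for f in fields(klass)}
            bad = set(section) - allowed
            if bad:
                raise ValueError(f"unknown keys in [{name}]: {sorted(bad)}")
            for k, v in section.items():
                if isinstance(v, list):
                    section[k] = tuple(v)
            kwargs[name] = klass(**section)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Short content hash for run logging."""
        doc = {name: asdict(getattr(self, name)) for name in self._SECTIONS}
        return hashlib.sha256(repr(sorted(doc.items())).encode()).hexdigest()[:12]
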