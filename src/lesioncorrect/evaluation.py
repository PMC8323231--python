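"""Segmentation, detection and classification metrics plus the CV harness.

Segmentation is scored with the Dice coefficient; detection and
classification with precision. A predicted lesion counts as a true positive
only when its IoU with a ground-truth lesion is strictly higher than the
threshold (default 0.6); matching is greedy, one-to-one, in descending IoU
order. Cross-validation splits at the patient level by default so no
patient's slices straddle folds; fold metrics are pooled over the fold's
slices and the reported value is the mean over folds (folds where a
precision is undefined — no predicted positives — are excluded from that
mean rather than counted as zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .networks import PrimaryNetSpec, SecondaryNetSpec
from .phantom import FCI, LACI, PhantomRecord
from .pipeline import LesionInstance, SemanticMask, correct_segmentation, extract_components, run_inference
from .preprocess import build_oversample_schedule, augment_rotations, extract_roi, OversampleSchedule
from .training import TrainConfig, train_primary, train_secondary

__all__ = [
    "EvalConfig",
    "EvalResult",
    "dice_coefficient",
    "instance_iou",
    "match_detections",
    "detection_precision",
    "classification_precision",
    "five_fold_cv",
    "make_train_fn",
    "run_ablation",
    "VARIANTS",
]


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings: IoU threshold, fold count, split granularity."""

    iou_threshold: float = 0.6
    n_folds: int = 5
    split_unit: str = "patient"
    seed: int = 0
    match_on: str = "mask"
    connectivity: int = 8

    def validate(self) -> None:
        if not 0.0 < self.iou_threshold <= 1.0:
            raise ValueError("iou_threshold must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.split_unit not in ("patient", "slice"):
            raise ValueError("split_unit must be 'patient' or 'slice'")
        if self.match_on not in ("mask", "bbox"):
            raise ValueError("match_on must be 'mask' or 'bbox'")


@dataclass
class EvalResult:
    """Per-fold and averaged metrics for one evaluated variant."""

    fold_dice: np.ndarray
    fold_detection_precision: np.ndarray
    fold_classification_precision: np.ndarray
    variant: str = ""

    @property
    def dice(self) -> float:
        return float(np.nanmean(self.fold_dice))

    @property
    def detection_precision(self) -> float:
        return float(np.nanmean(self.fold_detection_precision))

    @property
    def classification_precision(self) -> float:
        return float(np.nanmean(self.fold_classification_precision))

    def as_row(self) -> dict:
        return {
            "variant": self.variant,
            "dice": self.dice,
            "detection_precision": self.detection_precision,
            "classification_precision": self.classification_precision,
        }


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def dice_coefficient(pred_binary: np.ndarray, true_binary: np.ndarray) -> float:
    """2|P∩T| / (|P|+|T|); two empty masks score 1.0 by convention."""
    p = np.asarray(pred_binary).astype(bool)
    t = np.asarray(true_binary).astype(bool)
    if p.shape != t.shape:
        raise ValueError("mask shapes differ")
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)


def _bbox_iou(a: LesionInstance, b: LesionInstance) -> float:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    ih = max(0, min(ar1, br1) - max(ar0, br0) + 1)
    iw = max(0, min(ac1, bc1) - max(ac0, bc0) + 1)
    inter = ih * iw
    area_a = (ar1 - ar0 + 1) * (ac1 - ac0 + 1)
    area_b = (br1 - br0 + 1) * (bc1 - bc0 + 1)
    return inter / (area_a + area_b - inter)


def instance_iou(a: LesionInstance, b: LesionInstance, mode: str = "mask") -> float:
    """IoU of two instances on pixel sets (default) or bounding boxes."""
    if mode == "bbox":
        return _bbox_iou(a, b)
    sa, sb = a.pixel_set(), b.pixel_set()
    if not sa or not sb:
        raise ValueError("instances must be nonempty")
    return len(sa & sb) / len(sa | sb)


def match_detections(pred_instances: list[LesionInstance], true_instances: list[LesionInstance],
                     iou_threshold: float = 0.6, mode: str = "mask"):
    """Greedy one-to-one matching in descending IoU order.

    A pair is a match only if its IoU is *strictly* greater than
    ``iou_threshold``. Returns ``(matches, false_positives, false_negatives)``
    where matches are ``(pred, true, iou)`` triples. The result does not
    depend on the input ordering of the instance lists (ties break on
    bounding-box position).
    """
    candidates = []
    for p in pred_instances:
        for t in true_instances:
            iou = instance_iou(p, t, mode=mode)
            if iou > iou_threshold:
                candidates.append((iou, p, t))
    candidates.sort(key=lambda c: (-c[0], c[1].bbox, c[2].bbox))
    used_p, used_t = set(), set()
    matches = []
    for iou, p, t in candidates:
        if id(p) in used_p or id(t) in used_t:
            continue
        used_p.add(id(p))
        used_t.add(id(t))
        matches.append((p, t, iou))
    false_positives = [p for p in pred_instances if id(p) not in used_p]
    false_negatives = [t for t in true_instances if id(t) not in used_t]
    return matches, false_positives, false_negatives


def detection_precision(n_matches: int, n_false_positives: int) -> float:
    """TP / (TP + FP); NaN (undefined) when there are no predicted positives."""
    if n_matches < 0 or n_false_positives < 0:
        raise ValueError("counts must be nonnegative")
    total = n_matches + n_false_positives
    if total == 0:
        return float("nan")
    return n_matches / total


def classification_precision(matched_pairs) -> float:
    """Fraction of matched instances whose predicted class equals the truth.

    Pairs lacking a predicted or true class are ignored; NaN when no pair
    carries both.
    """
    scored = [
        (p.predicted_class, t.true_class)
        for p, t, *_ in matched_pairs
        if p.predicted_class is not None and t.true_class is not None
    ]
    if not scored:
        return float("nan")
    return sum(pc == tc for pc, tc in scored) / len(scored)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _fold_split(records: list[PhantomRecord], cfg: EvalConfig) -> list[tuple[list[int], list[int]]]:
    """Partition record indices into (train, test) folds of near-equal unit counts."""
    if cfg.split_unit == "patient":
        units: dict[str, list[int]] = {}
        for i, r in enumerate(records):
            units.setdefault(r.pair.patient_id, []).append(i)
        unit_ids = sorted(units)
    else:
        unit_ids = list(range(len(records)))
        units = {i: [i] for i in unit_ids}
    if len(unit_ids) < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} {cfg.split_unit}s, have {len(unit_ids)}")
    rng = np.random.default_rng(cfg.seed)
    order = [unit_ids[i] for i in rng.permutation(len(unit_ids))]
    chunks = np.array_split(np.arange(len(order)), cfg.n_folds)
    folds = []
    for chunk in chunks:
        test_units = {order[i] for i in chunk}
        test = sorted(i for u in test_units for i in units[u])
        train = sorted(i for u in order if u not in test_units for i in units[u])
        folds.append((train, test))
    return folds


def _evaluate_fold(predictor, test_records: list[PhantomRecord], cfg: EvalConfig):
    """Pooled (dice, detection precision, classification precision) over a fold."""
    inter = size_p = size_t = 0
    tp = fp = 0
    matched_pairs = []
    for rec in test_records:
        mask, instances = predictor(rec)
        pred_bin = mask.binary
        true_bin = rec.mask.binary
        inter += np.logical_and(pred_bin, true_bin).sum()
        size_p += pred_bin.sum()
        size_t += true_bin.sum()
        matches, fps, _ = match_detections(instances, rec.instances,
                                           iou_threshold=cfg.iou_threshold, mode=cfg.match_on)
        tp += len(matches)
        fp += len(fps)
        matched_pairs.extend(matches)
    dice = 1.0 if size_p + size_t == 0 else 2.0 * inter / (size_p + size_t)
    return float(dice), detection_precision(tp, fp), classification_precision(matched_pairs)


def five_fold_cv(dataset: list[PhantomRecord], train_fn, eval_cfg: EvalConfig | None = None,
                 variant: str = "") -> EvalResult:
    """Patient-level k-fold cross-validation of a training procedure.

    ``train_fn(train_records, rng)`` must return a predictor
    ``predictor(record) -> (SemanticMask, instances)``. Every slice is tested
    exactly once; folds are a seeded, reproducible partition of patients.
    """
    cfg = eval_cfg or EvalConfig()
    cfg.validate()
    folds = _fold_split(dataset, cfg)
    dice, det, cls = [], [], []
    for k, (train_idx, test_idx) in enumerate(folds):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, k]))
        predictor = train_fn([dataset[i] for i in train_idx], rng)
        d, p, c = _evaluate_fold(predictor, [dataset[i] for i in test_idx], cfg)
        dice.append(d)
        det.append(p)
        cls.append(c)
    return EvalResult(
        fold_dice=np.array(dice),
        fold_detection_precision=np.array(det),
        fold_classification_precision=np.array(cls),
        variant=variant,
    )


# ---------------------------------------------------------------------------
# ablation variants
# ---------------------------------------------------------------------------

#: the supported experiment switch set: task a = 3-class semantic segmentation
#: in one stage, task b = binary lesion segmentation; ``two_stage`` adds the
#: ROI correction classifier; ``augment``/``oversample`` toggle the training
#: strategies.
VARIANTS: dict[str, dict] = {
    "primary_a": dict(task="a", two_stage=False, augment=False, oversample=False),
    "primary_b": dict(task="b", two_stage=False, augment=False, oversample=False),
    "primary_a_aug": dict(task="a", two_stage=False, augment=True, oversample=False),
    "primary_b_aug": dict(task="b", two_stage=False, augment=True, oversample=False),
    "primary_a_oversample": dict(task="a", two_stage=False, augment=False, oversample=True),
    "primary_b_oversample": dict(task="b", two_stage=False, augment=False, oversample=True),
    "primary_a_aug_oversample": dict(task="a", two_stage=False, augment=True, oversample=True),
    "primary_b_aug_oversample": dict(task="b", two_stage=False, augment=True, oversample=True),
    "two_stage": dict(task="b", two_stage=True, augment=False, oversample=False),
    "two_stage_aug": dict(task="b", two_stage=True, augment=True, oversample=False),
    "two_stage_oversample": dict(task="b", two_stage=True, augment=False, oversample=True),
    "proposed": dict(task="b", two_stage=True, augment=True, oversample=True),
}


def _augmented(records: list[PhantomRecord], threshold: int, rng: np.random.Generator):
    """Training records plus rotated copies of lesion-rich slices."""
    out = list(records)
    for rec in records:
        if len(rec.instances) > threshold:
            for pair, mask in augment_rotations(rec.pair, rec.mask, rng=rng, n_angles=2):
                instances = extract_components(mask.binary, connectivity=8)
                for inst in instances:
                    vals = mask.labels[tuple(inst.pixels.T)]
                    inst.true_class = int(vals[0])
                out.append(PhantomRecord(pair=pair, mask=mask, instances=instances))
    return out


def _schedule_for(records: list[PhantomRecord], oversample: bool, threshold: int,
                  cfg: TrainConfig) -> tuple[OversampleSchedule, TrainConfig]:
    counts = [len(r.instances) for r in records]
    if oversample:
        return build_oversample_schedule(counts, threshold=threshold), cfg
    sched = OversampleSchedule(phase1_indices=(), phase2_indices=tuple(range(len(records))),
                               lesion_count_threshold=threshold)
    return sched, replace(cfg, epochs_phase1=0)


def _train_fold_primary(records, task: str, augment: bool, oversample: bool,
                        primary_spec: PrimaryNetSpec, train_cfg: TrainConfig,
                        rng: np.random.Generator, threshold: int = 5, eta: float = 0.01,
                        lesion_weight: float = 1.0, eta_decay: float = 1.0):
    recs = _augmented(records, threshold, rng) if augment else records
    n_classes = 3 if task == "a" else 2
    spec = replace(primary_spec, n_classes=n_classes)
    sched, cfg = _schedule_for(recs, oversample, threshold, train_cfg)
    weights = None if lesion_weight == 1.0 else (1.0,) + (lesion_weight,) * (n_classes - 1)
    net, _ = train_primary(recs, sched, spec, cfg, rng=rng, eta=eta, class_weights=weights,
                           eta_decay=eta_decay)
    return net


def _training_rois(records: list[PhantomRecord], gamma: float = 1.5):
    """Ground-truth-centroid T1 ROIs with class labels for the secondary network."""
    rois = []
    for rec in records:
        for inst in rec.instances:
            rois.append(
                extract_roi(rec.pair.t1, inst.centroid, gamma=gamma,
                            slice_id=rec.pair.slice_id, true_class=inst.true_class)
            )
    return rois


def _primary_only_predictor(net, task: str, cfg: EvalConfig):
    def predict(rec: PhantomRecord):
        probs = net.predict_proba(rec.pair.t2[None, None])[0]
        classes = probs.argmax(axis=0)
        binary = classes > 0
        instances = extract_components(binary, connectivity=cfg.connectivity)
        if task == "a":
            for inst in instances:
                vals = classes[tuple(inst.pixels.T)]
                inst.predicted_class = FCI if (vals == FCI).sum() >= (vals == LACI).sum() else LACI
            if instances:
                return correct_segmentation(binary, instances), instances
        labels = binary.astype(np.uint8) if task == "b" else np.zeros_like(binary, dtype=np.uint8)
        return SemanticMask(labels=labels), instances

    return predict


def make_train_fn(variant: str, primary_spec: PrimaryNetSpec | None = None,
                  secondary_spec: SecondaryNetSpec | None = None,
                  train_cfg: TrainConfig | None = None, eval_cfg: EvalConfig | None = None,
                  oversample_threshold: int = 5, eta: float = 0.01,
                  lesion_weight: float = 1.0, secondary_cfg: TrainConfig | None = None,
                  eta_secondary: float | None = None, eta_decay: float = 1.0):
    """Build a ``train_fn`` for :func:`five_fold_cv` from a variant name."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    v = VARIANTS[variant]
    pspec = primary_spec or PrimaryNetSpec()
    sspec = secondary_spec or SecondaryNetSpec()
    tcfg = train_cfg or TrainConfig()
    scfg = secondary_cfg or tcfg
    seta = eta if eta_secondary is None else eta_secondary

    ecfg = eval_cfg or EvalConfig()

    def train_fn(train_records, rng):
        primary = _train_fold_primary(train_records, v["task"], v["augment"], v["oversample"],
                                      pspec, tcfg, rng, threshold=oversample_threshold, eta=eta,
                                      lesion_weight=lesion_weight, eta_decay=eta_decay)
        if not v["two_stage"]:
            return _primary_only_predictor(primary, v["task"], ecfg)
        secondary, _ = train_secondary(_training_rois(train_records), sspec, scfg, rng=rng, eta=seta)

        def predict(rec: PhantomRecord):
            return run_inference(rec.pair, primary, secondary, connectivity=ecfg.connectivity)

        return predict

    return train_fn


def run_ablation(dataset: list[PhantomRecord], variants: list[str],
                 primary_spec: PrimaryNetSpec | None = None,
                 secondary_spec: SecondaryNetSpec | None = None,
                 train_cfg: TrainConfig | None = None, eval_cfg: EvalConfig | None = None,
                 oversample_threshold: int = 5, eta: float = 0.01,
                 lesion_weight: float = 1.0, secondary_cfg: TrainConfig | None = None,
                 eta_secondary: float | None = None,
                 eta_decay: float = 1.0) -> tuple[dict[str, EvalResult], pd.DataFrame]:
    """Evaluate several experiment variants on identical folds.

    Variants sharing an underlying primary-network configuration (same task /
    augmentation / oversampling switches) reuse the same trained network per
    fold, so e.g. the two-stage run and its primary-only counterpart are
    compared on literally the same segmentations. Returns the per-variant
    ``EvalResult`` objects and a tidy summary DataFrame.
    """
    unknown = [v for v in variants if v not in VARIANTS]
    if unknown:
        raise ValueError(f"unknown variants: {unknown}")
    pspec = primary_spec or PrimaryNetSpec()
    sspec = secondary_spec or SecondaryNetSpec()
    tcfg = train_cfg or TrainConfig()
    scfg = secondary_cfg or tcfg
    seta = eta if eta_secondary is None else eta_secondary
    ecfg = eval_cfg or EvalConfig()
    ecfg.validate()

    results = {v: {"dice": [], "det": [], "cls": []} for v in variants}
    if variants:
        folds = _fold_split(dataset, ecfg)
        for k, (train_idx, test_idx) in enumerate(folds):
            train_records = [dataset[i] for i in train_idx]
            test_records = [dataset[i] for i in test_idx]
            primary_cache: dict[tuple, object] = {}
            secondary_net = None
            for variant in variants:
                v = VARIANTS[variant]
                pkey = (v["task"], v["augment"], v["oversample"])
                if pkey not in primary_cache:
                    key_id = {"a": 0, "b": 1}[v["task"]] * 4 + v["augment"] * 2 + v["oversample"]
                    rng = np.random.default_rng(np.random.SeedSequence([ecfg.seed, k, key_id]))
                    primary_cache[pkey] = _train_fold_primary(
                        train_records, v["task"], v["augment"], v["oversample"],
                        pspec, tcfg, rng, threshold=oversample_threshold, eta=eta,
                        lesion_weight=lesion_weight, eta_decay=eta_decay)
                primary = primary_cache[pkey]
                if v["two_stage"]:
                    if secondary_net is None:
                        rng = np.random.default_rng(np.random.SeedSequence([ecfg.seed, k, 99]))
                        secondary_net, _ = train_secondary(_training_rois(train_records),
                                                           sspec, scfg, rng=rng, eta=seta)
                    secondary = secondary_net

                    def predictor(rec, primary=primary, secondary=secondary):
                        return run_inference(rec.pair, primary, secondary, connectivity=ecfg.connectivity)
                else:
                    predictor = _primary_only_predictor(primary, v["task"], ecfg)
                d, p, c = _evaluate_fold(predictor, test_records, ecfg)
                results[variant]["dice"].append(d)
                results[variant]["det"].append(p)
                results[variant]["cls"].append(c)

    out: dict[str, EvalResult] = {}
    rows = []
    for variant in variants:
        r = results[variant]
        res = EvalResult(
            fold_dice=np.array(r["dice"]),
            fold_detection_precision=np.array(r["det"]),
            fold_classification_precision=np.array(r["cls"]),
            variant=variant,
        )
        out[variant] = res
        rows.append(res.as_row())
    table = pd.DataFrame(rows, columns=["variant", "dice", "detection_precision",
                                        "classification_precision"])
    return out, table
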