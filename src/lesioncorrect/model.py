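"""High-level modelling interface for the segmentation-correction cascade.

Follows the model/results idiom: :class:`SegmentationCorrectionModel` is
built from a dataset (a list of phantom or loaded records) plus
specifications, ``fit()`` trains both stages and returns a
:class:`SegmentationCorrectionResults` carrying the trained networks, loss
histories and diagnostics, with ``predict`` / ``evaluate`` / ``summary``
methods. ``cross_validate`` runs the five-fold patient-level protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .evaluation import (
    EvalConfig,
    EvalResult,
    _evaluate_fold,
    _schedule_for,
    _training_rois,
    five_fold_cv,
    make_train_fn,
)
from .networks import PrimaryNetSpec, SecondaryNetSpec
from .phantom import PhantomConfig, PhantomRecord, generate_dataset
from .pipeline import run_inference
from .training import TrainConfig, train_primary, train_secondary

__all__ = ["SegmentationCorrectionModel", "SegmentationCorrectionResults"]


class SegmentationCorrectionModel:
    """Two-stage lesion segmentation-correction model over a slice dataset.

    Parameters
    ----------
    records
        The dataset: records with ``.pair`` (T2/T1 slice pair), ``.mask``
        (ground-truth labels) and ``.instances``.
    primary_spec, secondary_spec
        Network architectures; defaults are the full-size presets.
    train_config, secondary_config
        Training loop settings for each stage (the secondary defaults to the
        primary's settings).
    """

    def __init__(self, records: list[PhantomRecord],
                 primary_spec: PrimaryNetSpec | None = None,
                 secondary_spec: SecondaryNetSpec | None = None,
                 train_config: TrainConfig | None = None,
                 secondary_config: TrainConfig | None = None,
                 oversample_threshold: int = 5):
        if not records:
            raise ValueError("empty dataset")
        self.records = list(records)
        size = records[0].pair.t2.shape[0]
        self.primary_spec = primary_spec or PrimaryNetSpec(input_size=size)
        self.secondary_spec = secondary_spec or SecondaryNetSpec()
        self.train_config = train_config or TrainConfig()
        self.secondary_config = secondary_config or self.train_config
        self.oversample_threshold = oversample_threshold

    @classmethod
    def from_phantom(cls, config: PhantomConfig | None = None, n_patients: int = 20,
                     slices_per_patient: int = 3, seed: int = 0, **kwargs):
        """Build the model over a freshly generated phantom cohort."""
        cfg = config or PhantomConfig(seed=seed)
        records = generate_dataset(cfg, n_patients, slices_per_patient,
                                   rng=np.random.default_rng(seed))
        return cls(records, **kwargs)

    def fit(self, oversample: bool = True, lesion_weight: float = 1.0,
            eta: float = 0.01, eta_secondary: float | None = None,
            eta_decay: float = 1.0,
            seed: int | None = None) -> "SegmentationCorrectionResults":
        """Train both stages on the full dataset and return results.

        ``oversample`` enables the two-phase schedule (pre-training on slices
        with many lesions); ``lesion_weight`` optionally up-weights lesion
        pixels in the segmentation loss (1.0 = unweighted).
        """
        rng_seed = self.train_config.seed if seed is None else seed
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
        sched, cfg = _schedule_for(self.records, oversample, self.oversample_threshold,
                                   self.train_config)
        weights = None if lesion_weight == 1.0 else (1.0,) + (lesion_weight,) * (self.primary_spec.n_classes - 1)
        primary, phist = train_primary(self.records, sched, self.primary_spec, cfg,
                                       rng=rng, eta=eta, class_weights=weights,
                                       eta_decay=eta_decay)
        rng2 = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
        secondary, shist = train_secondary(
            _training_rois(self.records), self.secondary_spec, self.secondary_config,
            rng=rng2, eta=eta if eta_secondary is None else eta_secondary)
        return SegmentationCorrectionResults(self, primary, secondary, phist, shist)

    def cross_validate(self, variant: str = "two_stage_oversample",
                       eval_config: EvalConfig | None = None,
                       lesion_weight: float = 1.0,
                       eta: float = 0.01, eta_secondary: float | None = None,
                       eta_decay: float = 1.0) -> EvalResult:
        """Five-fold patient-level cross-validation of a training variant."""
        ecfg = eval_config or EvalConfig(seed=self.train_config.seed)
        train_fn = make_train_fn(
            variant, primary_spec=self.primary_spec, secondary_spec=self.secondary_spec,
            train_cfg=self.train_config, secondary_cfg=self.secondary_config,
            eval_cfg=ecfg, oversample_threshold=self.oversample_threshold,
            eta=eta, eta_secondary=eta_secondary, lesion_weight=lesion_weight,
            eta_decay=eta_decay)
        return five_fold_cv(self.records, train_fn, ecfg, variant=variant)


@dataclass
class SegmentationCorrectionResults:
    """Fitted cascade: trained networks, loss histories, evaluation helpers."""

    model: SegmentationCorrectionModel
    primary: object
    secondary: object
    primary_history: dict
    secondary_history: dict

    def predict(self, pair, cls_threshold: float = 0.5):
        """Run the cascade on one slice pair -> (SemanticMask, instances)."""
        return run_inference(pair, self.primary, self.secondary, cls_threshold=cls_threshold)

    def evaluate(self, records: list[PhantomRecord] | None = None,
                 eval_config: EvalConfig | None = None) -> tuple[float, float, float]:
        """(dice, detection precision, classification precision) on records.

        Defaults to the training records — an in-sample diagnostic, not a
        generalization estimate; use ``cross_validate`` for that.
        """
        recs = records if records is not None else self.model.records
        cfg = eval_config or EvalConfig()
        return _evaluate_fold(lambda r: self.predict(r.pair), recs, cfg)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.model
        d, p, c = self.evaluate()
        lines = [
            "Segmentation-Correction Cascade Results",
            "=" * 47,
            f"slices: {len(m.records):>5d}   patients: {len({r.pair.patient_id for r in m.records}):>4d}",
            f"primary:   U-Net depth {m.primary_spec.depth}, base {m.primary_spec.base_channels}, "
            f"{m.primary_spec.n_classes} classes ({self.primary.n_parameters():,d} params)",
            f"secondary: 5-conv CNN, base {m.secondary_spec.base_channels}, "
            f"{m.secondary_spec.head} head ({self.secondary.n_parameters():,d} params)",
            f"primary epochs run: {len(self.primary_history['loss'])} "
            f"(final loss {self.primary_history['loss'][-1]:.4f})",
            f"secondary epochs run: {len(self.secondary_history['loss'])} "
            f"(final loss {self.secondary_history['loss'][-1]:.4f})",
            "-" * 47,
            "in-sample (training) metrics:",
            f"  dice coefficient:         {d:8.4f}",
            f"  detection precision:      {p:8.4f}",
            f"  classification precision: {c:8.4f}",
            "=" * 47,
        ]
        return "\n".join(lines)
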