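"""The standard seeded phantom benchmark for the cascade.

Defines one fixed set of study conditions — a 20-patient, 128x128 phantom
cohort with the clinical patient-type proportions, small CPU-scale network
presets, and the two-phase oversampled training recipe — and evaluates a set
of experiment variants on identical five-fold patient-level splits.

Everything here is ordinary library code wired together; the point of the
module is that every caller (CLI, scripts, tests) measures the same
conditions.
"""

from __future__ import annotations

import numpy as np

from .evaluation import EvalConfig, EvalResult, run_ablation
from .networks import PrimaryNetSpec, SecondaryNetSpec
from .phantom import PhantomConfig, generate_dataset
from .training import TrainConfig

__all__ = ["cohort_patient_types", "run_phantom_benchmark", "DEFAULT_VARIANTS"]

#: the variants the benchmark reports by default: the full two-stage cascade
#: with oversampling, its one-stage 3-class counterpart, and the primary-only
#: binary network with and without oversampling.
DEFAULT_VARIANTS = [
    "two_stage_oversample",
    "primary_a_oversample",
    "primary_b_oversample",
    "primary_b",
]


def cohort_patient_types(n_patients: int, n_folds: int = 5) -> list[str]:
    """Patient-type quotas proportional to the 113-patient clinical cohort.

    Rounds 37/113 healthy and 30/113 LACI (remainder FCI), then guarantees at
    least ``n_folds`` LACI patients so that every cross-validation training
    fold contains both lesion classes.
    """
    healthy = round(n_patients * 37 / 113)
    laci = max(n_folds, round(n_patients * 30 / 113))
    fci = n_patients - healthy - laci
    if fci < 1:
        raise ValueError("n_patients too small for the cohort quotas")
    return ["healthy"] * healthy + ["fci"] * fci + ["laci"] * laci


def run_phantom_benchmark(seed: int, n_patients: int = 20, slices_per_patient: int = 3,
                          image_size: int = 128, variants: list[str] | None = None,
                          noise_sd: float = 0.02):
    """Generate the benchmark cohort and cross-validate the variants on it.

    Returns ``(results, table)`` as from
    :func:`lesioncorrect.evaluation.run_ablation`: a dict of per-variant
    :class:`EvalResult` and a tidy summary DataFrame. All randomness —
    phantom generation, fold assignment, weight initialization, batch order,
    dropout — derives from ``seed``.
    """
    variants = list(DEFAULT_VARIANTS if variants is None else variants)
    phantom_cfg = PhantomConfig(image_size=image_size, noise_sd=noise_sd, seed=seed)
    ss = np.random.SeedSequence([seed, 0])
    records = generate_dataset(
        phantom_cfg, n_patients, slices_per_patient,
        rng=np.random.default_rng(ss),
        patient_types=cohort_patient_types(n_patients),
    )
    primary_spec = PrimaryNetSpec(depth=3, base_channels=4, n_classes=2, input_size=image_size)
    # fully-connected head: the ROI's discriminative signal sits at the patch
    # centre, which global average pooling dilutes; the fc head trains
    # reliably on small ROI sets where the conv head does not
    secondary_spec = SecondaryNetSpec(base_channels=8, head="fc")
    train_cfg = TrainConfig(epochs_phase1=6, epochs_phase2=12, batch_size=4,
                            convergence_patience=5, seed=seed)
    secondary_cfg = TrainConfig(epochs_phase1=0, epochs_phase2=20, batch_size=16, seed=seed)
    eval_cfg = EvalConfig(iou_threshold=0.6, n_folds=5, split_unit="patient", seed=seed)
    return run_ablation(
        records, variants,
        primary_spec=primary_spec, secondary_spec=secondary_spec,
        train_cfg=train_cfg, secondary_cfg=secondary_cfg, eval_cfg=eval_cfg,
        eta=0.01, eta_secondary=0.003, lesion_weight=8.0, eta_decay=0.9,
    )
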