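"""Loss, RMSProp optimization, and the two-phase training loops.

The optimizer keeps a per-weight exponential moving average of the squared
gradient,

    E[g^2]_t = alpha * E[g^2]_{t-1} + (1 - alpha) * g_t^2
    W_{t+1}  = W_t - eta / sqrt(E[g^2]_t + eps) * g_t

with alpha = 0.9, base learning rate eta = 0.01 and a small eps guarding the
division. Both networks train on cross-entropy. The primary network uses a
two-phase schedule: pre-training on lesion-rich slices (oversampling) until
convergence, then training on all slices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import PrimaryNetSpec, RoiClassifier, SecondaryNetSpec, UNet
from .phantom import LACI
from .preprocess import OversampleSchedule, ROIPatch

__all__ = [
    "OptimizerState",
    "TrainConfig",
    "rmsprop_update",
    "RMSProp",
    "cross_entropy_loss",
    "train_primary",
    "train_secondary",
]


@dataclass
class OptimizerState:
    """Per-weight RMSProp accumulator and hyper-parameters."""

    mean_sq_grad: np.ndarray
    alpha: float = 0.9
    eta: float = 0.01
    epsilon: float = 1e-8

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if np.any(np.asarray(self.mean_sq_grad) < 0):
            raise ValueError("mean_sq_grad must be nonnegative")


def rmsprop_update(weights: np.ndarray, grad: np.ndarray,
                   state: OptimizerState) -> tuple[np.ndarray, OptimizerState]:
    """One RMSProp step; returns new weights and the updated state.

    The step uses the *new* accumulator: the squared-gradient average is
    updated first, then the weights move by ``eta / sqrt(E[g^2] + eps) * g``
    elementwise.
    """
    weights = np.asarray(weights, dtype=np.float64)
    grad = np.asarray(grad, dtype=np.float64)
    if weights.shape != grad.shape or np.shape(state.mean_sq_grad) != weights.shape:
        raise ValueError("weights, grad and state.mean_sq_grad must share a shape")
    if not np.all(np.isfinite(grad)):
        raise ValueError("non-finite gradient")
    state.validate()
    new_ms = state.alpha * np.asarray(state.mean_sq_grad, dtype=np.float64) + (1.0 - state.alpha) * grad ** 2
    new_w = weights - state.eta / np.sqrt(new_ms + state.epsilon) * grad
    return new_w, OptimizerState(mean_sq_grad=new_ms, alpha=state.alpha,
                                 eta=state.eta, epsilon=state.epsilon)


class RMSProp:
    """Applies :func:`rmsprop_update` to every parameter of a network."""

    def __init__(self, params, alpha: float = 0.9, eta: float = 0.01, epsilon: float = 1e-8):
        self.params = list(params)
        self.states = [
            OptimizerState(mean_sq_grad=np.zeros_like(p.value, dtype=np.float64),
                           alpha=alpha, eta=eta, epsilon=epsilon)
            for p in self.params
        ]

    def step(self) -> None:
        for p, st in zip(self.params, self.states):
            new_w, new_st = rmsprop_update(p.value, p.grad, st)
            p.value = new_w.astype(np.float32)
            st.mean_sq_grad = new_st.mean_sq_grad

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def cross_entropy_loss(predicted_probs: np.ndarray, true_labels: np.ndarray,
                       class_weights=None, tol: float = 1e-3) -> float:
    """Mean negative log-probability of the true class.

    ``predicted_probs`` carries classes on the last axis and must be
    normalized (sum to 1 within ``tol``); ``true_labels`` holds integer class
    indices with matching leading shape. Optional ``class_weights`` (one per
    class) weight the per-sample terms. Zero iff every true class receives
    probability 1.
    """
    probs = np.asarray(predicted_probs, dtype=np.float64)
    labels = np.asarray(true_labels)
    if probs.shape[:-1] != labels.shape:
        raise ValueError("probs and labels shapes are inconsistent")
    k = probs.shape[-1]
    if not np.issubdtype(labels.dtype, np.integer) or labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must be integers in [0, {k})")
    sums = probs.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > tol) or probs.min() < 0:
        raise ValueError("predicted_probs are not normalized probabilities")
    p_true = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    nll = -np.log(np.maximum(p_true, 1e-300))
    if class_weights is None:
        return float(nll.mean())
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape != (k,):
        raise ValueError("class_weights must have one entry per class")
    wl = w[labels]
    return float((wl * nll).sum() / wl.sum())


@dataclass
class TrainConfig:
    """Training-loop configuration for either network.

    Phase 1 is the oversampled pre-training pass on lesion-rich slices;
    "converged" there means no training-loss improvement greater than 1e-4
    for ``convergence_patience`` consecutive epochs.
    """

    epochs_phase1: int = 50
    epochs_phase2: int = 50
    batch_size: int = 8
    convergence_patience: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.epochs_phase1 < 0 or self.epochs_phase2 < 1:
            raise ValueError("epochs_phase1 must be >= 0 and epochs_phase2 >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.convergence_patience < 1:
            raise ValueError("convergence_patience must be positive")


_CONVERGENCE_DELTA = 1e-4


def recalibrate_batchnorm(net, images: np.ndarray, batch_size: int = 8) -> None:
    """Reset batch-norm running statistics to training-set population estimates.

    Running averages kept during optimization lag the final weights, which can
    make evaluation-mode normalization inconsistent with what the network
    learned. One pass over the training images in batch-statistics mode (with
    dropout disabled) replaces the running mean/variance with the cumulative
    average of the per-batch statistics.
    """
    bns = net._batchnorms()
    dropouts = net._dropouts() if hasattr(net, "_dropouts") else []
    saved_rates = [d.rate for d in dropouts]
    saved_momenta = [bn.momentum for bn in bns]
    try:
        for d in dropouts:
            d.rate = 0.0
        n = images.shape[0]
        for k, start in enumerate(range(0, n, batch_size)):
            m = k / (k + 1.0)  # cumulative moving average of batch statistics
            for bn in bns:
                bn.momentum = m
            net.forward_logits(images[start:start + batch_size], train=True)
    finally:
        for bn, m in zip(bns, saved_momenta):
            bn.momentum = m
        for d, r in zip(dropouts, saved_rates):
            d.rate = r


def _softmax_ce_grad(logits: np.ndarray, labels: np.ndarray, class_weights=None):
    """Fused softmax + cross-entropy: (loss, d loss / d logits).

    ``logits``: (N, K, H, W); ``labels``: (N, H, W) ints.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    n, k = logits.shape[0], logits.shape[1]
    onehot = np.moveaxis(np.eye(k, dtype=np.float32)[labels], -1, 1)
    p_true = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
    nll = -np.log(np.maximum(p_true, 1e-30))
    if class_weights is None:
        weights = np.ones_like(nll)
    else:
        weights = np.asarray(class_weights, dtype=np.float32)[labels]
    total = weights.sum()
    loss = float((weights * nll).sum() / total)
    grad = (probs - onehot) * weights[:, None] / total
    return loss, grad.astype(np.float32)


def _epoch_batches(indices: np.ndarray, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(indices)
    for i in range(0, len(order), batch_size):
        yield order[i:i + batch_size]


def _segmentation_targets(records, n_classes: int):
    t2 = np.stack([r.pair.t2 for r in records]).astype(np.float32)[:, None]
    if n_classes == 2:
        labels = np.stack([r.mask.binary.astype(np.int64) for r in records])
    else:
        labels = np.stack([r.mask.labels.astype(np.int64) for r in records])
    return t2, labels


def train_primary(records, schedule: OversampleSchedule, spec: PrimaryNetSpec,
                  cfg: TrainConfig, rng: np.random.Generator | None = None,
                  eta: float = 0.01, class_weights=None,
                  eta_decay: float = 1.0) -> tuple[UNet, dict]:
    """Train the segmentation network with the two-phase oversampling schedule.

    Phase 1 iterates over ``schedule.phase1_indices`` until the convergence
    patience rule fires or ``epochs_phase1`` is exhausted; phase 2 continues
    on ``phase2_indices`` for ``epochs_phase2`` epochs. ``eta`` is the base
    learning rate; ``eta_decay`` optionally multiplies it after every phase-2
    epoch (1.0 = constant), letting late epochs fine-tune with smaller steps.
    Returns the trained network and a history dict with per-epoch losses and
    phase tags. Fully reproducible from the generator/seed.
    """
    cfg.validate()
    if not records:
        raise ValueError("training set is empty")
    if max(schedule.phase2_indices, default=-1) >= len(records):
        raise ValueError("schedule indexes past the end of the training set")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    net = UNet(spec, rng=rng)
    opt = RMSProp(net.params(), eta=eta)
    images, labels = _segmentation_targets(records, spec.n_classes)

    history = {"loss": [], "phase": []}
    segments = [
        (np.asarray(schedule.phase1_indices, dtype=int), cfg.epochs_phase1, cfg.convergence_patience, 1),
        (np.asarray(schedule.phase2_indices, dtype=int), cfg.epochs_phase2, None, 2),
    ]
    for indices, max_epochs, patience, phase in segments:
        if max_epochs == 0 or len(indices) == 0:
            continue
        best = np.inf
        stall = 0
        for _ in range(max_epochs):
            losses = []
            for batch in _epoch_batches(indices, cfg.batch_size, rng):
                opt.zero_grad()
                logits = net.forward_logits(images[batch], train=True)
                loss, grad = _softmax_ce_grad(logits, labels[batch], class_weights)
                net.backward(grad)
                opt.step()
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            history["loss"].append(epoch_loss)
            history["phase"].append(phase)
            if phase == 2 and eta_decay != 1.0:
                for st in opt.states:
                    st.eta *= eta_decay
            if patience is not None:
                if epoch_loss < best - _CONVERGENCE_DELTA:
                    best = epoch_loss
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
    recalibrate_batchnorm(net, images[np.asarray(schedule.phase2_indices, dtype=int)],
                          cfg.batch_size)
    return net, history


def train_secondary(roi_set: list[ROIPatch], spec: SecondaryNetSpec, cfg: TrainConfig,
                    rng: np.random.Generator | None = None, eta: float = 0.01) -> tuple[RoiClassifier, dict]:
    """Train the ROI classifier on labelled patches (binary cross-entropy on P(LACI)).

    ``roi_set`` must contain both classes. Runs ``epochs_phase2`` single-phase
    epochs. Returns the trained classifier and its loss history.
    """
    cfg.validate()
    labels = np.array([1.0 if r.true_class == LACI else 0.0 for r in roi_set], dtype=np.float32)
    if len(roi_set) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("secondary training needs ROIs of both classes")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    net = RoiClassifier(spec, rng=rng)
    opt = RMSProp(net.params(), eta=eta)
    images = np.stack([r.pixels for r in roi_set]).astype(np.float32)[:, None]

    history = {"loss": []}
    all_idx = np.arange(len(roi_set))
    for _ in range(cfg.epochs_phase2):
        losses = []
        for batch in _epoch_batches(all_idx, cfg.batch_size, rng):
            opt.zero_grad()
            z = net.forward_logits(images[batch], train=True)
            p = 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable sigmoid
            y = labels[batch]
            loss = float(-np.mean(y * np.log(np.maximum(p, 1e-30))
                                  + (1 - y) * np.log(np.maximum(1 - p, 1e-30))))
            net.backward((p - y) / len(batch))
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
    recalibrate_batchnorm(net, images, cfg.batch_size)
    return net, history
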