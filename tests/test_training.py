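"""RMSProp oracle agreement, loss properties, and the two-phase loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesioncorrect.networks import PrimaryNetSpec, SecondaryNetSpec
from lesioncorrect.phantom import FCI, LACI, PhantomConfig, generate_dataset
from lesioncorrect.preprocess import OversampleSchedule, build_oversample_schedule
from lesioncorrect.training import (
    OptimizerState,
    TrainConfig,
    cross_entropy_loss,
    rmsprop_update,
    train_primary,
    train_secondary,
)
from lesioncorrect.evaluation import _training_rois


def rmsprop_oracle(w0, grads, alpha, eta, eps):
    """Independent scalar recurrence for the optimizer update."""
    w, ms = w0, 0.0
    trace = []
    for g in grads:
        ms = alpha * ms + (1 - alpha) * g * g
        w = w - eta / np.sqrt(ms + eps) * g
        trace.append((w, ms))
    return trace


class TestRmspropUpdate:
    def test_hand_computed_single_step(self):
        """W=0, E=0, g=1: E' = 0.1 and W' = -0.01/sqrt(0.1 + 1e-8)."""
        state = OptimizerState(mean_sq_grad=np.zeros(()))
        w, s = rmsprop_update(np.zeros(()), np.ones(()), state)
        assert s.mean_sq_grad == pytest.approx(0.1, abs=1e-15)
        assert w == pytest.approx(-0.0316228, abs=1e-6)

    def test_zero_gradient_leaves_weights(self):
        state = OptimizerState(mean_sq_grad=np.full((3,), 0.4))
        w0 = np.array([1.0, -2.0, 0.5])
        w, s = rmsprop_update(w0, np.zeros(3), state)
        assert np.array_equal(w, w0)
        assert np.allclose(s.mean_sq_grad, 0.9 * 0.4)

    def test_matches_scalar_recurrence_oracle_100_steps(self):
        """100 random scalar steps agree with the brute-force recurrence to 1e-12."""
        rng = np.random.default_rng(0)
        grads = rng.normal(size=100)
        trace = rmsprop_oracle(0.3, grads, 0.9, 0.01, 1e-8)
        w = np.asarray(0.3)
        state = OptimizerState(mean_sq_grad=np.zeros(()))
        for g, (w_exp, ms_exp) in zip(grads, trace):
            w, state = rmsprop_update(w, np.asarray(g), state)
            assert abs(float(w) - w_exp) < 1e-12
            assert abs(float(state.mean_sq_grad) - ms_exp) < 1e-12

    def test_constant_gradient_accumulator_limit(self):
        """With constant g the accumulator converges geometrically to g^2."""
        g = np.asarray(0.7)
        w = np.asarray(0.0)
        state = OptimizerState(mean_sq_grad=np.zeros(()))
        for _ in range(400):
            w, state = rmsprop_update(w, g, state)
        assert float(state.mean_sq_grad) == pytest.approx(0.49, rel=1e-9)

    def test_shape_mismatch_and_nonfinite_rejected(self):
        state = OptimizerState(mean_sq_grad=np.zeros(3))
        with pytest.raises(ValueError):
            rmsprop_update(np.zeros(2), np.zeros(3), state)
        with pytest.raises(ValueError):
            rmsprop_update(np.zeros(3), np.array([1.0, np.nan, 0.0]), state)


class TestCrossEntropyLoss:
    def test_perfect_prediction_zero_loss(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert cross_entropy_loss(probs, np.array([0, 1])) == 0.0

    def test_uniform_two_and_three_class(self):
        assert cross_entropy_loss(np.full((4, 2), 0.5), np.zeros(4, dtype=int)) == \
            pytest.approx(np.log(2))
        assert cross_entropy_loss(np.full((4, 3), 1 / 3), np.ones(4, dtype=int)) == \
            pytest.approx(np.log(3))

    def test_rejects_unnormalized_and_bad_labels(self):
        with pytest.raises(ValueError, match="normalized"):
            cross_entropy_loss(np.array([[0.9, 0.3]]), np.array([0]))
        with pytest.raises(ValueError, match="labels"):
            cross_entropy_loss(np.array([[0.5, 0.5]]), np.array([2]))

    @settings(max_examples=40, deadline=None)
    @given(p=st.floats(0.05, 0.90), delta=st.floats(0.01, 0.09))
    def test_monotone_in_true_class_probability(self, p, delta):
        """More probability on the true class never increases the loss."""
        lo = cross_entropy_loss(np.array([[p, 1 - p]]), np.array([0]))
        hi = cross_entropy_loss(np.array([[p + delta, 1 - p - delta]]), np.array([0]))
        assert hi < lo

    def test_class_weighting(self):
        probs = np.array([[0.5, 0.5], [0.5, 0.5]])
        labels = np.array([0, 1])
        w = cross_entropy_loss(probs, labels, class_weights=(1.0, 3.0))
        assert w == pytest.approx(np.log(2))  # symmetric probs: weights cancel


def _toy_records():
    cfg = PhantomConfig(image_size=32, lesion_count_range=(6, 8),
                        lesion_radius_range=(1, 2), noise_sd=0.0)
    types = ["fci"] * 4 + ["laci"] * 2
    return generate_dataset(cfg, 6, 1, rng=9, patient_types=types, healthy_fraction=0)


class TestTrainPrimary:
    SPEC = PrimaryNetSpec(depth=2, base_channels=4, n_classes=2, input_size=32)

    def test_seeded_reproducibility(self):
        recs = _toy_records()
        sched = build_oversample_schedule([len(r.instances) for r in recs], 5)
        cfg = TrainConfig(epochs_phase1=1, epochs_phase2=2, batch_size=3, seed=5)
        n1, h1 = train_primary(recs, sched, self.SPEC, cfg)
        n2, h2 = train_primary(recs, sched, self.SPEC, cfg)
        assert h1["loss"] == h2["loss"]
        for a, b in zip(n1.params(), n2.params()):
            assert np.array_equal(a.value, b.value)

    def test_two_phase_equals_single_phase_when_sets_coincide(self):
        """phase1 == phase2 with summed epochs reproduces one-phase training."""
        recs = _toy_records()
        all_idx = tuple(range(len(recs)))
        sched_two = OversampleSchedule(all_idx, all_idx, 5)
        cfg_two = TrainConfig(epochs_phase1=2, epochs_phase2=2, batch_size=3,
                              convergence_patience=50, seed=1)
        cfg_one = TrainConfig(epochs_phase1=0, epochs_phase2=4, batch_size=3,
                              convergence_patience=50, seed=1)
        _, h_two = train_primary(recs, sched_two, self.SPEC, cfg_two)
        _, h_one = train_primary(recs, sched_two, self.SPEC, cfg_one)
        assert h_two["loss"] == h_one["loss"]

    def test_pure_single_phase_when_phase1_zero_epochs(self):
        recs = _toy_records()
        sched = build_oversample_schedule([len(r.instances) for r in recs], 5)
        cfg = TrainConfig(epochs_phase1=0, epochs_phase2=2, batch_size=3, seed=2)
        _, hist = train_primary(recs, sched, self.SPEC, cfg)
        assert set(hist["phase"]) == {2}

    def test_learns_separable_phantoms(self):
        """Weighted training on noise-free separable slices reaches Dice > 0.9."""
        from lesioncorrect.evaluation import dice_coefficient

        recs = _toy_records()
        sched = build_oversample_schedule([len(r.instances) for r in recs], 5)
        cfg = TrainConfig(epochs_phase1=5, epochs_phase2=25, batch_size=3,
                          convergence_patience=50, seed=3)
        net, hist = train_primary(recs, sched, self.SPEC, cfg,
                                  class_weights=(1.0, 8.0))
        dices = []
        for r in recs:
            pred = net.predict_proba(r.pair.t2[None, None])[0].argmax(axis=0) > 0
            dices.append(dice_coefficient(pred, r.mask.binary))
        assert np.mean(dices) > 0.9

    def test_empty_training_set_raises(self):
        sched = OversampleSchedule((), (), 5)
        with pytest.raises(ValueError, match="empty"):
            train_primary([], sched, self.SPEC, TrainConfig())


class TestTrainSecondary:
    SPEC = SecondaryNetSpec(base_channels=4)

    def test_single_class_rejected(self):
        recs = _toy_records()
        rois = [r for r in _training_rois(recs) if r.true_class == FCI]
        with pytest.raises(ValueError, match="both classes"):
            train_secondary(rois, self.SPEC, TrainConfig())

    def test_seeded_reproducibility(self):
        rois = _training_rois(_toy_records())
        cfg = TrainConfig(epochs_phase2=2, batch_size=8, seed=4)
        n1, h1 = train_secondary(rois, self.SPEC, cfg)
        n2, h2 = train_secondary(rois, self.SPEC, cfg)
        assert h1["loss"] == h2["loss"]
        for a, b in zip(n1.params(), n2.params()):
            assert np.array_equal(a.value, b.value)

    def test_learns_separable_rois(self):
        """Noise-free T1 ROIs (LACI dark vs FCI isointense) reach accuracy > 0.95."""
        rois = _training_rois(_toy_records())
        cfg = TrainConfig(epochs_phase2=20, batch_size=8, seed=6)
        spec = SecondaryNetSpec(base_channels=4, head="fc")
        net, _ = train_secondary(rois, spec, cfg, eta=0.003)
        X = np.stack([r.pixels for r in rois])[:, None]
        y = np.array([r.true_class == LACI for r in rois])
        acc = float(((net.predict_proba(X) > 0.5) == y).mean())
        assert acc > 0.95
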