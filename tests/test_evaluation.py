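"""Metric oracles, greedy matching vs exhaustive assignment, CV partitioning."""

import itertools

import numpy as np
import pytest

from lesioncorrect.evaluation import (
    EvalConfig,
    EvalResult,
    classification_precision,
    detection_precision,
    dice_coefficient,
    five_fold_cv,
    instance_iou,
    match_detections,
    run_ablation,
    _fold_split,
)
from lesioncorrect.phantom import FCI, LACI
from lesioncorrect.pipeline import LesionInstance, SemanticMask, extract_components


def make_instance(pixels, cls=None, true_cls=None):
    px = np.array(sorted(pixels))
    return LesionInstance(
        pixels=px,
        centroid=(float(px[:, 0].mean()), float(px[:, 1].mean())),
        bbox=(int(px[:, 0].min()), int(px[:, 1].min()),
              int(px[:, 0].max()), int(px[:, 1].max())),
        predicted_class=cls,
        true_class=true_cls,
    )


def square(r0, c0, side):
    return [(r, c) for r in range(r0, r0 + side) for c in range(c0, c0 + side)]


class TestDice:
    def test_identical_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:4, 2:4] = True
        b = np.zeros((8, 8), bool)
        b[5:7, 5:7] = True
        assert dice_coefficient(a, a) == 1.0
        assert dice_coefficient(a, b) == 0.0

    def test_partial_overlap_value(self):
        p = np.zeros((8, 8), bool)
        p[0, 0:4] = True
        t = np.zeros((8, 8), bool)
        t[0, 2:6] = True
        assert dice_coefficient(p, t) == pytest.approx(0.5)  # 2*2/(4+4)

    def test_both_empty_convention(self):
        z = np.zeros((4, 4), bool)
        assert dice_coefficient(z, z) == 1.0

    def test_symmetry_and_iou_identity(self, rng):
        """dice(A,B) == dice(B,A) == 2*IoU/(1+IoU) on random masks."""
        for _ in range(200):
            a = rng.random((10, 10)) < 0.4
            b = rng.random((10, 10)) < 0.4
            d1, d2 = dice_coefficient(a, b), dice_coefficient(b, a)
            assert d1 == d2
            union = np.logical_or(a, b).sum()
            if union:
                iou = np.logical_and(a, b).sum() / union
                assert d1 == pytest.approx(2 * iou / (1 + iou))


class TestInstanceIoU:
    def test_identical_disjoint_offset(self):
        a = make_instance(square(0, 0, 2))
        b = make_instance(square(0, 1, 2))  # shares 2 of 6
        c = make_instance(square(10, 10, 2))
        assert instance_iou(a, a) == 1.0
        assert instance_iou(a, c) == 0.0
        assert instance_iou(a, b) == pytest.approx(1 / 3)

    def test_random_sets_match_enumeration(self, rng):
        for _ in range(200):
            pa = {(int(r), int(c)) for r, c in rng.integers(0, 6, (8, 2))}
            pb = {(int(r), int(c)) for r, c in rng.integers(0, 6, (8, 2))}
            a, b = make_instance(pa), make_instance(pb)
            assert instance_iou(a, b) == pytest.approx(len(pa & pb) / len(pa | pb))

    def test_bbox_mode(self):
        a = make_instance(square(0, 0, 2))
        b = make_instance(square(1, 1, 2))
        # boxes [0,1]x[0,1] and [1,2]x[1,2]: intersection 1, union 7
        assert instance_iou(a, b, mode="bbox") == pytest.approx(1 / 7)


def brute_force_best_matching(preds, trues, thr):
    """Exhaustive optimal one-to-one assignment oracle (small inputs)."""
    best = 0
    idx = range(len(trues))
    for k in range(min(len(preds), len(trues)), 0, -1):
        for psel in itertools.permutations(range(len(preds)), k):
            for tsel in itertools.combinations(idx, k):
                n = sum(
                    instance_iou(preds[p], trues[t]) > thr
                    for p, t in zip(psel, tsel)
                )
                best = max(best, n)
        if best == k:
            break
    return best


class TestMatchDetections:
    def test_perfect_match(self):
        insts = [make_instance(square(0, 0, 2)), make_instance(square(5, 5, 3))]
        m, fp, fn = match_detections(insts, insts)
        assert len(m) == 2 and not fp and not fn

    def test_empty_predictions(self):
        trues = [make_instance(square(0, 0, 2))]
        m, fp, fn = match_detections([], trues)
        assert not m and not fp and fn == trues

    def test_iou_exactly_at_threshold_excluded(self):
        """IoU == 0.6 does not count: the criterion is strictly 'higher than'."""
        # 3x5 vs 3x5 shifted by one column: inter 12, union 18 -> IoU 2/3 > 0.6
        # build IoU exactly 0.6: |A|=|B|=8, overlap 6 -> 6/10 = 0.6
        pa = [(0, c) for c in range(8)]
        pb = [(0, c) for c in range(2, 10)]
        a, b = make_instance(pa), make_instance(pb)
        assert instance_iou(a, b) == pytest.approx(0.6)
        m, fp, fn = match_detections([a], [b], iou_threshold=0.6)
        assert not m and len(fp) == 1 and len(fn) == 1

    def test_one_to_one_with_competing_predictions(self):
        t = make_instance(square(0, 0, 3))
        p1 = make_instance(square(0, 0, 3))
        p2 = make_instance([(r, c) for r, c in square(0, 0, 3) if (r, c) != (2, 2)])
        m, fp, fn = match_detections([p2, p1], [t])
        assert len(m) == 1 and m[0][0] is p1  # higher IoU wins
        assert fp == [p2] and not fn

    def test_order_invariance(self, rng):
        preds = [make_instance(square(0, 0, 3)), make_instance(square(4, 4, 2)),
                 make_instance(square(8, 0, 2))]
        trues = [make_instance(square(0, 1, 3)), make_instance(square(4, 4, 2))]
        ref = match_detections(preds, trues)
        for perm in itertools.permutations(preds):
            m, fp, fn = match_detections(list(perm), trues)
            assert {id(x[0]) for x in m} == {id(x[0]) for x in ref[0]}
            assert len(fp) == len(ref[1]) and len(fn) == len(ref[2])

    def test_greedy_equals_exhaustive_small(self, rng):
        """Greedy matching is optimal for <= 5 instances per side (oracle)."""
        for _ in range(60):
            preds = [make_instance({(int(r), int(c))
                                    for r, c in rng.integers(0, 8, (rng.integers(2, 7), 2))})
                     for _ in range(rng.integers(1, 5))]
            trues = [make_instance({(int(r), int(c))
                                    for r, c in rng.integers(0, 8, (rng.integers(2, 7), 2))})
                     for _ in range(rng.integers(1, 5))]
            m, _, _ = match_detections(preds, trues, iou_threshold=0.3)
            assert len(m) == brute_force_best_matching(preds, trues, 0.3)


class TestPrecision:
    def test_detection_values(self):
        assert detection_precision(3, 1) == pytest.approx(0.75)
        assert detection_precision(5, 0) == 1.0
        assert np.isnan(detection_precision(0, 0))

    def test_classification_values(self):
        def pair(pc, tc):
            return (make_instance([(0, 0)], cls=pc), make_instance([(0, 0)], true_cls=tc))

        allc = [pair(FCI, FCI), pair(LACI, LACI)]
        none = [pair(FCI, LACI), pair(LACI, FCI)]
        assert classification_precision(allc) == 1.0
        assert classification_precision(none) == 0.0
        mixed = [pair(FCI, FCI)] * 13 + [pair(FCI, LACI)]
        assert classification_precision(mixed) == pytest.approx(13 / 14)
        assert np.isnan(classification_precision([]))


class TestFoldSplit:
    def test_partition_ten_patients(self, tiny_dataset):
        cfg = EvalConfig(seed=3)
        folds = _fold_split(tiny_dataset, cfg)
        assert len(folds) == 5
        all_test = [i for _, test in folds for i in test]
        assert sorted(all_test) == list(range(len(tiny_dataset)))  # each slice once
        for train, test in folds:
            pats_tr = {tiny_dataset[i].pair.patient_id for i in train}
            pats_te = {tiny_dataset[i].pair.patient_id for i in test}
            assert not (pats_tr & pats_te)
            assert len(pats_te) == 2

    def test_seeded_reproducible(self, tiny_dataset):
        a = _fold_split(tiny_dataset, EvalConfig(seed=9))
        b = _fold_split(tiny_dataset, EvalConfig(seed=9))
        assert a == b

    def test_too_few_units(self, tiny_dataset):
        with pytest.raises(ValueError, match="at least"):
            _fold_split(tiny_dataset[:4], EvalConfig(n_folds=5, split_unit="slice"))

    def test_fold_mean_excludes_undefined(self):
        res = EvalResult(
            fold_dice=np.array([1, 1, 1, 1, 0.0]),
            fold_detection_precision=np.array([1, 1, np.nan, 1, 1.0]),
            fold_classification_precision=np.array([np.nan] * 5),
        )
        assert res.dice == pytest.approx(0.8)
        assert res.detection_precision == pytest.approx(1.0)
        assert np.isnan(res.classification_precision)


class TestCvAndAblation:
    def _oracle_train_fn(self, train_records, rng):
        """A 'model' that reads off the ground truth — exercises the harness."""

        def predict(rec):
            labels = rec.mask.labels.copy()
            instances = extract_components(labels > 0)
            for inst in instances:
                inst.predicted_class = int(labels[tuple(inst.pixels.T)][0])
            return SemanticMask(labels=labels), instances

        return predict

    def test_oracle_predictor_scores_perfectly(self, tiny_dataset):
        res = five_fold_cv(tiny_dataset, self._oracle_train_fn, EvalConfig(seed=1))
        assert res.dice == 1.0
        assert res.detection_precision == 1.0
        assert res.classification_precision == 1.0

    def test_empty_variant_list(self, tiny_dataset):
        results, table = run_ablation(tiny_dataset, [])
        assert results == {} and len(table) == 0

    def test_unknown_variant_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown"):
            run_ablation(tiny_dataset, ["nonexistent_variant"])

    def test_eval_config_validation(self):
        with pytest.raises(ValueError):
            EvalConfig(iou_threshold=0.0).validate()
        with pytest.raises(ValueError):
            EvalConfig(n_folds=1).validate()
        with pytest.raises(ValueError):
            EvalConfig(split_unit="hospital").validate()
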