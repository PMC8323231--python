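"""Phantom generator: determinism, exact ground truth, contrast semantics."""

import numpy as np
import pytest

from lesioncorrect.phantom import (
    FCI,
    LACI,
    HEALTHY_PATIENT_FRACTION,
    PhantomConfig,
    generate_dataset,
    generate_slice,
)


def _hash_record(pair, mask):
    return (pair.t2.tobytes(), pair.t1.tobytes(), mask.labels.tobytes())


class TestGenerateSlice:
    def test_seeded_determinism(self, small_config):
        a = generate_slice(small_config, rng=123)
        b = generate_slice(small_config, rng=123)
        assert _hash_record(a[0], a[1]) == _hash_record(b[0], b[1])

    def test_zero_lesions(self, small_config):
        cfg = PhantomConfig(image_size=64, lesion_count_range=(0, 0))
        pair, mask, instances = generate_slice(cfg, rng=1)
        assert mask.labels.sum() == 0
        assert instances == []

    def test_disk_areas_match_enumeration(self, noise_free_config):
        """Each planted lesion is exactly the set of pixels within its radius."""
        pair, mask, instances = generate_slice(noise_free_config, rng=5)
        assert len(instances) == 3
        for inst in instances:
            # brute-force oracle: re-derive the disk from the component's own
            # centre/radius and compare pixel sets
            r0 = int(round(inst.centroid[0]))
            c0 = int(round(inst.centroid[1]))
            # radius from area: find r with matching enumerated pixel count
            found = False
            for r in range(1, 6):
                rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
                disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= r ** 2
                if disk.sum() == inst.n_pixels:
                    expected = {(int(a), int(b)) for a, b in zip(*np.nonzero(disk))}
                    assert inst.pixel_set() == expected
                    found = True
                    break
            assert found, "component is not a centred disk of any radius 1..5"

    def test_values_in_unit_interval(self, small_config):
        pair, _, _ = generate_slice(small_config, rng=2)
        for img in (pair.t2, pair.t1):
            assert np.isfinite(img).all()
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_mask_instance_consistency(self, small_config):
        """Instance pixel sets partition the binary foreground exactly."""
        for seed in range(5):
            _, mask, instances = generate_slice(small_config, rng=seed)
            union = set()
            total = 0
            for inst in instances:
                s = inst.pixel_set()
                assert not (union & s), "instances overlap"
                union |= s
                total += len(s)
            fg = {(int(r), int(c)) for r, c in zip(*np.nonzero(mask.binary))}
            assert union == fg and total == len(fg)

    def test_contrast_semantics_noise_free(self):
        """LACI dark on T1, every lesion bright on T2, FCI isointense on T1."""
        cfg = PhantomConfig(image_size=64, lesion_count_range=(4, 4), noise_sd=0.0)
        pair, mask, instances = generate_slice(
            cfg, rng=3, lesion_classes=np.array([FCI, LACI, FCI, LACI]))
        laci_px = mask.labels == LACI
        fci_px = mask.labels == FCI
        assert pair.t1[laci_px].mean() < cfg.brain_level
        assert pair.t2[laci_px | fci_px].min() > cfg.brain_level
        assert np.allclose(pair.t1[fci_px], cfg.t1_fci_level)

    def test_too_dense_raises(self):
        cfg = PhantomConfig(image_size=32, lesion_count_range=(60, 60),
                            lesion_radius_range=(3, 4))
        with pytest.raises(RuntimeError, match="dense"):
            generate_slice(cfg, rng=0)

    @pytest.mark.parametrize("bad", [
        dict(t1_laci_level=0.5),                      # not dark on T1
        dict(t2_lesion_level=0.3),                    # not bright on T2
        dict(t1_fci_level=0.9),                       # not isointense
        dict(lesion_radius_range=(0, 2)),
        dict(lesion_count_range=(4, 1)),
        dict(class_mix=1.5),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomConfig(**bad).validate()


class TestGenerateDataset:
    def test_counts_and_patient_partition(self, small_config):
        recs = generate_dataset(small_config, 10, 4, rng=3)
        assert len(recs) == 40
        assert len({r.pair.patient_id for r in recs}) == 10
        # slice ids unique
        assert len({r.pair.slice_id for r in recs}) == 40

    def test_all_healthy(self, small_config):
        recs = generate_dataset(small_config, 6, 2, healthy_fraction=1.0, rng=0)
        assert all(r.mask.labels.sum() == 0 for r in recs)

    def test_healthy_fraction_binomial(self):
        """Healthy-patient rate matches the cohort proportion at large n."""
        cfg = PhantomConfig(image_size=32, lesion_count_range=(1, 2),
                            lesion_radius_range=(1, 2))
        n = 400
        recs = generate_dataset(cfg, n, 1, rng=99)
        healthy = sum(r.mask.labels.sum() == 0 for r in recs)
        p = HEALTHY_PATIENT_FRACTION
        se = np.sqrt(p * (1 - p) / n)
        # note lesioned patients can also draw slices whose count lands at the
        # low end; count_range starts at 1 so zero-lesion implies healthy here
        assert abs(healthy / n - p) < 4 * se

    def test_patient_types_quota(self, small_config):
        types = ["healthy"] * 2 + ["fci"] * 2 + ["laci"] * 2
        recs = generate_dataset(small_config, 6, 2, rng=1, patient_types=types)
        by_pid = {}
        for r in recs:
            by_pid.setdefault(r.pair.patient_id, []).append(r)
        for p, t in zip(sorted(by_pid), types):
            lesions = sum(len(r.instances) for r in by_pid[p])
            if t == "healthy":
                assert lesions == 0
            else:
                classes = {i.true_class for r in by_pid[p] for i in r.instances}
                if t == "fci":
                    assert classes <= {FCI}

    def test_determinism(self, small_config):
        a = generate_dataset(small_config, 5, 2, rng=42)
        b = generate_dataset(small_config, 5, 2, rng=42)
        assert all(_hash_record(x.pair, x.mask) == _hash_record(y.pair, y.mask)
                   for x, y in zip(a, b))

    def test_too_few_patients(self, small_config):
        with pytest.raises(ValueError, match="at least 5"):
            generate_dataset(small_config, 4, 2, rng=0)
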