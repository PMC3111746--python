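"""The slicewise deviation statistic, volume flagging, and QC removal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sliceqc as sq
from sliceqc.io import ValidationError
from sliceqc.qc import QCConfig, SliceIntensityMatrix

from conftest import (
    brute_force_deviation,
    brute_force_outlier_counts,
    random_unit_vectors,
)


class TestSliceMeans:
    def test_constant_dataset(self, small_scheme):
        data = np.full((5, 5, 4, len(small_scheme)), 7.0)
        ds = sq.DWIDataset(data, np.ones(3), small_scheme)
        assert np.allclose(sq.slice_means(ds).means, 7.0)

    def test_halving_one_slice_halves_one_entry(self, small_scheme):
        rng = np.random.default_rng(0)
        data = 50 + rng.random((4, 4, 4, len(small_scheme)))
        ds = sq.DWIDataset(data, np.ones(3), small_scheme)
        ref = sq.slice_means(ds).means
        data2 = data.copy()
        data2[:, :, 2, 3] *= 0.5
        got = sq.slice_means(sq.DWIDataset(data2, np.ones(3), small_scheme)).means
        expected = ref.copy()
        expected[3, 2] *= 0.5
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_mask_restriction_and_empty_slice(self, small_scheme):
        rng = np.random.default_rng(1)
        data = 50 + rng.random((4, 4, 3, len(small_scheme)))
        ds = sq.DWIDataset(data, np.ones(3), small_scheme)
        mask = np.ones((4, 4, 3), dtype=bool)
        mask[:, :, 1] = False
        means = sq.slice_means(ds, mask).means
        assert np.all(np.isnan(means[:, 1]))
        np.testing.assert_allclose(means[:, 0], data[:, :, 0, :].mean(axis=(0, 1)))

    def test_mask_shape_mismatch(self, small_scheme):
        ds = sq.DWIDataset(np.ones((4, 4, 3, len(small_scheme))), np.ones(3),
                           small_scheme)
        with pytest.raises(ValidationError):
            sq.slice_means(ds, np.ones((5, 4, 3), dtype=bool))


class TestPairDeviation:
    @pytest.mark.parametrize("a, b, expected", [
        (100.0, 100.0, 0.0),
        (150.0, 50.0, 0.5),
        (0.0, 0.0, 0.0),
        (1.0, 0.0, 1.0),
    ])
    def test_known_values(self, a, b, expected):
        assert sq.pair_deviation(a, b) == pytest.approx(expected, abs=1e-15)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            sq.pair_deviation(-1.0, 2.0)

    @given(st.floats(0, 1e6), st.floats(0, 1e6), st.floats(1e-3, 1e3))
    def test_symmetric_bounded_scale_invariant(self, a, b, c):
        d = sq.pair_deviation(a, b)
        assert 0.0 <= d <= 1.0
        assert d == sq.pair_deviation(b, a)
        assert sq.pair_deviation(c * a, c * b) == pytest.approx(d, abs=1e-9)
        if a == b:
            assert d == 0.0


class TestDirectionWeight:
    def test_identical_orthogonal_antipodal(self):
        ex, ey = np.eye(3)[0], np.eye(3)[1]
        assert sq.direction_weight(ex, ex) == pytest.approx(1.0)
        assert sq.direction_weight(ex, ey) == pytest.approx(0.0)
        assert sq.direction_weight(ex, -ex, antipodal=True) == pytest.approx(1.0)
        assert sq.direction_weight(ex, -ex, antipodal=False) == 0.0

    def test_antipodal_matches_signal_symmetry(self, small_phantom_truth):
        """g and −g produce identical diffusion-weighted signals."""
        g = np.array([0.6, 0.64, 0.48])
        g /= np.linalg.norm(g)
        gt_pos = sq.GradientTable(np.stack([g, -g]), np.full(2, 1000.0))
        ds = sq.simulate_signal(small_phantom_truth, gt_pos, snr=None)
        np.testing.assert_allclose(ds.intensities[..., 0], ds.intensities[..., 1],
                                   rtol=1e-12)

    def test_nonunit_rejected(self):
        with pytest.raises(ValidationError):
            sq.direction_weight(np.array([2.0, 0, 0]), np.array([1.0, 0, 0]))


class TestDeviationMatrix:
    def test_identical_volumes_give_zero(self):
        rng = np.random.default_rng(3)
        dirs = random_unit_vectors(5, rng)
        gt = sq.GradientTable(dirs, np.full(5, 1000.0))
        means = np.tile(100 + 10 * rng.random(4), (5, 1))
        dev = sq.deviation_matrix(SliceIntensityMatrix(means), gt,
                                  QCConfig(background_floor=0.0))
        assert np.allclose(dev.delta[dev.evaluated], 0.0)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("normalize", [True, False])
    def test_matches_brute_force_oracle(self, seed, normalize):
        rng = np.random.default_rng(seed)
        V = int(rng.integers(3, 9))
        Z = int(rng.integers(2, 7))
        dirs = random_unit_vectors(V, rng)
        gt = sq.GradientTable(dirs, np.full(V, 1000.0))
        means = 50 + 50 * rng.random((V, Z))
        cfg = QCConfig(background_floor=0.0, normalize_weights=normalize)
        got = sq.deviation_matrix(SliceIntensityMatrix(means), gt, cfg).delta
        want = brute_force_deviation(means, dirs, normalize=normalize)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_attenuated_slice_dominates(self):
        rng = np.random.default_rng(11)
        dirs = random_unit_vectors(6, rng)
        gt = sq.GradientTable(dirs, np.full(6, 1000.0))
        means = 100 + 5 * rng.random((6, 5))
        means[2, 3] *= 0.5
        dev = sq.deviation_matrix(SliceIntensityMatrix(means), gt,
                                  QCConfig(background_floor=0.0))
        d = dev.delta
        assert d[2, 3] == np.nanmax(d)
        others = np.delete(d.ravel(), 2 * 5 + 3)
        assert d[2, 3] > np.nanmax(others)

    def test_scale_invariance(self, toy_dataset):
        cfg = QCConfig(background_floor=0.0)
        dev1 = sq.deviation_matrix(sq.slice_means(toy_dataset),
                                   toy_dataset.gradients, cfg).delta
        scaled = sq.DWIDataset(toy_dataset.intensities * 3.7,
                               toy_dataset.voxel_size, toy_dataset.gradients)
        dev2 = sq.deviation_matrix(sq.slice_means(scaled),
                                   scaled.gradients, cfg).delta
        np.testing.assert_allclose(dev1, dev2, atol=1e-12)

    def test_background_slices_not_evaluated(self):
        rng = np.random.default_rng(5)
        dirs = random_unit_vectors(4, rng)
        gt = sq.GradientTable(dirs, np.full(4, 1000.0))
        means = 100 + rng.random((4, 3))
        means[:, 0] = 0.5  # below the default 5%-of-robust-max floor
        dev = sq.deviation_matrix(SliceIntensityMatrix(means), gt)
        assert np.all(np.isnan(dev.delta[:, 0]))
        assert not np.any(np.isnan(dev.delta[:, 1:]))

    def test_single_volume_rejected(self):
        gt = sq.GradientTable(np.array([[1.0, 0, 0]]), np.array([1000.0]))
        with pytest.raises(ValidationError):
            sq.deviation_matrix(SliceIntensityMatrix(np.ones((1, 3))), gt)

    def test_uniform_weights_for_shared_lowb_direction(self):
        """A low-b shell with one shared direction has no direction
        contrast; all comparisons weight equally."""
        gt = sq.GradientTable(np.tile([0.0, 0.0, 1.0], (4, 1)), np.full(4, 100.0))
        means = np.array([[100.0], [100.0], [100.0], [40.0]])
        dev = sq.deviation_matrix(SliceIntensityMatrix(means), gt,
                                  QCConfig(background_floor=0.0))
        expected = np.mean([sq.pair_deviation(100.0, 40.0)] * 3)
        assert dev.delta[3, 0] == pytest.approx(expected, abs=1e-12)


class TestFlagging:
    def test_clean_empty_and_threshold_rule(self):
        delta = np.zeros((4, 6))
        dev = sq.DeviationMatrix(delta, 3)
        assert sq.flag_volumes(dev, QCConfig(threshold=0.2)) == set()
        delta2 = delta.copy()
        delta2[1, 4] = 0.25
        delta2[1, 5] = 0.30  # two exceeding slices, one volume
        dev2 = sq.DeviationMatrix(delta2, 3)
        assert sq.flag_volumes(dev2, QCConfig(threshold=0.2)) == {1}

    def test_background_never_flags(self):
        delta = np.zeros((3, 4))
        delta[0, 2] = np.nan
        dev = sq.DeviationMatrix(delta, 2)
        assert sq.flag_volumes(dev, QCConfig(threshold=0.2)) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_flag_monotonicity_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        dev = sq.DeviationMatrix(rng.random((8, 6)) * 0.6, 7)
        flags = [sq.flag_volumes(dev, QCConfig(threshold=t))
                 for t in (0.1, 0.2, 0.3, 0.5)]
        for larger, smaller in zip(flags, flags[1:]):
            assert smaller <= larger


class TestVoxelOutlierCounts:
    def test_identical_volumes_count_zero(self, small_scheme):
        data = np.tile(np.random.default_rng(0).random((4, 4, 3))[..., None] * 100,
                       (1, 1, 1, len(small_scheme)))
        ds = sq.DWIDataset(data, np.ones(3), small_scheme)
        assert sq.voxel_outlier_counts(ds).sum() == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        dirs = random_unit_vectors(3, rng)
        gt = sq.GradientTable(dirs, np.full(3, 1000.0))
        data = 100 + 20 * rng.random((2, 2, 2, 3))
        ds = sq.DWIDataset(data, np.ones(3), gt)
        np.testing.assert_array_equal(
            sq.voxel_outlier_counts(ds),
            brute_force_outlier_counts(data, dirs))

    def test_dropout_slice_stands_out(self):
        ds, _, labels = sq.simulate_study_dataset(
            seed=4, snr=30.0, n_high=30, n_low=2, grid_shape=(16, 16, 12),
            artifact_spec=sq.ArtifactSpec([sq.ArtifactEvent(5, 6, 6, 0.3)]))
        _, high = sq.split_by_shell(ds, 500.0)
        counts = sq.voxel_outlier_counts(high)
        clean = np.delete(counts, 5, axis=0)
        assert counts[5, 6] > np.median(clean)

    def test_too_few_volumes_rejected(self):
        gt = sq.GradientTable(np.eye(3)[:2], np.full(2, 1000.0))
        ds = sq.DWIDataset(np.ones((2, 2, 2, 2)), np.ones(3), gt)
        with pytest.raises(ValidationError):
            sq.voxel_outlier_counts(ds)


class TestApplyQC:
    def test_empty_flag_set_is_identity(self, noisefree_small_dataset):
        out = sq.apply_qc(noisefree_small_dataset, set())
        np.testing.assert_array_equal(out.intensities,
                                      noisefree_small_dataset.intensities)

    def test_consistent_removal_bookkeeping(self):
        rng = np.random.default_rng(13)
        gt = sq.default_gradient_scheme(n_high=64, n_low=8)
        data = 100 + rng.random((4, 4, 3, 72))
        ds = sq.DWIDataset(data, np.ones(3), gt)
        flagged = {3, 17, 25, 41, 58}
        out = sq.apply_qc(ds, flagged)
        assert out.n_volumes == 67
        assert set(out.original_indices.tolist()) == set(range(72)) - flagged
        np.testing.assert_array_equal(out.intensities,
                                      data[..., out.original_indices])
        np.testing.assert_array_equal(out.gradients.directions,
                                      gt.directions[out.original_indices])

    def test_overremoval_raises_insufficient_data(self, noisefree_small_dataset):
        n = noisefree_small_dataset.n_volumes
        with pytest.raises(ValidationError, match="insufficient data"):
            sq.apply_qc(noisefree_small_dataset, set(range(n - 4)))


class TestRunQC:
    def test_clean_dataset_flags_nothing(self):
        ds, _, _ = sq.simulate_study_dataset(seed=2, snr=25.0, n_high=30,
                                             n_low=3, grid_shape=(16, 16, 12))
        report = sq.run_qc(ds)
        assert report.flagged_volumes == set()
        assert set(report.deviation) == {"low_b", "high_b"}
        assert report.outlier_counts is not None

    def test_injected_volumes_flagged_exactly(self):
        events = [sq.ArtifactEvent(v, 5, 7, 0.5) for v in (2, 9, 20)]
        ds, _, labels = sq.simulate_study_dataset(
            seed=3, snr=20.0, n_high=30, n_low=3, grid_shape=(16, 16, 12),
            artifact_spec=sq.ArtifactSpec(events))
        report = sq.run_qc(ds)
        assert report.flagged_volumes == labels["corrupted_volumes"]

    def test_lowb_artifact_detected_on_its_own_shell(self):
        events = [sq.ArtifactEvent(31, 4, 6, 0.4)]  # a low-b volume
        ds, _, labels = sq.simulate_study_dataset(
            seed=6, snr=20.0, n_high=30, n_low=4, grid_shape=(16, 16, 12),
            artifact_spec=sq.ArtifactSpec(events))
        report = sq.run_qc(ds)
        assert report.flagged_volumes == {31}

    def test_deterministic_rerun(self):
        ds, _, _ = sq.simulate_study_dataset(seed=5, snr=20.0, n_high=12,
                                             n_low=2, grid_shape=(12, 12, 8))
        r1, r2 = sq.run_qc(ds), sq.run_qc(ds)
        assert r1.flagged_volumes == r2.flagged_volumes
        for label in r1.deviation:
            np.testing.assert_array_equal(r1.deviation[label].delta,
                                          r2.deviation[label].delta)
        np.testing.assert_array_equal(r1.outlier_counts, r2.outlier_counts)
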