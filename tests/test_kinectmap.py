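"""Per-joint affine map fitting, application and alignment evaluation."""

import numpy as np
import pytest

from virafall.core import Convention, SkeletonSequence
from virafall.kinectmap import (
    DEFAULT_CORRESPONDENCE,
    AffineAligner,
    AffineJointMap,
    MapFitReport,
    apply_affine_map,
    evaluate_alignment,
    fit_affine_map,
)
from virafall.synth import GeneratorConfig, generate_paired_samples


def _random_pairs(rng, n=40, maps=None):
    kin = rng.normal(size=(n, 25, 3))
    if maps is None:
        maps = AffineJointMap.identity()
    coco = maps.transform_frames(kin)
    return kin, coco


def _random_maps(rng):
    a = np.stack([np.eye(3) + 0.4 * rng.normal(size=(3, 3)) for _ in range(17)])
    while (np.abs(np.linalg.det(a)) < 0.2).any():
        bad = np.abs(np.linalg.det(a)) < 0.2
        a[bad] = np.eye(3) + 0.4 * rng.normal(size=(int(bad.sum()), 3, 3))
    return AffineJointMap(DEFAULT_CORRESPONDENCE, a, rng.normal(size=(17, 3)))


class TestFit:
    def test_identical_points_give_identity_map_zero_mse(self, rng):
        kin, coco = _random_pairs(rng)
        amap, report = fit_affine_map((kin, coco), n_train=30, seed=0)
        np.testing.assert_allclose(amap.A, np.broadcast_to(np.eye(3), (17, 3, 3)),
                                   atol=1e-9)
        np.testing.assert_allclose(amap.b, 0.0, atol=1e-9)
        assert report.overall_mse < 1e-18

    def test_recovers_known_random_maps_exactly(self, rng):
        true = _random_maps(rng)
        kin, coco = _random_pairs(rng, maps=true)
        amap, report = fit_affine_map((kin, coco), n_train=30, seed=1)
        np.testing.assert_allclose(amap.A, true.A, atol=1e-8)
        np.testing.assert_allclose(amap.b, true.b, atol=1e-8)
        assert report.overall_mse < 1e-12

    def test_pure_translation_recovered(self, rng):
        shift = AffineJointMap.identity()
        shift.b[:] = [1.0, 2.0, 3.0]
        kin, coco = _random_pairs(rng, maps=shift)
        amap, _ = fit_affine_map((kin, coco), n_train=30, seed=2)
        np.testing.assert_allclose(amap.b, np.tile([1.0, 2.0, 3.0], (17, 1)),
                                   atol=1e-9)

    def test_too_few_frames_rejected(self, rng):
        kin, coco = _random_pairs(rng, n=3)
        with pytest.raises(ValueError, match="at least 4"):
            fit_affine_map((kin, coco))

    def test_degenerate_geometry_names_joint(self, rng):
        kin, coco = _random_pairs(rng, n=20)
        kin[:, 3, :] = [1.0, 2.0, 3.0]  # head joint frozen -> affinely degenerate
        with pytest.raises(ValueError, match="nose"):
            fit_affine_map((kin, coco), n_train=20)

    def test_post_fit_error_never_worse_than_identity_baseline(self, rng):
        # least squares contains the identity map in its feasible set
        kin = rng.normal(size=(50, 25, 3))
        coco = AffineJointMap.identity().transform_frames(kin)
        coco += 0.05 * rng.normal(size=coco.shape)
        res = AffineAligner(kin, coco).fit(n_train=50, seed=0)
        assert (
            res.report.euclidean_error_per_joint_after
            <= res.report.euclidean_error_per_joint_before + 1e-12
        ).all()

    def test_overall_mse_is_mean_of_per_joint(self, rng):
        true = _random_maps(rng)
        kin, coco = _random_pairs(rng, maps=true)
        coco += 0.01 * rng.normal(size=coco.shape)
        _, report = fit_affine_map((kin, coco), n_train=30, seed=3)
        assert abs(report.overall_mse - report.mse_per_joint.mean()) <= 1e-12


class TestApply:
    def test_identity_map_selects_correspondence_subset(self, rng):
        seq = SkeletonSequence(
            coords=rng.normal(size=(8, 25, 3)), label=1, convention="KINECT25"
        )
        out = apply_affine_map(seq, AffineJointMap.identity())
        assert out.convention is Convention.COCO17
        np.testing.assert_array_equal(
            out.coords, seq.coords[:, DEFAULT_CORRESPONDENCE, :]
        )
        assert out.label == 1

    def test_zero_frame_maps_to_translation(self, rng):
        maps = _random_maps(rng)
        seq = SkeletonSequence(
            coords=np.zeros((2, 25, 3)), label=0, convention="KINECT25"
        )
        out = apply_affine_map(seq, maps)
        np.testing.assert_allclose(out.coords[0], maps.b, atol=1e-12)

    def test_convention_mismatch_rejected(self, rng):
        seq = SkeletonSequence(
            coords=rng.normal(size=(5, 17, 3)), label=0, convention="COCO17"
        )
        with pytest.raises(ValueError, match="KINECT25"):
            apply_affine_map(seq, AffineJointMap.identity())

    def test_fit_then_apply_rms_matches_sqrt_mse(self, rng):
        true = _random_maps(rng)
        kin, coco = _random_pairs(rng, n=30, maps=true)
        coco += 0.02 * rng.normal(size=coco.shape)
        res = AffineAligner(kin, coco).fit(n_train=30, seed=0)
        pred = res.map_.transform_frames(kin)
        rms = np.sqrt(((pred - coco) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(rms, np.sqrt(res.report.mse_per_joint), atol=1e-9)


class TestEvaluateAlignment:
    def test_equal_inputs_give_zero_error(self, rng):
        frames = rng.normal(size=(20, 17, 3))
        rep = evaluate_alignment(frames, frames.copy())
        np.testing.assert_array_equal(rep.mse_per_joint, 0.0)

    def test_unit_shift_closed_form(self, rng):
        frames = rng.normal(size=(20, 17, 3))
        shifted = frames.copy()
        shifted[:, :, 0] += 1.0
        rep = evaluate_alignment(shifted, frames)
        np.testing.assert_allclose(rep.euclidean_error_per_joint_after, 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(rep.mse_per_joint, 1.0, atol=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        a = rng.normal(size=(6, 17, 3))
        b = rng.normal(size=(6, 17, 3))
        rep = evaluate_alignment(a, b)
        for j in range(17):
            acc = 0.0
            for i in range(6):
                d = a[i, j] - b[i, j]
                acc += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
            assert abs(rep.mse_per_joint[j] - acc / 6) < 1e-12

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate_alignment(rng.normal(size=(5, 17, 3)),
                               rng.normal(size=(6, 17, 3)))


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        maps = _random_maps(rng)
        maps.n_train = 30
        path = tmp_path / "map.json"
        maps.to_json(path)
        back = AffineJointMap.from_json(path)
        np.testing.assert_array_equal(back.A, maps.A)
        np.testing.assert_array_equal(back.b, maps.b)
        assert back.correspondence == maps.correspondence
        assert back.n_train == 30


class TestEndToEndWithGenerator:
    def test_recovery_from_generated_paired_sequences(self):
        cfg = GeneratorConfig(n_sequences=3, frame_len=80, fps=10.0,
                              noise_sd=0.0, seed=21)
        pairs = generate_paired_samples(cfg, "random")
        kin = np.concatenate([p.kinect25.coords for p in pairs])
        coco = np.concatenate([p.coco17.coords for p in pairs])
        amap, report = fit_affine_map((kin, coco), n_train=30, seed=4)
        true = pairs[0].true_maps
        np.testing.assert_allclose(amap.A, true.A, atol=1e-8)
        np.testing.assert_allclose(amap.b, true.b, atol=1e-8)
        assert report.overall_mse < 1e-12

    def test_noise_floor_sets_recovery_mse_scale(self):
        cfg = GeneratorConfig(n_sequences=3, frame_len=80, fps=10.0,
                              noise_sd=0.01, seed=22)
        pairs = generate_paired_samples(cfg, "random")
        kin = np.concatenate([p.kinect25.coords for p in pairs])
        coco = np.concatenate([p.coco17.coords for p in pairs])
        _, report = fit_affine_map((kin, coco), n_train=100, seed=5)
        # residual MSE per joint ~ 3 * sigma^2 (three coordinates of noise)
        assert 0.5 * 3e-4 < report.overall_mse < 2.0 * 3e-4
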