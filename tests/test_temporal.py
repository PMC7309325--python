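"""Difference images, region-information functions and tracking."""

import numpy as np
import pytest

import respvol as rv
from respvol.levelset import signed_distance
from respvol.temporal import (
    TemporalParams,
    adaptive_region_info,
    adaptive_weight,
    difference_image,
    evolve_region,
    region_energy,
    region_info,
)


def disk(shape, center, radius):
    rows, cols = np.indices(shape)
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2


class TestDifferenceImage:
    def test_identical_frames_zero(self):
        f = np.full((10, 10), 450.0)
        np.testing.assert_array_equal(difference_image(f, f), 0.0)

    def test_inhale_positive_constant_shift(self):
        cur = np.full((10, 10), 447.0)
        prev = cur + 3.0
        np.testing.assert_allclose(difference_image(cur, prev), 3.0)
        np.testing.assert_allclose(difference_image(cur, prev, sign="camera"), -3.0)

    def test_invalid_pixel_rule(self):
        cur = np.full((5, 5), 450.0)
        prev = cur + 2.0
        cur[2, 2] = 0.0
        prev2 = prev.copy()
        prev2[1, 1] = 0.0
        d = difference_image(cur, prev2)
        assert d[2, 2] == 0.0
        assert d[1, 1] == 0.0
        assert d[0, 0] == 2.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            difference_image(np.zeros((4, 4)), np.zeros((5, 5)))


class TestRegionInfo:
    def test_branch_values(self):
        W = disk((60, 60), (30, 30), 12)
        p = region_info(W, eps_region=10.0)
        assert (p[W] == 1.0).all()
        phi_w = signed_distance(W)
        # boundary-adjacent exterior pixel sits just below the midpoint
        near = (~W) & (phi_w > -1.0)
        assert np.all(np.abs(p[near] - 0.5) < 0.05)
        far = phi_w < -20 * 10.0
        if far.any():
            assert p[far].max() < 0.02

    def test_monotone_decay_outside(self):
        W = disk((120, 200), (60, 60), 15)
        p = region_info(W, eps_region=10.0)
        row = p[60, 76:195]
        assert (np.diff(row) <= 1e-12).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(rv.DegenerateInputError):
            region_info(np.zeros((10, 10), bool))


class TestAdaptiveWeight:
    def test_branch_values(self):
        R = disk((40, 40), (20, 20), 8)
        phi = signed_distance(R)
        f = adaptive_weight(R, phi, TH=1.0)
        assert f[20, 20] == 1.0                    # deep interior, phi >= TH
        band = R & (phi > 0) & (phi < 1.0)
        np.testing.assert_allclose(f[band], phi[band])  # interior band
        assert (f[~R] == 0.0).all()                # exterior
        assert f.min() >= 0.0 and f.max() <= 1.0

    def test_threshold_caps_weight(self):
        R = disk((40, 40), (20, 20), 10)
        phi = signed_distance(R)
        f = adaptive_weight(R, phi, TH=2.5)
        assert f.max() == pytest.approx(2.5, abs=0.6)

    def test_nonpositive_threshold_rejected(self):
        R = disk((20, 20), (10, 10), 4)
        with pytest.raises(ValueError):
            adaptive_weight(R, signed_distance(R), TH=0.0)


class TestAdaptiveRegionInfo:
    def test_reduces_to_static_without_previous(self):
        W = disk((50, 50), (25, 25), 12)
        np.testing.assert_array_equal(
            adaptive_region_info(W, None, None), region_info(W)
        )
        np.testing.assert_array_equal(
            adaptive_region_info(W, np.zeros_like(W), None), region_info(W)
        )

    def test_branch_values_with_previous(self):
        W = disk((60, 60), (30, 30), 15)
        R = disk((60, 60), (30, 30), 8)
        phi = signed_distance(R)
        pa = adaptive_region_info(W, R, phi, TH=1.0)
        assert pa[30, 30] == 2.0                  # W and deep inside R_prev
        outside = ~W
        np.testing.assert_array_equal(pa[outside], region_info(W)[outside])
        assert pa.min() >= 0.0 and pa.max() <= 2.0

    def test_range_with_larger_threshold(self):
        W = disk((60, 60), (30, 30), 15)
        R = disk((60, 60), (30, 30), 9)
        pa = adaptive_region_info(W, R, signed_distance(R), TH=3.0)
        assert pa.max() <= 4.0


class TestRegionEnergy:
    def test_constant_field(self):
        p = np.ones((20, 20))
        mask = disk((20, 20), (10, 10), 5)
        assert region_energy(p, mask) == -float(mask.sum())

    def test_empty_mask(self):
        assert region_energy(np.ones((10, 10)), np.zeros((10, 10), bool)) == 0.0

    def test_zero_weight_region_neutral(self):
        p = np.zeros((20, 20))
        small = disk((20, 20), (10, 10), 3)
        big = disk((20, 20), (10, 10), 6)
        assert region_energy(p, small) == region_energy(p, big) == 0.0


class TestEvolveRegion:
    def test_region_weights_gate_motion_blobs(self):
        # motion inside W is kept, an equally strong blob far outside is
        # rejected by the decaying region weights
        shape = (80, 120)
        W = disk(shape, (40, 40), 18)
        diff = np.zeros(shape)
        inner = disk(shape, (40, 40), 9)
        outer = disk(shape, (40, 100), 9)
        diff[inner] = 3.0
        diff[outer] = 3.0
        p = region_info(W)
        params = TemporalParams(smooth_sigma=0.0, diff_scale=3.0)
        phi, _ = evolve_region(diff, signed_distance(W), p, params)
        mask = phi > 0
        assert (mask & inner).sum() / inner.sum() >= 0.9
        assert (mask & outer).sum() / outer.sum() <= 0.05

    def test_zero_weights_shrink_without_data(self):
        shape = (50, 50)
        p = np.zeros(shape)
        start = disk(shape, (25, 25), 10)
        phi, _ = evolve_region(np.zeros(shape), signed_distance(start), p,
                               TemporalParams(smooth_sigma=0.0, diff_scale=1.0))
        assert (phi > 0).sum() < start.sum()

    def test_zero_lambda_is_plain_chan_vese(self):
        shape = (60, 60)
        diff = np.zeros(shape)
        diff[disk(shape, (30, 30), 10)] = 2.0
        start = disk(shape, (30, 30), 20)
        params = TemporalParams(lambda_region=0.0, smooth_sigma=0.0, diff_scale=2.0)
        phi_a, _ = evolve_region(diff, signed_distance(start), np.ones(shape), params)
        phi_b, _ = rv.evolve_chan_vese(np.clip(np.abs(diff) / 2.0, 0, 1),
                                       signed_distance(start), params.cv)
        np.testing.assert_array_equal(phi_a > 0, phi_b > 0)


class TestTrackSequence:
    def test_static_scene_has_empty_masks(self):
        depths = np.full((8, 40, 50), 500.0)
        seq = rv.DepthSequence.from_array(depths, 16.0)
        W = disk((40, 50), (20, 25), 10)
        masks, info = rv.track_sequence(seq, W, adaptive=True)
        assert all(not m.any() for m in masks)

    def test_static_mode_has_no_hidden_state(self, tiny_clean):
        # with the sequence-level context pinned (fixed normalization
        # scale, no temporal averaging), static tracking of a
        # sub-sequence reproduces the same masks: no state flows from
        # earlier results
        cfg, seq, truth = tiny_clean
        params = TemporalParams(diff_scale=0.6, time_window=1, retain_floor=0.1)
        masks, _ = rv.track_sequence(seq, truth.torso_mask, params, adaptive=False)
        sub = rv.DepthSequence(frames=seq.frames[3:6], frame_rate=seq.frame_rate)
        masks_sub, _ = rv.track_sequence(sub, truth.torso_mask, params, adaptive=False)
        np.testing.assert_array_equal(masks[3], masks_sub[0])
        np.testing.assert_array_equal(masks[4], masks_sub[1])

    def test_adaptive_converges_to_static_as_th_vanishes(self, tiny_clean):
        cfg, seq, truth = tiny_clean
        static, _ = rv.track_sequence(seq, truth.torso_mask, adaptive=False)
        diffs = []
        for th in [1.0, 0.1, 1e-3]:
            params = TemporalParams(th=th)
            adaptive, _ = rv.track_sequence(seq, truth.torso_mask, params, adaptive=True)
            diffs.append(max(int((a ^ b).sum()) for a, b in zip(adaptive, static)))
        assert diffs[2] <= diffs[0]
        npix = np.prod(cfg.shape)
        assert diffs[2] <= 0.005 * npix

    def test_short_sequence_rejected(self):
        seq = rv.DepthSequence.from_array(np.full((1, 20, 20), 500.0), 16.0)
        with pytest.raises(ValueError):
            rv.track_sequence(seq, disk((20, 20), (10, 10), 5))
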