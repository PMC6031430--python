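"""Segmentation, body-size normalization and rigid alignment."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.transform import rotate as sk_rotate

from optomap import frame_prep as fp
from optomap import synthetic_arena as sa


@pytest.fixture(scope="module")
def fly_frame(rendered_movie=None):
    cfg = sa.activated_config(noise_sd=0.0)
    sched = sa.make_led_schedule(100, 1, 15, 45)
    gt = sa.simulate_states(cfg, sched, seed=2)
    mv = sa.render_movie(gt, cfg, seed=3, size=96, n_frames=5, schedule=sched)
    return mv.frames[0].astype(float)


class TestSegment:
    def test_blank_frame_invalid(self):
        mask, ok = fp.segment_fly(np.zeros((64, 64)))
        assert not ok and mask.sum() == 0

    def test_rendered_fly_area_close_to_silhouette(self, fly_frame):
        mask, ok = fp.segment_fly(fly_frame)
        fg = (fly_frame > 0).sum()
        assert ok
        assert abs(mask.sum() - fg) / fg < 0.10

    def test_border_touching_fly_invalid(self, fly_frame):
        from scipy.ndimage import shift as nd_shift
        # push the fly partially out of frame (no wraparound)
        shifted = nd_shift(fly_frame, (0, 44), order=0, cval=0.0)
        mask, ok = fp.segment_fly(shifted)
        assert not ok


class TestBodyArea:
    def _two_tone_fly(self, scale=1.0):
        img = np.zeros((128, 128))
        rr, cc = draw_disk((64, 64), 12 * scale)
        img[rr, cc] = 200.0  # body
        for ang in range(0, 360, 60):
            y = 64 + 22 * scale * np.sin(np.deg2rad(ang))
            x = 64 + 22 * scale * np.cos(np.deg2rad(ang))
            rr, cc = draw_disk((y, x), 4 * scale, shape=img.shape)
            img[rr, cc] = 80.0  # legs
        return img

    def test_two_intensity_fly_counts_body_pixels(self):
        img = self._two_tone_fly()
        mask = img > 0
        frames = np.stack([img] * 100)
        masks = np.stack([mask] * 100)
        est = fp.estimate_body_area(frames, masks)
        exact = (img == 200.0).sum()
        assert abs(est - exact) / exact < 0.05

    def test_uniform_blob_falls_back_to_full_area(self):
        img = np.zeros((64, 64))
        rr, cc = draw_disk((32, 32), 10)
        img[rr, cc] = 150.0
        frames = np.stack([img] * 100)
        masks = np.stack([img > 0] * 100)
        est = fp.estimate_body_area(frames, masks)
        assert est == pytest.approx((img > 0).sum(), rel=0.01)

    def test_doubling_size_quadruples_area(self):
        a1 = fp.estimate_body_area(np.stack([self._two_tone_fly(1.0)] * 100),
                                   np.stack([self._two_tone_fly(1.0) > 0] * 100))
        a2 = fp.estimate_body_area(np.stack([self._two_tone_fly(2.0)] * 100),
                                   np.stack([self._two_tone_fly(2.0) > 0] * 100))
        assert a2 / a1 == pytest.approx(4.0, rel=0.10)

    def test_requires_enough_frames(self):
        img = self._two_tone_fly()
        with pytest.raises(ValueError, match="100"):
            fp.estimate_body_area(np.stack([img] * 10), np.stack([img > 0] * 10))


class TestRescale:
    def test_identity_when_areas_match(self, fly_frame):
        out, factor = fp.rescale_frame(fly_frame, 400.0, 400.0)
        assert factor == 1.0
        assert np.array_equal(out, fly_frame)

    def test_factor_is_sqrt_area_ratio(self, fly_frame):
        _, factor = fp.rescale_frame(fly_frame, 4 * 300.0, 300.0)
        assert factor == pytest.approx(0.5)

    def test_rescaled_fly_reaches_reference_area(self, fly_frame):
        mask, _ = fp.segment_fly(fly_frame)
        area = float(mask.sum())
        target = area / 1.6
        out, _ = fp.rescale_frame(fly_frame, area, target)
        mask2, ok = fp.segment_fly(out)
        assert ok
        assert abs(mask2.sum() - target) / target < 0.10


class TestAlignment:
    def test_zero_rotation_for_identical_frames(self, fly_frame):
        mask, _ = fp.segment_fly(fly_frame)
        ref = np.where(mask, fly_frame, 0.0)
        angle, _, ok = fp.align_rotation(ref, ref)
        assert ok
        assert min(angle % 360, 360 - angle % 360) < 1.0

    def test_recovers_34_degrees(self, fly_frame):
        mask, _ = fp.segment_fly(fly_frame)
        ref = np.where(mask, fly_frame, 0.0)
        rotated = sk_rotate(ref, 34.0, preserve_range=True)
        angle, _, ok = fp.align_rotation(rotated, ref)
        assert ok
        err = min(abs((angle - 34.0) % 360), abs((34.0 - angle) % 360))
        assert err <= 1.0

    def test_symmetric_image_half_turn_ambiguity_resolved_head_up(self):
        """A 180-degree-symmetric spectrum leaves {theta, theta+180}; the
        resolver picks the head-up (top-heavy) candidate."""
        img = np.zeros((96, 96))
        rr, cc = draw_disk((38, 48), 9)
        img[rr, cc] = 200.0  # head-up blob
        rr, cc = draw_disk((60, 48), 6)
        img[rr, cc] = 120.0
        flipped = sk_rotate(img, 180.0, preserve_range=True)
        angle, rotated, ok = fp.align_rotation(flipped, img)
        assert ok
        # after rotation by -angle the mass must sit in the top half again
        H = rotated.shape[0]
        assert rotated[: H // 2].sum() > rotated[H // 2:].sum()

    def test_blank_frame_flagged(self):
        _, _, ok = fp.align_rotation(np.zeros((64, 64)), np.ones((64, 64)))
        assert not ok

    def test_translation_identity_and_known_shift(self, fly_frame):
        dx, dy, _ = fp.align_translation(fly_frame, fly_frame)
        assert (dx, dy) == (0, 0)
        shifted = np.roll(fly_frame, (7, -3), axis=(0, 1))
        dx, dy, back = fp.align_translation(shifted, fly_frame)
        assert (dx, dy) == (7, -3)
        assert np.array_equal(back, fly_frame)

    def test_pure_noise_frame_still_returns_a_shift(self, rng):
        a = rng.random((64, 64))
        b = rng.random((64, 64))
        dx, dy, out = fp.align_translation(a, b)
        assert out.shape == a.shape
        assert np.isfinite([dx, dy]).all()

    def test_alignment_idempotent(self, fly_frame):
        mask, _ = fp.segment_fly(fly_frame)
        ref = np.where(mask, fly_frame, 0.0)
        rotated = sk_rotate(ref, 57.0, preserve_range=True)
        a1, out1, _ = fp.align_rotation(rotated, ref)
        a2, _, _ = fp.align_rotation(out1, ref)
        assert min(a2 % 360, 360 - a2 % 360) <= 1.0


class TestPrepareStack:
    def test_whole_stack_segments_aligns_and_reports_validity(self):
        cfg = sa.activated_config(noise_sd=0.0)
        sched = sa.make_led_schedule(100, 1, 15, 45)
        gt = sa.simulate_states(cfg, sched, seed=2)
        mv = sa.render_movie(gt, cfg, seed=3, size=96, n_frames=120,
                             schedule=sched, rotation_step_sd=8.0)
        stack = fp.prepare_stack(mv.frames.astype(float), fps=100.0,
                                 sample_size=100)
        assert stack.fps == 100.0
        assert stack.valid.mean() > 0.9  # validity fraction is reported
        # aligned frames correlate strongly with the reference frame
        ref = stack.frames[np.flatnonzero(stack.valid)[0]]
        cors = []
        for t in np.flatnonzero(stack.valid)[1:20]:
            f = stack.frames[t]
            cors.append(float((f * ref).sum() /
                              np.sqrt((f ** 2).sum() * (ref ** 2).sum())))
        assert np.median(cors) > 0.9

    def test_all_blank_stack_is_all_invalid(self):
        stack = fp.prepare_stack(np.zeros((5, 64, 64)), fps=100.0)
        assert not stack.valid.any()


class TestComposeAndRecover:
    def test_rotation_translation_roundtrip(self, fly_frame):
        """Injected (theta, dx, dy) recovered: angle within one bin, shift
        magnitude within 1 px (rotation turns the shift vector), and the
        doubly-aligned frame matching the reference."""
        mask, _ = fp.segment_fly(fly_frame)
        ref = np.where(mask, fly_frame, 0.0)
        rng = np.random.default_rng(5)
        for _ in range(10):
            theta = rng.uniform(0, 360)
            dx, dy = (int(v) for v in rng.integers(-6, 7, size=2))
            moved = np.roll(sk_rotate(ref, theta, preserve_range=True),
                            (dx, dy), axis=(0, 1))
            ang, rot, ok = fp.align_rotation(moved, ref)
            assert ok
            sx, sy, back = fp.align_translation(rot, ref)
            err = min(abs((ang - theta) % 360), abs((theta - ang) % 360))
            err = min(err, abs(err - 180))
            assert err <= 1.0
            assert abs(np.hypot(sx, sy) - np.hypot(dx, dy)) <= 1.5
            num = float((back * ref).sum())
            den = float(np.sqrt((back ** 2).sum() * (ref ** 2).sum()))
            assert num / den > 0.95
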