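"""Stimulus generators: rings, scrambles, postcards, scotomas, arrays."""

import math

import numpy as np
import pytest

from fullfield import stimgen, synthetic
from fullfield.geometry import CanvasSpec, OutOfFieldError, eccentricity_to_radius_px
from fullfield.stimgen import (
    ArrayLayoutSpec,
    PostcardSpec,
    RingSpec,
    ScotomaSpec,
    apply_scotoma,
    layout_item_array,
    make_postcard,
    make_ring_checkerboard,
    match_luminance,
    phase_scramble,
)


@pytest.fixture(scope="module")
def scene():
    return synthetic.synth_images("scene", 1, seed=0)[0]


@pytest.fixture(scope="module")
def face_pool():
    return synthetic.synth_images("face", 58, seed=2)


class TestRingCheckerboard:
    def test_band_confinement(self):
        spec = RingSpec(6.3, 16.5)
        img = make_ring_checkerboard(spec)
        r_in = eccentricity_to_radius_px(6.3)
        r_out = eccentricity_to_radius_px(16.5)
        yy, xx = np.mgrid[0:768, 0:1024]
        rr = np.hypot(xx - 511.5, yy - 383.5)
        assert np.all(img[(rr < r_in - 1) | (rr > r_out + 1)] == 128.0)
        assert np.any(img[(rr > r_in + 1) & (rr < r_out - 1)] != 128.0)

    def test_contrast_inversion_between_flicker_states(self):
        bw = make_ring_checkerboard(RingSpec(2.0, 5.6, "black-white"))
        wb = make_ring_checkerboard(RingSpec(2.0, 5.6, "white-black"))
        band = bw != 128.0
        assert np.array_equal(255.0 - bw[band], wb[band])

    def test_phase_flips_checks(self):
        a = make_ring_checkerboard(RingSpec(6.3, 16.5), phase=0)
        b = make_ring_checkerboard(RingSpec(6.3, 16.5), phase=1)
        band = a != 128.0
        assert np.array_equal(255.0 - a[band], b[band])

    def test_band_area_matches_analytic_annulus(self):
        spec = RingSpec(6.3, 16.5)
        img = make_ring_checkerboard(spec)
        r_in = eccentricity_to_radius_px(6.3)
        r_out = eccentricity_to_radius_px(16.5)
        analytic = math.pi * (r_out**2 - r_in**2)
        assert (img != 128.0).sum() == pytest.approx(analytic, rel=0.02)

    def test_random_color_state_rgb(self, rng):
        img = make_ring_checkerboard(RingSpec(2.0, 5.6, "random-color"), rng=rng)
        assert img.ndim == 3 and img.shape[2] == 3

    def test_meridian_band_variant(self):
        h = make_ring_checkerboard(RingSpec(2.0, 50.0), orientation_band="horizontal")
        v = make_ring_checkerboard(RingSpec(2.0, 50.0), orientation_band="vertical")
        # horizontal meridian wedge is stimulated left/right of fixation
        assert np.any(h[380:388, 700:900] != 128.0)
        assert np.all(h[100:250, 505:520] == 128.0)
        assert np.any(v[100:250, 505:520] != 128.0)

    def test_band_outside_screen_rejected(self):
        with pytest.raises(OutOfFieldError):
            make_ring_checkerboard(RingSpec(95.0, 120.0))


class TestPhaseScramble:
    def test_amplitude_spectrum_preserved(self, scene, rng):
        out = phase_scramble(scene, rng)
        a0 = np.abs(np.fft.fft2(scene))
        a1 = np.abs(np.fft.fft2(out))
        assert np.max(np.abs(a1 - a0)) / a0.max() < 1e-6

    def test_mean_luminance_preserved(self, scene, rng):
        out = phase_scramble(scene, rng)
        assert out.mean() == pytest.approx(scene.mean(), abs=1e-6)

    def test_zero_magnitude_is_identity(self, scene, rng):
        out = phase_scramble(scene, rng, magnitude=0.0)
        assert np.abs(out - scene).max() < 1e-9

    def test_rgb_channels_share_noise(self, rng):
        img = np.dstack([synthetic.synth_images("scene", 1, seed=7)[0]] * 3)
        out = phase_scramble(img, rng, share_channels=True)
        # identical channels stay identical under shared phase noise
        assert np.abs(out[:, :, 0] - out[:, :, 1]).max() < 1e-9

    def test_output_differs_from_input(self, scene, rng):
        out = phase_scramble(scene, rng)
        assert np.abs(out - scene).max() > 10.0


class TestPostcard:
    def test_output_is_canvas_sized(self, scene):
        out = make_postcard(scene)
        assert out.shape == (768, 1024)

    def test_corners_are_pad_value(self, scene):
        out = make_postcard(scene, PostcardSpec(pad_value=40.0))
        for y, x in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            assert out[y, x] == 40.0

    def test_central_region_matches_oracle_resampler(self, scene):
        """Bicubic downscale agrees with an independent resampler."""
        from skimage.transform import resize

        out = make_postcard(scene)
        tw, th = 205, 154
        y0, x0 = (768 - th) // 2, (1024 - tw) // 2
        centre = out[y0:y0 + th, x0:x0 + tw]
        oracle = resize(scene, (th, tw), order=3, anti_aliasing=True,
                        preserve_range=True)
        assert np.mean(np.abs(centre - oracle)) < 1.0

    def test_face_bounding_box_variant(self, scene):
        out = make_postcard(scene, PostcardSpec(target_size_px=(171, 129),
                                                pad_value=255.0))
        assert out.shape == (768, 1024)
        assert out[0, 0] == 255.0

    def test_target_larger_than_canvas_rejected(self):
        with pytest.raises(ValueError):
            PostcardSpec(target_size_px=(2000, 100))


class TestScotoma:
    def test_zero_diameter_is_identity(self, scene):
        out = apply_scotoma(scene, ScotomaSpec(0.0))
        assert np.array_equal(out, scene)

    def test_centre_pixel_filled(self, scene):
        for d in (29.0, 58.0, 88.0, 140.0):
            out = apply_scotoma(scene, ScotomaSpec(d, fill=128.0))
            assert out[384, 512] == 128.0

    def test_masked_area_matches_analytic_disc(self, scene):
        d = 58.0
        out = apply_scotoma(scene, ScotomaSpec(d, fill=-1.0))
        masked = (out == -1.0).sum()
        assert masked == pytest.approx(stimgen.scotoma_mask_area_px(d), rel=0.02)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            ScotomaSpec(-1.0)

    def test_both_diameter_conventions_supported(self):
        assert stimgen.SCOTOMA_DIAMETERS_DEG == (0.0, 29.0, 58.0, 88.0, 140.0)
        assert stimgen.SCOTOMA_DIAMETERS_MAIN_TEXT_DEG == (0.0, 30.0, 58.0, 88.0, 138.0)


class TestItemArray:
    def test_thirteen_items_placed(self, face_pool, rng):
        canvas, table = layout_item_array(face_pool, rng=rng)
        assert len(table) == 13
        assert sorted(table["diameter_px"].unique()) == [113, 178, 295]

    def test_zero_jitter_ring_rotation_symmetry(self, face_pool):
        spec = ArrayLayoutSpec(jitter_px=0.0)
        _, table = layout_item_array(face_pool, spec, np.random.default_rng(0))
        mid = table[table["ring"] == 1]
        ang = np.sort(
            np.arctan2(mid["y"] - 384.0, mid["x"] - 512.0) % (2 * np.pi)
        )
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        assert np.allclose(gaps, 2 * np.pi / 6, atol=1e-6)

    def test_outer_items_at_corners(self, face_pool):
        spec = ArrayLayoutSpec(jitter_px=0.0)
        _, table = layout_item_array(face_pool, spec, np.random.default_rng(0))
        outer = table[table["ring"] == 2]
        assert len(outer) == 4
        assert set(map(tuple, np.round(outer[["x", "y"]].values).astype(int))) == {
            (130, 130), (894, 130), (894, 638), (130, 638)
        }

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_no_overlap_across_seeds(self, face_pool, seed):
        _, table = layout_item_array(face_pool, rng=np.random.default_rng(seed))
        pts = table[["x", "y"]].values
        rr = table["diameter_px"].values / 2.0
        d = np.hypot(pts[:, 0, None] - pts[None, :, 0],
                     pts[:, 1, None] - pts[None, :, 1])
        iu = np.triu_indices(len(pts), k=1)
        assert np.all(d[iu] >= (rr[:, None] + rr[None, :])[iu])

    def test_pool_too_small_rejected(self, face_pool):
        with pytest.raises(ValueError):
            layout_item_array(face_pool[:5], rng=np.random.default_rng(0))

    def test_unsatisfiable_layout_reports_error(self, face_pool):
        spec = ArrayLayoutSpec(ring_radii_px=(60.0, 120.0), jitter_px=30.0,
                               max_retries=5)
        with pytest.raises(stimgen.LayoutError):
            layout_item_array(face_pool, spec, np.random.default_rng(0))


class TestMatchLuminance:
    def test_identical_inputs_unchanged(self, scene):
        out = match_luminance([scene, scene.copy()])
        assert np.allclose(out[0], scene, atol=1e-9)

    def test_mean_luminance_spread_collapses(self):
        imgs = synthetic.synth_images("scene", 4, seed=5)
        out = match_luminance(imgs)
        means = [o.mean() for o in out]
        assert np.ptp(means) < 0.5

    def test_histograms_match_average(self):
        imgs = synthetic.synth_images("scene", 2, seed=6)
        out = match_luminance(imgs)
        h0, edges = np.histogram(out[0], bins=64, range=(0, 255))
        h1, _ = np.histogram(out[1], bins=64, range=(0, 255))
        chi2 = np.sum((h0 - h1) ** 2 / np.maximum(h0 + h1, 1))
        assert chi2 < 1.0

    def test_rank_order_preserved(self):
        imgs = synthetic.synth_images("scene", 3, seed=8)
        out = match_luminance(imgs)
        a, b = imgs[0].ravel(), out[0].ravel()
        pick = np.random.default_rng(0).choice(a.size, 4000, replace=False)
        ia = np.argsort(a[pick], kind="stable")
        assert np.all(np.diff(b[pick][ia]) >= 0)

    def test_single_image_warns_identity(self, scene):
        with pytest.warns(UserWarning):
            out = match_luminance([scene])
        assert np.array_equal(out[0], scene)


class TestDeterminism:
    def test_generators_reproduce_byte_identical(self):
        a = synthetic.synth_images("scene", 2, seed=3)
        b = synthetic.synth_images("scene", 2, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        s1 = phase_scramble(a[0], np.random.default_rng(5))
        s2 = phase_scramble(b[0], np.random.default_rng(5))
        assert np.array_equal(s1, s2)
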