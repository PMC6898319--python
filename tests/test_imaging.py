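"""Reference image, convolution, neural cutoff surface, low-pass, crop."""

import numpy as np
import pytest

from periq.imaging import (
    DEFAULT_CUTOFF_ANCHORS,
    CutoffAnchor,
    CutoffSurface,
    convolve_psf,
    crop_margin,
    eval_cutoff,
    gaussian_lowpass,
    make_reference,
    simulate_retinal_image,
)
from periq.mapping import cross_correlation
from periq.optics import PSFImage, ZernikeSample, compute_psf


class TestMakeReference:
    def test_builtin_is_seeded_and_reproducible(self):
        a = make_reference("builtin", seed=0)
        b = make_reference("builtin", seed=0)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, make_reference("builtin", seed=1).pixels)

    def test_geometry_contract(self, reference):
        assert reference.side == 512
        assert reference.sampling_arcmin == pytest.approx(0.234375)
        assert reference.pixels.min() >= 0 and reference.pixels.max() <= 1

    def test_small_file_rejected(self, tmp_path):
        from PIL import Image

        p = tmp_path / "small.png"
        Image.fromarray(np.zeros((100, 100), dtype=np.uint8)).save(p)
        with pytest.raises(ValueError):
            make_reference(p)

    def test_large_file_centre_cropped(self, tmp_path):
        from PIL import Image

        rng = np.random.default_rng(0)
        p = tmp_path / "big.png"
        Image.fromarray(rng.integers(0, 255, (600, 700), dtype=np.uint8).astype(np.uint8)).save(p)
        ref = make_reference(p)
        assert ref.side == 512

    def test_unreadable_file_rejected(self, tmp_path):
        p = tmp_path / "junk.png"
        p.write_text("not an image")
        with pytest.raises(ValueError):
            make_reference(p)


class TestConvolvePsf:
    def test_unit_impulse_is_identity(self, reference):
        imp = np.zeros((128, 128))
        imp[64, 64] = 1.0
        out = convolve_psf(reference, PSFImage(imp, reference.sampling_arcmin))
        assert np.abs(out - reference.pixels).max() < 1e-12

    def test_mean_preserved(self, reference):
        psf = compute_psf(ZernikeSample(0, 0, {(2, 0): 0.3}))
        out = convolve_psf(reference, psf)
        assert abs(out.mean() - reference.pixels.mean()) < 1e-6

    def test_wider_defocus_lowers_variance(self, reference):
        v = []
        for c20 in (0.1, 0.3):
            psf = compute_psf(ZernikeSample(0, 0, {(2, 0): c20}))
            v.append(convolve_psf(reference, psf).var())
        assert v[1] < v[0]

    def test_sampling_mismatch_rejected(self, reference):
        psf = PSFImage(np.full((4, 4), 1 / 16), sampling_arcmin=1.0)
        with pytest.raises(ValueError):
            convolve_psf(reference, psf)


class TestCutoffSurface:
    def test_anchor_identity(self, surface):
        for a in surface.anchors:
            assert eval_cutoff(surface, a.x_deg, a.y_deg) == pytest.approx(a.f_cutoff_cpd)

    def test_edge_midpoint_is_mean(self):
        # a single triangle: any edge midpoint interpolates linearly
        surf = CutoffSurface(
            [CutoffAnchor(0, 0, 40.0), CutoffAnchor(10, 0, 20.0), CutoffAnchor(0, 10, 30.0)]
        )
        assert surf(5.0, 0.0) == pytest.approx(30.0)
        assert surf(0.0, 5.0) == pytest.approx(35.0)

    def test_outside_hull_nearest_anchor(self, surface):
        assert eval_cutoff(surface, 80.0, 0.0) == pytest.approx(6.0)

    def test_bounded_inside_hull(self, surface):
        vals = [a.f_cutoff_cpd for a in surface.anchors]
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y = rng.uniform(-40, 40), rng.uniform(-20, 20)
            v = eval_cutoff(surface, x, y)
            assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9

    def test_default_fixture_has_twenty_anchors(self):
        assert len(DEFAULT_CUTOFF_ANCHORS) == 20

    def test_csv_round_trip_exact(self, surface, tmp_path):
        p = tmp_path / "anchors.csv"
        surface.to_csv(p)
        again = CutoffSurface.from_csv(p)
        assert again.anchors == surface.anchors

    def test_empty_anchor_set_rejected(self):
        with pytest.raises(ValueError):
            CutoffSurface([])


class TestGaussianLowpass:
    def test_constant_image_unchanged(self):
        img = np.full((64, 64), 0.3)
        out = gaussian_lowpass(img, 5.0, 0.234375)
        assert np.abs(out - img).max() < 1e-12

    def test_half_amplitude_gain_at_cutoff(self, reference):
        fc = 20.0  # exact FFT bin of the 2-degree window
        out = gaussian_lowpass(reference.pixels, fc, reference.sampling_arcmin)
        F = np.fft.rfft2(reference.pixels)
        G = np.fft.rfft2(out)
        fx = np.fft.rfftfreq(512, d=reference.sampling_arcmin / 60.0)
        j = int(np.argmin(np.abs(fx - fc)))
        assert abs(G[0, j] / F[0, j]) == pytest.approx(0.5, abs=1e-6)

    def test_large_cutoff_approaches_identity(self, reference):
        devs = [
            np.abs(gaussian_lowpass(reference.pixels, fc, reference.sampling_arcmin) - reference.pixels).max()
            for fc in (50.0, 1000.0, 100000.0)
        ]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 1e-5

    def test_alternative_cutoff_definitions(self):
        img = np.random.default_rng(0).uniform(size=(64, 64))
        for definition in ("one_over_e", "two_sigma"):
            out = gaussian_lowpass(img, 10.0, 0.234375, definition)
            assert out.shape == img.shape
        with pytest.raises(ValueError):
            gaussian_lowpass(img, 10.0, 0.234375, "bogus")

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            gaussian_lowpass(np.zeros((8, 8)), 0.0, 0.234375)


class TestCropMargin:
    def test_zero_margin_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(crop_margin(img, 0), img)

    def test_standard_crop_arithmetic(self):
        assert crop_margin(np.zeros((512, 512)), 64).shape == (384, 384)

    def test_margin_too_large_rejected(self):
        with pytest.raises(ValueError):
            crop_margin(np.zeros((512, 512)), 256)


class TestSimulateRetinalImage:
    def test_foveal_limit_path_bounded_only_by_diffraction(self, reference, high_cutoff_surface):
        # with an effectively transparent neural filter the limit path
        # reduces to diffraction blur alone: high correlation, and exactly
        # equal to the optics path with zero aberrations
        sim = simulate_retinal_image(
            reference,
            ZernikeSample(0, 0, {}),
            high_cutoff_surface,
            include_optics=False,
        )
        optics = simulate_retinal_image(
            reference, ZernikeSample(0, 0, {}), high_cutoff_surface, include_optics=True
        )
        ref_crop = crop_margin(reference.pixels, 64)
        assert cross_correlation(sim, ref_crop) > 0.9
        assert np.array_equal(sim, optics)

    def test_zero_aberrations_equals_limit_path(self, reference, surface):
        a = simulate_retinal_image(reference, ZernikeSample(5, 0, {}), surface, include_optics=True)
        b = simulate_retinal_image(reference, ZernikeSample(5, 0, {}), surface, include_optics=False)
        assert np.array_equal(a, b)

    def test_output_side_under_defaults(self, reference, surface):
        sim = simulate_retinal_image(reference, ZernikeSample(0, 0, {(2, 0): 0.1}), surface)
        assert sim.shape == (384, 384)

    def test_blur_degrades_correlation_monotonically(self, reference, high_cutoff_surface):
        ref_crop = crop_margin(reference.pixels, 64)
        corrs = []
        for c20 in (0.0, 0.1, 0.2, 0.3):
            sim = simulate_retinal_image(
                reference, ZernikeSample(0, 0, {(2, 0): c20}), high_cutoff_surface
            )
            corrs.append(cross_correlation(sim, ref_crop))
        assert all(a > b for a, b in zip(corrs, corrs[1:]))
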