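"""Cross-correlation metric, map interpolation, difference maps, RMSE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from periq.config import PipelineConfig
from periq.mapping import (
    MAP_GRID_DEG,
    DifferenceMap,
    QualityMap,
    cross_correlation,
    difference_map,
    interpolate_map,
    map_rmse,
    neural_limit_samples,
    sample_quality,
)
from periq.optics import ZernikeField, ZernikeSample


class TestCrossCorrelation:
    def test_identical_images_give_exactly_one(self, reference):
        assert cross_correlation(reference.pixels, reference.pixels.copy()) == 1.0

    def test_inverted_image_clamps_to_zero(self, reference):
        assert cross_correlation(reference.pixels, 1.0 - reference.pixels) == 0.0

    @given(scale=st.floats(0.05, 3.0), offset=st.floats(-0.5, 0.5))
    def test_affine_invariance(self, scale, offset):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(32, 32))
        assert cross_correlation(a, scale * a + offset) == pytest.approx(1.0, abs=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_correlation(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_two_constant_images_undefined(self):
        with pytest.raises(ValueError):
            cross_correlation(np.full((4, 4), 0.5), np.full((4, 4), 0.2))

    def test_one_constant_image_gives_zero(self):
        rng = np.random.default_rng(0)
        assert cross_correlation(rng.uniform(size=(8, 8)), np.full((8, 8), 0.5)) == 0.0


class TestInterpolateMap:
    def test_constant_samples_fill_map(self):
        samples = [(-20.0, -20.0, 0.7), (20.0, -20.0, 0.7), (0.0, 20.0, 0.7), (5.0, 0.0, 0.7)]
        qmap = interpolate_map(samples)
        assert qmap.values.shape == (40, 40)
        assert np.allclose(qmap.values, 0.7)

    def test_exact_at_coincident_cells(self):
        # sample positions chosen on the half-integer map grid
        samples = [
            (-10.5, -10.5, 0.2),
            (10.5, -10.5, 0.4),
            (-10.5, 10.5, 0.6),
            (10.5, 10.5, 0.8),
        ]
        qmap = interpolate_map(samples)
        grid = list(MAP_GRID_DEG)
        for x, y, v in samples:
            assert qmap.values[grid.index(y), grid.index(x)] == pytest.approx(v, abs=1e-12)

    def test_bounded_by_sample_range(self):
        rng = np.random.default_rng(3)
        samples = [
            (float(x), float(y), float(rng.uniform(0.2, 0.9)))
            for x in (-20, 0, 20)
            for y in (-20, 0, 20)
        ]
        qmap = interpolate_map(samples)
        vals = [v for _, _, v in samples]
        assert qmap.values.min() >= min(vals) - 1e-9
        assert qmap.values.max() <= max(vals) + 1e-9

    def test_collinear_samples_rejected(self):
        with pytest.raises(ValueError):
            interpolate_map([(0.0, 0.0, 0.5), (1.0, 0.0, 0.5), (2.0, 0.0, 0.5)])


class TestDifferenceMapAndRmse:
    def test_equal_maps_give_zero(self):
        q = QualityMap(np.full((40, 40), 0.6))
        d = difference_map(q, QualityMap(np.full((40, 40), 0.6)))
        assert np.all(d.values == 0.0)
        assert map_rmse(d) == 0.0

    def test_constant_difference(self):
        d = difference_map(QualityMap(np.full((40, 40), 0.9)), QualityMap(np.full((40, 40), 0.6)))
        assert np.allclose(d.values, 0.3)
        assert map_rmse(d) == pytest.approx(0.3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = QualityMap(rng.uniform(size=(40, 40)))
        b = QualityMap(rng.uniform(size=(40, 40)))
        assert np.allclose(difference_map(a, b).values, -difference_map(b, a).values)

    def test_rmse_mixed_cells(self):
        vals = np.zeros(1600)
        vals[:800] = 0.4
        d = DifferenceMap(vals.reshape(40, 40))
        assert map_rmse(d) == pytest.approx(np.sqrt(0.08))


class TestQualitySampling:
    def _flat_field(self, coeffs):
        cfg = PipelineConfig()
        samples = [
            ZernikeSample(x, y, dict(coeffs))
            for (x, y) in cfg.mapping.locations()
        ]
        return ZernikeField("S01", "naked_eye", samples)

    def test_default_locations_count(self, config):
        assert len(config.mapping.locations()) == 45

    def test_zero_aberration_field_matches_neural_limit(self, reference, surface, config):
        field = self._flat_field({})
        optical = sample_quality(field, reference, surface, config)
        limit = neural_limit_samples(reference, surface, config)
        for (x1, y1, v1), (x2, y2, v2) in zip(optical, limit):
            assert (x1, y1) == (x2, y2)
            assert v1 == pytest.approx(v2, abs=1e-12)

    def test_defocus_lowers_every_sample(self, reference, surface, config):
        clear = sample_quality(self._flat_field({}), reference, surface, config)
        blurred = sample_quality(
            self._flat_field({(2, 0): 0.3}), reference, surface, config
        )
        assert all(b < c for (_, _, c), (_, _, b) in zip(clear, blurred))

    def test_location_outside_field_rejected(self, reference, surface, config):
        field = self._flat_field({})
        with pytest.raises(KeyError):
            sample_quality(field, reference, surface, config, locations=[(33.0, 7.0)])

    def test_neural_limit_foveal_close_to_diffraction_bound(
        self, reference, high_cutoff_surface, config
    ):
        # the broadband 1/f reference carries energy out to the image
        # Nyquist (128 cyc/deg), so diffraction at a 3 mm pupil caps the
        # foveal limit correlation near 0.92 even without a neural filter
        samples = neural_limit_samples(
            reference, high_cutoff_surface, config, locations=[(0.0, 0.0)]
        )
        assert samples[0][2] > 0.9

    def test_neural_limit_deterministic(self, reference, surface, config):
        a = neural_limit_samples(reference, surface, config)
        b = neural_limit_samples(reference, surface, config)
        assert a == b


class TestEndToEndMaps:
    """Invariants of the fitted small-cohort study."""

    def test_quality_maps_in_unit_interval(self, small_results):
        for qmap in small_results.quality_maps.values():
            assert qmap.values.min() >= 0.0 and qmap.values.max() <= 1.0
            assert qmap.values.shape == (40, 40)

    def test_difference_maps_nearly_nonnegative(self, small_results):
        for dmap in small_results.difference_maps.values():
            assert dmap.values.min() >= -0.02

    def test_naked_eye_pooled_rmse_smallest(self, small_results):
        pooled = small_results.pooled_rmse
        assert pooled["naked_eye"] < pooled["centre_near"]
        assert pooled["naked_eye"] < pooled["centre_distance"]
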