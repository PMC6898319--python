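"""Synthetic cohort generator: profiles, fields, cohorts, label recovery."""

import numpy as np
import pytest

from periq.optics import normalize_low_order, spherical_equivalent
from periq.segmentation import classify_pattern
from periq.synthetic import (
    CONDITIONS,
    PATTERNS,
    CohortDataset,
    LensDesign,
    extract_refraction_profile,
    generate_cohort,
    generate_refraction_profile,
    generate_zernike_field,
    lens_weight,
)


class TestRefractionProfiles:
    def test_rph_raises_both_edges_by_magnitude(self):
        prof = generate_refraction_profile("RPH", 1.0, 0.0, 0.0, seed=0)
        M = dict(zip(prof.eccentricity_deg, prof.M))
        assert M[40.0] - M[0.0] == pytest.approx(1.0)
        assert M[-40.0] - M[0.0] == pytest.approx(1.0)

    def test_pns_edge_difference_equals_skew(self):
        prof = generate_refraction_profile("PNS", 0.0, 1.0, 0.0, seed=0)
        M = dict(zip(prof.eccentricity_deg, prof.M))
        assert M[40.0] - M[-40.0] == pytest.approx(1.0)

    def test_seeded_reproducibility(self):
        a = generate_refraction_profile("RPM", 1.0, 0.0, 0.05, seed=7)
        b = generate_refraction_profile("RPM", 1.0, 0.0, 0.05, seed=7)
        assert np.array_equal(a.M, b.M)

    def test_unknown_pattern_and_negative_magnitude_rejected(self):
        with pytest.raises(ValueError):
            generate_refraction_profile("XYZ", 1.0, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            generate_refraction_profile("RPM", -1.0, 0.0, 0.0, seed=0)


class TestZernikeFields:
    def test_astigmatism_grows_with_eccentricity(self):
        prof = generate_refraction_profile("RPM", 1.0, 0.0, 0.0, seed=0)
        field = generate_zernike_field(prof, seed=0, scan_noise_um=0.0)
        assert field.sample_at(20, 0).coeff(2, 2) > field.sample_at(0, 0).coeff(2, 2)

    def test_centre_near_foveal_defocus_shift_equals_add(self):
        prof = generate_refraction_profile("RPM", 1.0, 0.0, 0.0, seed=0)
        naked = generate_zernike_field(prof, LensDesign.none(), seed=0, scan_noise_um=0.0)
        lens = LensDesign("centre_near", distance_power_D=0.0, add_power_D=2.25)
        with_lens = generate_zernike_field(prof, lens, seed=0, scan_noise_um=0.0)
        dc20 = with_lens.sample_at(0, 0).coeff(2, 0) - naked.sample_at(0, 0).coeff(2, 0)
        # invert the spherical-equivalent conversion: the foveal shift is
        # the full add power since w(0) = 1
        assert spherical_equivalent(dc20, 1.5) == pytest.approx(2.25 * lens_weight(0.0))

    def test_centre_distance_concentrates_add_peripherally(self):
        prof = generate_refraction_profile("RPM", 1.0, 0.0, 0.0, seed=0)
        lens = LensDesign("centre_distance", distance_power_D=0.0, add_power_D=2.50)
        naked = generate_zernike_field(prof, LensDesign.none(), seed=0, scan_noise_um=0.0)
        with_lens = generate_zernike_field(prof, lens, seed=0, scan_noise_um=0.0)

        def shift(x):
            d = with_lens.sample_at(x, 0).coeff(2, 0) - naked.sample_at(x, 0).coeff(2, 0)
            return spherical_equivalent(d, 1.5)

        assert shift(0) < shift(40)
        assert shift(40) == pytest.approx(2.50 * (1 - lens_weight(40.0)), abs=1e-9)

    def test_same_seed_bit_identical(self):
        prof = generate_refraction_profile("PNS", 1.0, 1.0, 0.1, seed=3)
        a = generate_zernike_field(prof, seed=5)
        b = generate_zernike_field(prof, seed=5)
        for sa, sb in zip(a.samples, b.samples):
            assert sa.coeffs == sb.coeffs

    def test_grid_coverage_mismatch_rejected(self):
        prof = generate_refraction_profile(
            "RPM", 1.0, 0.0, 0.0, seed=0, eccentricities_deg=np.arange(-40.0, 41.0)
        )
        with pytest.raises(ValueError):
            generate_zernike_field(prof, grid_x_deg=np.arange(-50.0, 51.0))

    def test_higher_orders_constant_across_field(self):
        prof = generate_refraction_profile("RPM", 1.0, 0.0, 0.0, seed=0)
        field = generate_zernike_field(prof, seed=0, scan_noise_um=0.0)
        c40 = {field.sample_at(x, 0).coeff(4, 0) for x in (-30, 0, 30)}
        assert len(c40) == 1


class TestCohorts:
    def test_default_mix_is_thirteen_subjects_three_conditions(self):
        cohort = generate_cohort(seed=0, scan_noise_um=0.0)
        assert len(cohort.subjects) == 13
        labels = [s.pattern for s in cohort.subjects]
        assert {p: labels.count(p) for p in PATTERNS} == {
            "PNS": 5, "RPM": 4, "RPH": 3, "PTS": 1
        }
        for s in cohort.subjects:
            assert set(s.fields) == set(CONDITIONS)

    def test_seeded_determinism(self):
        a = generate_cohort({"RPM": 1, "PTS": 1}, seed=4)
        b = generate_cohort({"RPM": 1, "PTS": 1}, seed=4)
        for sa, sb in zip(a.subjects, b.subjects):
            for cond in CONDITIONS:
                for xa, xb in zip(sa.fields[cond].samples, sb.fields[cond].samples):
                    assert xa.coeffs == xb.coeffs

    def test_single_subject_round_trips_through_classifier(self):
        cohort = generate_cohort({"RPM": 1}, seed=2)
        profile = extract_refraction_profile(cohort.subjects[0].fields["naked_eye"])
        assert classify_pattern(profile) == "RPM"

    def test_empty_mix_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort({"PNS": 0, "RPM": 0}, seed=0)
        with pytest.raises(ValueError):
            generate_cohort({"BAD": 1}, seed=0)

    def test_incomplete_conditions_rejected(self):
        cohort = generate_cohort({"RPM": 1}, seed=0)
        subject = cohort.subjects[0]
        subject.fields.pop("centre_near")
        with pytest.raises(ValueError):
            CohortDataset(subjects=[subject], seed=0)


class TestLabelRecovery:
    def test_pattern_recovery_rate_at_default_noise(self):
        # >= 95% of 100 subjects per archetype recover their generating
        # label at magnitude 1.0 D, skew 1.0 D, noise 0.1 D
        hits = total = 0
        for pattern in PATTERNS:
            for rep in range(100):
                prof = generate_refraction_profile(
                    pattern, 1.0, 1.0, 0.1, seed=10_000 + total
                )
                hits += classify_pattern(prof) == pattern
                total += 1
        assert hits / total >= 0.95

    def test_zero_noise_naked_eye_fovea_normalises_to_zero(self):
        prof = generate_refraction_profile("RPH", 1.0, 0.0, 0.0, seed=0)
        field = generate_zernike_field(prof, seed=0, scan_noise_um=0.0)
        normed = normalize_low_order(field)
        fov = normed.foveal_sample
        assert fov.coeff(2, 0) == 0.0
        assert fov.coeff(2, -2) == 0.0
        assert fov.coeff(2, 2) == 0.0
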