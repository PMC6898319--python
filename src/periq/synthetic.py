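"""Synthetic cohort generator.

Emulates the structure of a peripheral Hartmann-Shack study: an 80-degree
horizontal scan sampled every degree (81 frames) repeated at five vertical
fixations (0, +/-10, +/-20 deg), four scans averaged per fixation, Zernike
coefficients to 6th order over a 3 mm pupil.  Subjects are drawn from four
peripheral-refraction archetypes (PNS, RPM, RPH, PTS) and measured under
three optical conditions: naked eye and two multifocal contact-lens
designs (centre-near, centre-distance).

The generator's randomness flows entirely from the supplied seeds, so a
cohort is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import (
    ZernikeField,
    ZernikeSample,
    defocus_from_spherical_equivalent,
    spherical_equivalent,
    zernike_nm_terms,
)

__all__ = [
    "CONDITIONS",
    "PATTERNS",
    "DEFAULT_N_PER_PATTERN",
    "RefractionProfile",
    "LensDesign",
    "SubjectRecord",
    "CohortDataset",
    "lens_weight",
    "generate_refraction_profile",
    "generate_zernike_field",
    "generate_cohort",
    "extract_refraction_profile",
]

CONDITIONS = ("naked_eye", "centre_near", "centre_distance")
PATTERNS = ("PNS", "RPM", "RPH", "PTS")
#: Default cohort mix: 13 subjects (5 PNS, 4 RPM, 3 RPH, 1 PTS).
DEFAULT_N_PER_PATTERN = {"PNS": 5, "RPM": 4, "RPH": 3, "PTS": 1}

#: Measurement grid: 81 horizontal positions x 5 vertical fixations.
GRID_X_DEG = tuple(float(x) for x in range(-40, 41))
GRID_Y_DEG = (-20.0, -10.0, 0.0, 10.0, 20.0)

#: Scans averaged per vertical fixation (4 x 81 = 324 frames).
N_SCANS = 4

#: Default per-subject draws for field-constant higher-order terms and the
#: eccentricity slope of trefoil: (n, m) -> (base um, slope um/deg).
DEFAULT_HOA_PARAMS: dict[tuple[int, int], tuple[float, float]] = {
    (3, 3): (0.02, 0.0008),
    (3, -3): (0.015, 0.0006),
    (4, 0): (0.03, 0.0),
    (4, 2): (0.01, 0.0),
    (4, -2): (0.01, 0.0),
    (4, 4): (0.008, 0.0),
    (4, -4): (0.008, 0.0),
    (5, 1): (0.005, 0.0),
    (5, -1): (0.005, 0.0),
    (6, 0): (0.004, 0.0),
}


@dataclass
class RefractionProfile:
    """Spherical-equivalent refraction along the horizontal meridian.

    Eccentricity is signed (temporal negative, nasal positive, degrees);
    M is in dioptres.
    """

    eccentricity_deg: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.eccentricity_deg = np.asarray(self.eccentricity_deg, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.eccentricity_deg.shape != self.M.shape:
            raise ValueError("eccentricity and M must have the same length")
        if np.any(np.diff(self.eccentricity_deg) <= 0):
            raise ValueError("eccentricities must be strictly increasing")
        if np.any(np.abs(self.M) > 15.0):
            raise ValueError("|M| must not exceed 15 dioptres")
        if self.eccentricity_deg.min() > -40.0 or self.eccentricity_deg.max() < 40.0:
            raise ValueError("profile must cover at least [-40, +40] degrees")

    def at(self, x_deg) -> np.ndarray:
        return np.interp(x_deg, self.eccentricity_deg, self.M)


@dataclass(frozen=True)
class LensDesign:
    """Multifocal soft-lens description: distance power plus an add.

    The centre-near design concentrates the add centrally, centre-distance
    peripherally; ``design="none"`` is the naked eye.
    """

    design: str = "none"
    distance_power_D: float = -0.25
    add_power_D: float | None = None

    _DEFAULT_ADD = {"none": 0.0, "centre_near": 2.25, "centre_distance": 2.50}

    def __post_init__(self) -> None:
        if self.design not in self._DEFAULT_ADD:
            raise ValueError(f"unknown lens design {self.design!r}")
        if self.add_power_D is None:
            object.__setattr__(self, "add_power_D", self._DEFAULT_ADD[self.design])

    @classmethod
    def none(cls) -> "LensDesign":
        return cls("none", distance_power_D=0.0)

    @classmethod
    def centre_near(cls) -> "LensDesign":
        return cls("centre_near")

    @classmethod
    def centre_distance(cls) -> "LensDesign":
        return cls("centre_distance")

    def defocus_offset_D(self, eccentricity_deg: float, weight_width_deg: float = 10.0) -> float:
        """Lens power (D) added to the eye's refraction at one eccentricity."""
        if self.design == "none":
            return 0.0
        w = lens_weight(eccentricity_deg, weight_width_deg)
        if self.design == "centre_near":
            return self.distance_power_D + self.add_power_D * w
        return self.distance_power_D + self.add_power_D * (1.0 - w)


def lens_weight(eccentricity_deg, width_deg: float = 10.0):
    """Radial weighting of the add power: w(e) = exp(-(e/width)^2).

    Decays from 1 at the lens centre to ~0 beyond ~2 widths, so the
    centre-near design places the add centrally and the centre-distance
    design places it peripherally.  A configurable stand-in: real lenses
    do not publish their radial power profiles.
    """
    e = np.asarray(eccentricity_deg, dtype=float)
    w = np.exp(-((e / width_deg) ** 2))
    return float(w) if np.isscalar(eccentricity_deg) else w


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: Quadratic/linear shape coefficients (a, b) per archetype for
#: M(e) = M0 + a (e/40)^2 + b (e/40) + noise.  The skew slope is halved so
#: that skew_D is the nasal-minus-temporal edge difference M(+40) - M(-40).
_PATTERN_SHAPES = {
    "RPM": lambda mag, skew: (-mag, 0.0),
    "RPH": lambda mag, skew: (+mag, 0.0),
    "PNS": lambda mag, skew: (0.0, +skew / 2.0),
    "PTS": lambda mag, skew: (0.0, -skew / 2.0),
}


def generate_refraction_profile(
    pattern: str,
    magnitude_D: float = 1.0,
    skew_D: float = 1.0,
    noise_sd_D: float = 0.1,
    seed: int = 0,
    central_M_D: float = -3.25,
    eccentricities_deg=None,
) -> RefractionProfile:
    """Draw one horizontal refraction profile of a given archetype.

    M(e) = M0 + a (e/40)^2 + b (e/40) + eps with (a, b) set by the pattern
    (RPM: a=-magnitude; RPH: a=+magnitude; PNS/PTS: b=+/-skew/2, so that
    the nasal-temporal edge difference equals skew_D) and eps ~
    Normal(0, noise_sd) independently per sampled eccentricity.
    """
    if pattern not in _PATTERN_SHAPES:
        raise ValueError(f"unknown refraction pattern {pattern!r}")
    if magnitude_D < 0:
        raise ValueError("magnitude_D must be non-negative")
    if noise_sd_D < 0:
        raise ValueError("noise_sd_D must be non-negative")
    ecc = (
        np.arange(-40.0, 41.0)
        if eccentricities_deg is None
        else np.asarray(eccentricities_deg, dtype=float)
    )
    a, b = _PATTERN_SHAPES[pattern](magnitude_D, skew_D)
    rng = np.random.default_rng(seed)
    u = ecc / 40.0
    M = central_M_D + a * u**2 + b * u
    if noise_sd_D > 0:
        M = M + rng.normal(0.0, noise_sd_D, size=ecc.shape)
    return RefractionProfile(eccentricity_deg=ecc, M=M)


def generate_zernike_field(
    profile: RefractionProfile,
    lens: LensDesign | None = None,
    hoa_params: dict | None = None,
    seed: int = 0,
    subject_id: str = "S00",
    condition: str | None = None,
    grid_x_deg=GRID_X_DEG,
    grid_y_deg=GRID_Y_DEG,
    pupil_diameter_mm: float = 3.0,
    n_scans: int = N_SCANS,
    scan_noise_um: float = 0.005,
    astig_40deg_um: float = 0.6,
    coma_slope_um_per_deg: float = 0.0025,
    hoa_scatter_um: float = 0.01,
    lens_weight_width_deg: float = 10.0,
) -> ZernikeField:
    """Synthesize one Zernike field from a refraction profile and a lens.

    At each grid location the defocus term encodes the horizontal
    refraction M(x) plus the lens's radial power offset; with-the-rule
    astigmatism c(2,+2) grows quadratically with eccentricity, coma
    c(3,+/-1) linearly with the signed field angle, and 4th-6th-order
    terms are drawn once per subject and held constant across the field.
    Each location is "measured" ``n_scans`` times with independent
    coefficient noise and averaged, emulating the four-scan protocol.
    """
    lens = lens or LensDesign.none()
    hoa_params = DEFAULT_HOA_PARAMS if hoa_params is None else hoa_params
    gx = np.asarray(grid_x_deg, dtype=float)
    if profile.eccentricity_deg.min() > gx.min() or profile.eccentricity_deg.max() < gx.max():
        raise ValueError("refraction profile does not cover the measurement grid")
    rng = np.random.default_rng(seed)
    r_mm = pupil_diameter_mm / 2.0

    # subject-level draws (one per subject, shared across the field)
    hoa_draws = {
        nm: rng.normal(base, hoa_scatter_um)
        for nm, (base, _slope) in sorted(hoa_params.items())
    }
    a22 = rng.normal(astig_40deg_um, 0.05)
    coma_h = rng.normal(coma_slope_um_per_deg, 0.2 * abs(coma_slope_um_per_deg))
    coma_v = rng.normal(coma_slope_um_per_deg, 0.2 * abs(coma_slope_um_per_deg))

    terms = zernike_nm_terms(6, min_order=2)
    samples = []
    for y in np.asarray(grid_y_deg, dtype=float):
        for x in gx:
            e = float(np.hypot(x, y))
            M_tot = float(profile.at(x)) + lens.defocus_offset_D(e, lens_weight_width_deg)
            coeffs = {nm: 0.0 for nm in terms}
            coeffs[(2, 0)] = defocus_from_spherical_equivalent(M_tot, r_mm)
            coeffs[(2, 2)] = a22 * (e / 40.0) ** 2
            coeffs[(3, 1)] = coma_h * x
            coeffs[(3, -1)] = coma_v * y
            for nm, (_base, slope) in sorted(hoa_params.items()):
                coeffs[nm] = hoa_draws[nm] + slope * e
            if scan_noise_um > 0:
                noise = rng.normal(0.0, scan_noise_um, size=(n_scans, len(terms)))
                mean_noise = noise.mean(axis=0)
                for t, nm in enumerate(terms):
                    coeffs[nm] += mean_noise[t]
            samples.append(
                ZernikeSample(
                    x_deg=float(x),
                    y_deg=float(y),
                    coeffs=coeffs,
                    pupil_diameter_mm=pupil_diameter_mm,
                )
            )
    return ZernikeField(
        subject_id=subject_id,
        condition=condition or lens.design,
        samples=samples,
    )


@dataclass
class SubjectRecord:
    """One synthetic subject: archetype label and the three measured fields."""

    subject_id: str
    pattern: str
    fields: dict = field(default_factory=dict)  # condition -> ZernikeField


@dataclass
class CohortDataset:
    """A seeded cohort of subjects with all three optical conditions."""

    subjects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for s in self.subjects:
            if set(s.fields) != set(CONDITIONS):
                raise ValueError(
                    f"subject {s.subject_id} must carry exactly the conditions {CONDITIONS}"
                )

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def generate_cohort(
    n_per_pattern: dict[str, int] | None = None,
    seed: int = 0,
    magnitude_D: float = 1.0,
    skew_D: float = 1.0,
    noise_sd_D: float = 0.1,
    central_M_mean_D: float = -3.25,
    central_M_sd_D: float = 1.5,
    scan_noise_um: float = 0.005,
    **field_kwargs,
) -> CohortDataset:
    """Generate a full cohort; default mix is 5 PNS + 4 RPM + 3 RPH + 1 PTS.

    Each subject gets one refraction profile, one set of per-subject
    higher-order draws (shared across conditions, since the eye is the
    same), and three Zernike fields: naked eye, centre-near and
    centre-distance lens.
    """
    mix = dict(DEFAULT_N_PER_PATTERN) if n_per_pattern is None else dict(n_per_pattern)
    for p, n in mix.items():
        if p not in PATTERNS:
            raise ValueError(f"unknown refraction pattern {p!r}")
        if n < 0:
            raise ValueError("subject counts must be non-negative")
    if sum(mix.values()) == 0:
        raise ValueError("cohort must contain at least one subject")

    rng = np.random.default_rng(seed)
    lenses = {
        "naked_eye": LensDesign.none(),
        "centre_near": LensDesign.centre_near(),
        "centre_distance": LensDesign.centre_distance(),
    }
    subjects = []
    idx = 0
    for pattern in PATTERNS:
        for _ in range(mix.get(pattern, 0)):
            idx += 1
            sid = f"S{idx:02d}"
            M0 = float(np.clip(rng.normal(central_M_mean_D, central_M_sd_D), -6.5, -0.75))
            profile_seed = int(rng.integers(2**31))
            subject_seed = int(rng.integers(2**31))
            profile = generate_refraction_profile(
                pattern, magnitude_D, skew_D, noise_sd_D, profile_seed, M0
            )
            fields = {
                condition: generate_zernike_field(
                    profile,
                    lens,
                    seed=subject_seed,
                    subject_id=sid,
                    condition=condition,
                    scan_noise_um=scan_noise_um,
                    **field_kwargs,
                )
                for condition, lens in lenses.items()
            }
            subjects.append(SubjectRecord(subject_id=sid, pattern=pattern, fields=fields))
    return CohortDataset(subjects=subjects, seed=seed)


def extract_refraction_profile(zfield: ZernikeField) -> RefractionProfile:
    """Recover the horizontal refraction profile from a measured field.

    Reads the defocus coefficient along the y = 0 meridian and converts it
    to spherical equivalent; used to classify a subject's peripheral
    refraction archetype from naked-eye data.
    """
    row = sorted(
        (s for s in zfield.samples if abs(s.y_deg) < 1e-9), key=lambda s: s.x_deg
    )
    if len(row) < 2:
        raise ValueError("field has no horizontal meridian row")
    ecc = np.array([s.x_deg for s in row])
    r_mm = row[0].pupil_diameter_mm / 2.0
    M = np.array([spherical_equivalent(s.coeff(2, 0), r_mm) for s in row])
    return RefractionProfile(eccentricity_deg=ecc, M=M)
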