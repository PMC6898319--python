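"""Zernike wavefronts, point-spread functions and refraction conversions.

Zernike convention: OSA/ANSI double indices (n, m) with unit-variance
(Noll) normalisation over the unit pupil; coefficients in micrometres at
the stated pupil diameter.  Wavefront error at pupil coordinates
(rho, theta) is ``W = sum c_nm * N_nm * R_n^|m|(rho) * trig(m theta)``.

The PSF is the squared modulus of the Fourier transform of the
generalised pupil function ``A * exp(i 2 pi W / lambda)``, sampled so
that one PSF pixel subtends exactly the configured angular pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import OpticsConfig

__all__ = [
    "ZernikeSample",
    "ZernikeField",
    "PSFImage",
    "zernike_term_count",
    "zernike_nm_terms",
    "zernike_radial",
    "zernike_basis_value",
    "normalize_low_order",
    "spherical_equivalent",
    "defocus_from_spherical_equivalent",
    "compute_psf",
]

ARCMIN_PER_RAD = 60.0 * 180.0 / math.pi

#: Low-order terms re-referenced to the fovea before image simulation:
#: defocus and the two astigmatism components.
LOW_ORDER_TERMS = ((2, 0), (2, -2), (2, 2))


# ---------------------------------------------------------------------------
# Indexing and polynomial evaluation
# ---------------------------------------------------------------------------

def zernike_term_count(max_order: int) -> int:
    """Number of Zernike terms up to and including radial order ``max_order``."""
    if max_order < 0:
        raise ValueError("max_order must be non-negative")
    return (max_order + 1) * (max_order + 2) // 2


def zernike_nm_terms(max_order: int, min_order: int = 0) -> list[tuple[int, int]]:
    """All (n, m) index pairs with min_order <= n <= max_order."""
    return [
        (n, m)
        for n in range(min_order, max_order + 1)
        for m in range(-n, n + 1, 2)
    ]


def _validate_nm(n: int, m: int) -> None:
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike index pair (n={n}, m={m})")


def zernike_radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_n^|m| evaluated at rho (any array shape)."""
    _validate_nm(n, m_abs)
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for k in range((n - m_abs) // 2 + 1):
        coef = (
            (-1) ** k
            * math.factorial(n - k)
            / (
                math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)
            )
        )
        out += coef * rho ** (n - 2 * k)
    return out


def zernike_basis_value(n: int, m: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Unit-variance Zernike polynomial Z_n^m over the unit pupil."""
    _validate_nm(n, abs(m))
    norm = math.sqrt(2.0 * (n + 1) / (1.0 + (1.0 if m == 0 else 0.0)))
    radial = zernike_radial(n, abs(m), rho)
    if m == 0:
        return norm * radial
    if m > 0:
        return norm * radial * np.cos(m * theta)
    return norm * radial * np.sin(-m * theta)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class ZernikeSample:
    """Zernike expansion at one visual-field location.

    x is positive nasal, y positive superior (degrees); coefficients are a
    mapping (n, m) -> micrometres over a pupil of ``pupil_diameter_mm``.
    Radial orders 0 and 1 (piston/tilt) may be present but are ignored by
    the PSF computation; orders above 6 are rejected.
    """

    x_deg: float
    y_deg: float
    coeffs: dict = field(default_factory=dict)
    pupil_diameter_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be positive")
        for (n, m) in self.coeffs:
            _validate_nm(n, m)
            if n > 6:
                raise ValueError(f"radial order {n} exceeds the 6th-order model")

    @property
    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)

    def coeff(self, n: int, m: int) -> float:
        return float(self.coeffs.get((n, m), 0.0))


@dataclass
class ZernikeField:
    """Per-subject, per-condition set of Zernike samples on the measurement grid."""

    subject_id: str
    condition: str
    samples: list[ZernikeSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[float, float]] = set()
        for s in self.samples:
            key = (round(s.x_deg, 6), round(s.y_deg, 6))
            if key in seen:
                raise ValueError(f"duplicate sample location {key}")
            seen.add(key)

    def sample_at(self, x_deg: float, y_deg: float) -> ZernikeSample:
        key = (round(x_deg, 6), round(y_deg, 6))
        for s in self.samples:
            if (round(s.x_deg, 6), round(s.y_deg, 6)) == key:
                return s
        raise KeyError(f"no sample at ({x_deg}, {y_deg}) degrees")

    @property
    def foveal_sample(self) -> ZernikeSample:
        try:
            return self.sample_at(0.0, 0.0)
        except KeyError:
            raise ValueError("field has no foveal (0, 0) sample") from None

    def locations(self) -> list[tuple[float, float]]:
        return [(s.x_deg, s.y_deg) for s in self.samples]


@dataclass
class PSFImage:
    """Non-negative point-spread grid with angular sampling metadata."""

    values: np.ndarray
    sampling_arcmin: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PSF must be a 2-D grid")
        if np.any(self.values < 0):
            raise ValueError("PSF values must be non-negative")
        if self.sampling_arcmin <= 0:
            raise ValueError("sampling_arcmin must be positive")


# ---------------------------------------------------------------------------
# Refraction conversions
# ---------------------------------------------------------------------------

def spherical_equivalent(c20_um: float, pupil_radius_mm: float) -> float:
    """Spherical-equivalent refraction M (dioptres) from the defocus coefficient.

    M = -4 sqrt(3) c20 / r^2 with c20 in micrometres and r in millimetres;
    positive defocus coefficient means myopic (negative) M.
    """
    if pupil_radius_mm <= 0:
        raise ValueError("pupil_radius_mm must be positive")
    return -4.0 * math.sqrt(3.0) * c20_um / pupil_radius_mm**2


def defocus_from_spherical_equivalent(M_D: float, pupil_radius_mm: float) -> float:
    """Inverse of :func:`spherical_equivalent`: c20 (um) encoding M (D)."""
    if pupil_radius_mm <= 0:
        raise ValueError("pupil_radius_mm must be positive")
    return -M_D * pupil_radius_mm**2 / (4.0 * math.sqrt(3.0))


# ---------------------------------------------------------------------------
# Foveal normalisation
# ---------------------------------------------------------------------------

def normalize_low_order(field_: ZernikeField) -> ZernikeField:
    """Re-reference defocus and astigmatism to the foveal error.

    The foveal values of c(2,0), c(2,-2) and c(2,+2) are subtracted from
    every sample, so the fovea carries exactly zero low-order error and
    peripheral low orders become relative errors.  Higher orders are left
    untouched.
    """
    fov = field_.foveal_sample
    offsets = {nm: fov.coeff(*nm) for nm in LOW_ORDER_TERMS}
    new_samples = []
    for s in field_.samples:
        coeffs = dict(s.coeffs)
        for nm, off in offsets.items():
            coeffs[nm] = s.coeff(*nm) - off
        new_samples.append(replace(s, coeffs=coeffs))
    return ZernikeField(field_.subject_id, field_.condition, new_samples)


# ---------------------------------------------------------------------------
# PSF computation
# ---------------------------------------------------------------------------

def _padded_grid_size(config: OpticsConfig) -> tuple[int, float]:
    """FFT size N and effective pupil span (samples) achieving the exact pitch.

    The DFT of an N-point pupil sampled at pitch dx yields an angular PSF
    pitch of lambda / (N dx).  N is the nearest integer realising the
    requested pitch with the requested pupil sampling; the pupil span is
    then re-derived so the pitch is met exactly.  If no integer N keeps the
    pupil span within 10% of ``pupil_grid_n`` the pitch is unattainable.
    """
    lam_m = config.wavelength_nm * 1e-9
    D_m = config.pupil_diameter_mm * 1e-3
    pitch_rad = config.psf_sampling_arcmin / ARCMIN_PER_RAD
    n_exact = lam_m * config.pupil_grid_n / (pitch_rad * D_m)
    N = int(round(n_exact))
    pupil_span = D_m * pitch_rad * N / lam_m  # samples across the pupil
    if N < config.psf_support_px or abs(pupil_span - config.pupil_grid_n) > 0.1 * config.pupil_grid_n:
        raise ValueError(
            "requested PSF sampling pitch unattainable with this pupil grid"
        )
    return N, pupil_span


def compute_psf(sample: ZernikeSample, config: OpticsConfig | None = None) -> PSFImage:
    """Point-spread function of one Zernike sample.

    Builds the generalised pupil function on a zero-padded grid chosen so
    that the PSF pixel pitch equals ``config.psf_sampling_arcmin`` exactly,
    Fourier-transforms it, crops the central ``psf_support_px`` square and
    renormalises to unit sum.  Piston and tilt terms (n < 2), which only
    offset or translate the image, are ignored.
    """
    config = config or OpticsConfig()
    N, pupil_span = _padded_grid_size(config)

    idx = np.arange(N) - N // 2
    # normalised pupil coordinates: rho = 1 at the pupil edge
    u = idx * (2.0 / pupil_span)
    X, Y = np.meshgrid(u, u)
    rho = np.hypot(X, Y)
    mask = rho <= 1.0

    lam_um = config.wavelength_nm * 1e-3
    theta = np.arctan2(Y, X)
    W = np.zeros((N, N))
    rho_in = rho[mask]
    theta_in = theta[mask]
    for (n, m), c in sample.coeffs.items():
        if n < 2 or c == 0.0:
            continue
        W[mask] += c * zernike_basis_value(n, m, rho_in, theta_in)

    pupil = np.where(mask, np.exp(1j * 2.0 * np.pi * W / lam_um), 0.0)
    psf_full = np.abs(np.fft.fftshift(np.fft.fft2(pupil))) ** 2

    c0 = N // 2
    half = config.psf_support_px // 2
    lo, hi = c0 - half, c0 - half + config.psf_support_px
    if lo < 0 or hi > N:
        raise ValueError("PSF support window exceeds the transform grid")
    window = psf_full[lo:hi, lo:hi]
    window = window / window.sum()
    return PSFImage(values=window, sampling_arcmin=config.psf_sampling_arcmin)


def diffraction_limited_sample(
    x_deg: float = 0.0, y_deg: float = 0.0, pupil_diameter_mm: float = 3.0
) -> ZernikeSample:
    """Aberration-free sample (all coefficients zero) at a field location."""
    return ZernikeSample(x_deg=x_deg, y_deg=y_deg, coeffs={}, pupil_diameter_mm=pupil_diameter_mm)
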