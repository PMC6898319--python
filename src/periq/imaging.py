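"""Eccentricity-specific simulated retinal images.

The simulation chain for one visual-field location is

    reference image -> convolve with the local PSF
                    -> Gaussian low-pass matched to the local neural
                       cutoff frequency
                    -> crop the borders

The neural cutoff frequency is read from a piecewise-linear surface fitted
over literature anchor points (cycles/degree as a function of field
position); inside the convex hull of the anchors the surface interpolates
linearly over a Delaunay triangulation and evaluates to the anchor values
exactly at the anchors, outside it falls back to the nearest anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.signal import fftconvolve

from .config import ImagingConfig, OpticsConfig
from .optics import PSFImage, ZernikeSample, compute_psf, diffraction_limited_sample

__all__ = [
    "ReferenceImage",
    "CutoffAnchor",
    "CutoffSurface",
    "DEFAULT_CUTOFF_ANCHORS",
    "make_reference",
    "convolve_psf",
    "eval_cutoff",
    "gaussian_lowpass",
    "crop_margin",
    "simulate_retinal_image",
]


# ---------------------------------------------------------------------------
# Reference image
# ---------------------------------------------------------------------------

@dataclass
class ReferenceImage:
    """Square grayscale reference image with angular metadata.

    512 x 512 pixels subtending 2 degrees gives 2 * 60 / 512 = 0.234375
    arcmin per pixel, matching the PSF pitch.
    """

    pixels: np.ndarray
    subtense_deg: float = 2.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("reference image must be square")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1 + 1e-12:
            raise ValueError("reference intensities must lie in [0, 1]")

    @property
    def side(self) -> int:
        return self.pixels.shape[0]

    @property
    def sampling_arcmin(self) -> float:
        return self.subtense_deg * 60.0 / self.side


def _builtin_texture(seed: int, side: int) -> np.ndarray:
    """Seeded 1/f-amplitude-spectrum texture, a synthetic natural-image
    stand-in with the spatial statistics of broadband natural scenes."""
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(side)
    fy = np.fft.fftfreq(side)
    FX, FY = np.meshgrid(fx, fy)
    f = np.hypot(FX, FY)
    f[0, 0] = np.inf  # zero the DC amplitude; mean re-added via normalisation
    amplitude = 1.0 / f
    phase = rng.uniform(0.0, 2.0 * np.pi, size=(side, side))
    spectrum = amplitude * np.exp(1j * phase)
    img = np.fft.ifft2(spectrum).real
    img = img - img.min()
    img = img / img.max()
    return img


def make_reference(
    source: str | Path = "builtin",
    seed: int = 0,
    side: int = 512,
    subtense_deg: float = 2.0,
) -> ReferenceImage:
    """Build the reference image.

    ``source="builtin"`` produces a seeded procedural 1/f texture (licence
    free).  A file path is decoded to grayscale, centre-cropped to square
    and rescaled to ``side``; files smaller than ``side`` in either
    dimension are rejected.
    """
    if isinstance(source, str) and source == "builtin":
        pixels = _builtin_texture(seed, side)
        return ReferenceImage(pixels=pixels, subtense_deg=subtense_deg)

    from PIL import Image

    path = Path(source)
    try:
        img = Image.open(path).convert("L")
    except Exception as exc:  # unreadable / not an image
        raise ValueError(f"cannot read reference image {path}: {exc}") from exc
    w, h = img.size
    if w < side or h < side:
        raise ValueError(
            f"reference image must be at least {side}x{side} px, got {w}x{h}"
        )
    short = min(w, h)
    left = (w - short) // 2
    top = (h - short) // 2
    img = img.crop((left, top, left + short, top + short))
    if short != side:
        img = img.resize((side, side), Image.LANCZOS)
    pixels = np.asarray(img, dtype=float) / 255.0
    return ReferenceImage(pixels=np.clip(pixels, 0.0, 1.0), subtense_deg=subtense_deg)


# ---------------------------------------------------------------------------
# Neural cutoff surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffAnchor:
    """One literature anchor of the neural cutoff surface."""

    x_deg: float
    y_deg: float
    f_cutoff_cpd: float

    def __post_init__(self) -> None:
        if self.f_cutoff_cpd <= 0:
            raise ValueError("f_cutoff_cpd must be positive")


# Synthetic fixture of 20 anchors on the five measured meridians
# (y = 0, +/-10, +/-20 deg): foveal cutoff 48 cyc/deg decaying to ~6 cyc/deg
# at 40 deg, with a mild nasal-temporal asymmetry.  Literature-plausible
# placeholder values, not measured data; fully configurable.
DEFAULT_CUTOFF_ANCHORS: tuple[CutoffAnchor, ...] = tuple(
    CutoffAnchor(*t)
    for t in [
        (0.0, 0.0, 48.0),
        (10.0, 0.0, 25.0),
        (-10.0, 0.0, 25.5),
        (20.0, 0.0, 15.0),
        (-20.0, 0.0, 15.5),
        (30.0, 0.0, 9.5),
        (-30.0, 0.0, 10.0),
        (40.0, 0.0, 6.0),
        (-40.0, 0.0, 6.5),
        (0.0, 10.0, 24.0),
        (0.0, -10.0, 23.0),
        (0.0, 20.0, 14.5),
        (0.0, -20.0, 13.5),
        (40.0, 20.0, 5.5),
        (-40.0, 20.0, 5.8),
        (40.0, -20.0, 5.2),
        (-40.0, -20.0, 5.5),
        (20.0, 10.0, 13.5),
        (-20.0, 10.0, 14.0),
        (20.0, -10.0, 13.0),
    ]
)


class CutoffSurface:
    """Piecewise-linear neural cutoff-frequency surface over the visual field.

    Linear interpolation over a Delaunay triangulation of the anchors
    inside their convex hull; nearest-anchor value outside.
    """

    def __init__(self, anchors: tuple[CutoffAnchor, ...] | list[CutoffAnchor] = DEFAULT_CUTOFF_ANCHORS):
        anchors = tuple(anchors)
        if len(anchors) == 0:
            raise ValueError("anchor set must be non-empty")
        self.anchors = anchors
        pts = np.array([(a.x_deg, a.y_deg) for a in anchors])
        vals = np.array([a.f_cutoff_cpd for a in anchors])
        self._nearest = NearestNDInterpolator(pts, vals)
        self._linear = LinearNDInterpolator(pts, vals) if len(anchors) >= 3 else None

    def __call__(self, x_deg, y_deg):
        x = np.asarray(x_deg, dtype=float)
        y = np.asarray(y_deg, dtype=float)
        out = self._nearest(x, y)
        if self._linear is not None:
            lin = self._linear(x, y)
            out = np.where(np.isnan(lin), out, lin)
        return float(out) if np.isscalar(x_deg) and np.isscalar(y_deg) else out

    # -- serialisation -----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("x_deg,y_deg,f_cutoff_cpd\n")
            for a in self.anchors:
                fh.write(f"{a.x_deg!r},{a.y_deg!r},{a.f_cutoff_cpd!r}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CutoffSurface":
        anchors = []
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header[:3] != ["x_deg", "y_deg", "f_cutoff_cpd"]:
                raise ValueError("expected header x_deg,y_deg,f_cutoff_cpd")
            for line in fh:
                if not line.strip():
                    continue
                x, y, f = line.strip().split(",")
                anchors.append(CutoffAnchor(float(x), float(y), float(f)))
        return cls(anchors)


def eval_cutoff(surface: CutoffSurface, x_deg: float, y_deg: float) -> float:
    """Neural cutoff frequency (cycles/degree) at one field location."""
    return float(surface(x_deg, y_deg))


# ---------------------------------------------------------------------------
# Image operations
# ---------------------------------------------------------------------------

def convolve_psf(ref: ReferenceImage | np.ndarray, psf: PSFImage) -> np.ndarray:
    """Blur the reference image with a PSF kernel.

    Linear convolution evaluated over the full reference extent using
    symmetric boundary padding.  Because edge reflection can leak a tiny
    mean shift, the output is rescaled to preserve the input mean exactly
    (the Pearson quality metric is unaffected by this affine factor).
    """
    if isinstance(ref, ReferenceImage):
        if abs(psf.sampling_arcmin - ref.sampling_arcmin) > 1e-9:
            raise ValueError(
                f"PSF pitch {psf.sampling_arcmin} arcmin/px does not match "
                f"reference pitch {ref.sampling_arcmin}"
            )
        image = ref.pixels
    else:
        image = np.asarray(ref, dtype=float)
    k = psf.values.shape[0]
    # kernel centre convention: index k//2 -> pad (k-1)//2 before, k//2 after
    before, after = (k - 1) // 2, k // 2
    padded = np.pad(image, ((before, after), (before, after)), mode="symmetric")
    out = fftconvolve(padded, psf.values, mode="valid")
    mean_out = out.mean()
    if mean_out > 0:
        out = out * (image.mean() / mean_out)
    return out


_SIGMA_FACTORS = {
    # sigma_f = f_cutoff / factor
    "half_amplitude": math.sqrt(2.0 * math.log(2.0)),
    "one_over_e": math.sqrt(2.0),
    "two_sigma": 2.0,
}


def gaussian_lowpass(
    image: np.ndarray,
    f_cutoff_cpd: float,
    sampling_arcmin: float,
    definition: str = "half_amplitude",
) -> np.ndarray:
    """Frequency-domain Gaussian low-pass matched to a neural cutoff.

    Multiplies the spectrum by G(f) = exp(-f^2 / (2 sigma_f^2)) with
    sigma_f = f_cutoff / sqrt(2 ln 2) under the default half-amplitude
    convention (gain exactly 0.5 at f_cutoff); DC gain is exactly 1.
    """
    if f_cutoff_cpd <= 0:
        raise ValueError("f_cutoff_cpd must be positive")
    try:
        sigma_f = f_cutoff_cpd / _SIGMA_FACTORS[definition]
    except KeyError:
        raise ValueError(f"unknown cutoff definition {definition!r}") from None
    image = np.asarray(image, dtype=float)
    ny, nx = image.shape
    d_deg = sampling_arcmin / 60.0  # pixel pitch in degrees
    fx = np.fft.rfftfreq(nx, d=d_deg)  # cycles/degree
    fy = np.fft.fftfreq(ny, d=d_deg)
    F2 = fx[None, :] ** 2 + fy[:, None] ** 2
    gain = np.exp(-F2 / (2.0 * sigma_f**2))
    return np.fft.irfft2(np.fft.rfft2(image) * gain, s=image.shape)


def crop_margin(image: np.ndarray, margin_px: int) -> np.ndarray:
    """Central window after removing ``margin_px`` pixels from each edge."""
    image = np.asarray(image)
    side = min(image.shape)
    if margin_px < 0 or 2 * margin_px >= side:
        raise ValueError(f"margin {margin_px} too large for image side {side}")
    if margin_px == 0:
        return image
    return image[margin_px:-margin_px, margin_px:-margin_px]


def simulate_retinal_image(
    ref: ReferenceImage,
    sample: ZernikeSample,
    surface: CutoffSurface,
    optics: OpticsConfig | None = None,
    imaging: ImagingConfig | None = None,
    include_optics: bool = True,
) -> np.ndarray:
    """Simulated retinal image at one field location.

    With ``include_optics`` the local aberrated PSF is used; without it the
    aberration-free (diffraction-limited) PSF is substituted, giving the
    neural/diffraction-limit path.  Both paths then apply the local neural
    low-pass and the anti-aliasing border crop.
    """
    optics = optics or OpticsConfig()
    imaging = imaging or ImagingConfig()
    if include_optics:
        psf = compute_psf(sample, optics)
    else:
        psf = compute_psf(
            diffraction_limited_sample(sample.x_deg, sample.y_deg, sample.pupil_diameter_mm),
            optics,
        )
    blurred = convolve_psf(ref, psf)
    fc = eval_cutoff(surface, sample.x_deg, sample.y_deg)
    filtered = gaussian_lowpass(blurred, fc, ref.sampling_arcmin, imaging.cutoff_definition)
    return crop_margin(filtered, imaging.crop_margin_px)
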