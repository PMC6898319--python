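"""Cross-correlation quality maps and difference maps.

A quality sample is the zero-lag Pearson correlation between the cropped
reference image and the simulated retinal image at one field location.
Scattered samples (default: every 5 degrees over the central 40 x 40 deg
field) are interpolated to a 40 x 40 map at half-integer degrees; the
difference map is the neural/diffraction-limit map minus the optical map,
i.e. the quality deficit attributable to the eye's (and lens's) optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from .config import PipelineConfig
from .imaging import (
    CutoffSurface,
    ReferenceImage,
    convolve_psf,
    crop_margin,
    eval_cutoff,
    gaussian_lowpass,
    simulate_retinal_image,
)
from .optics import ZernikeField, compute_psf, diffraction_limited_sample

__all__ = [
    "MAP_GRID_DEG",
    "QualityMap",
    "DifferenceMap",
    "cross_correlation",
    "sample_quality",
    "neural_limit_samples",
    "interpolate_map",
    "difference_map",
    "map_rmse",
]

#: 40 map coordinates per axis at half-integer degrees.
MAP_GRID_DEG = np.arange(-19.5, 20.0, 1.0)


@dataclass
class QualityMap:
    """40 x 40 grid of cross-correlation coefficients.

    ``values[i, j]`` corresponds to x = grid_deg[j] (nasal positive),
    y = grid_deg[i] (superior positive).
    """

    values: np.ndarray
    grid_deg: np.ndarray = field(default_factory=lambda: MAP_GRID_DEG.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_deg = np.asarray(self.grid_deg, dtype=float)
        n = len(self.grid_deg)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("quality values must lie in [0, 1]")


@dataclass
class DifferenceMap:
    """Limit-minus-optical quality deficit on the map grid."""

    values: np.ndarray
    grid_deg: np.ndarray = field(default_factory=lambda: MAP_GRID_DEG.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.grid_deg = np.asarray(self.grid_deg, dtype=float)
        n = len(self.grid_deg)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")


def cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-lag Pearson correlation of two images, clamped to [0, 1].

    Identical images give exactly 1; anticorrelated images clamp to 0 so
    the metric ranges from 0 (worst) to 1 (best).  If exactly one image is
    constant the correlation is taken as 0 (no covariation); two constant
    images leave it undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if np.array_equal(a, b):
        if np.ptp(a) == 0:
            raise ValueError("correlation of two constant images is undefined")
        return 1.0
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.sum(da * da))
    vb = float(np.sum(db * db))
    if va == 0.0 and vb == 0.0:
        raise ValueError("correlation of two constant images is undefined")
    if va == 0.0 or vb == 0.0:
        return 0.0
    r = float(np.sum(da * db)) / np.sqrt(va * vb)
    return float(np.clip(r, 0.0, 1.0))


def _resolve_locations(
    config: PipelineConfig, locations: list[tuple[float, float]] | None
) -> list[tuple[float, float]]:
    return list(locations) if locations is not None else config.mapping.locations()


def sample_quality(
    zfield: ZernikeField,
    ref: ReferenceImage,
    surface: CutoffSurface,
    config: PipelineConfig | None = None,
    locations: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float, float]]:
    """Cross-correlation quality at each sampled field location (optics on).

    Each location must carry a Zernike sample in ``zfield``.  Returns
    (x_deg, y_deg, coefficient) triples.
    """
    config = config or PipelineConfig()
    locs = _resolve_locations(config, locations)
    ref_crop = crop_margin(ref.pixels, config.imaging.crop_margin_px)
    out = []
    for (x, y) in locs:
        sample = zfield.sample_at(x, y)  # KeyError if outside measured field
        sim = simulate_retinal_image(
            ref, sample, surface, config.optics, config.imaging, include_optics=True
        )
        out.append((x, y, cross_correlation(sim, ref_crop)))
    return out


def neural_limit_samples(
    ref: ReferenceImage,
    surface: CutoffSurface,
    config: PipelineConfig | None = None,
    locations: list[tuple[float, float]] | None = None,
) -> list[tuple[float, float, float]]:
    """Neural/diffraction-limit quality samples (optics replaced by the
    diffraction-limited pupil).

    The diffraction-limited blur is field-independent, so the convolution
    is computed once and only the local neural low-pass varies.
    """
    config = config or PipelineConfig()
    locs = _resolve_locations(config, locations)
    psf = compute_psf(
        diffraction_limited_sample(pupil_diameter_mm=config.optics.pupil_diameter_mm),
        config.optics,
    )
    blurred = convolve_psf(ref, psf)
    ref_crop = crop_margin(ref.pixels, config.imaging.crop_margin_px)
    out = []
    for (x, y) in locs:
        fc = eval_cutoff(surface, x, y)
        filtered = gaussian_lowpass(
            blurred, fc, ref.sampling_arcmin, config.imaging.cutoff_definition
        )
        sim = crop_margin(filtered, config.imaging.crop_margin_px)
        out.append((x, y, cross_correlation(sim, ref_crop)))
    return out


def interpolate_map(samples: list[tuple[float, float, float]]) -> QualityMap:
    """Interpolate scattered quality samples onto the 40 x 40 map grid.

    Piecewise-linear over a Delaunay triangulation of the sample positions,
    nearest-sample value outside the convex hull, clamped to [0, 1].
    """
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to interpolate a map")
    pts = np.array([(x, y) for x, y, _ in samples])
    vals = np.array([v for _, _, v in samples])
    if np.linalg.matrix_rank(pts - pts[0]) < 2:
        raise ValueError("sample locations are collinear; cannot triangulate")
    linear = LinearNDInterpolator(pts, vals)
    nearest = NearestNDInterpolator(pts, vals)
    X, Y = np.meshgrid(MAP_GRID_DEG, MAP_GRID_DEG)
    out = linear(X, Y)
    nan = np.isnan(out)
    if nan.any():
        out[nan] = nearest(X[nan], Y[nan])
    return QualityMap(values=np.clip(out, 0.0, 1.0))


def difference_map(limit: QualityMap, optical: QualityMap) -> DifferenceMap:
    """Cellwise limit-minus-optical quality deficit."""
    if not np.array_equal(limit.grid_deg, optical.grid_deg):
        raise ValueError("maps are defined on different grids")
    return DifferenceMap(values=limit.values - optical.values, grid_deg=limit.grid_deg.copy())


def map_rmse(diff: DifferenceMap | QualityMap) -> float:
    """Root-mean-square of the map cells: one number for the whole field."""
    return float(np.sqrt(np.mean(np.square(diff.values))))
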