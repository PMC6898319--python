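"""Pipeline configuration.

Every tunable of the analysis lives in one serialisable tree so that a run
is fully described by (input data, PipelineConfig, seed).  All physical
quantities are validated on construction; ``PipelineConfig`` round-trips
losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "OpticsConfig",
    "ImagingConfig",
    "MappingConfig",
    "SegmentationConfig",
    "StatsConfig",
    "PipelineConfig",
]

#: Gaussian low-pass cutoff conventions: gain at f_cutoff is 0.5, 1/e, or
#: the cutoff sits at two standard deviations of the transfer function.
CUTOFF_DEFINITIONS = ("half_amplitude", "one_over_e", "two_sigma")


@dataclass
class OpticsConfig:
    """Physical-optics settings for PSF computation.

    Parameters
    ----------
    wavelength_nm : float
        Monochromatic wavelength of the simulation (green, 532 nm).
    pupil_diameter_mm : float
        Pupil diameter over which Zernike coefficients are defined.
    pupil_grid_n : int
        Requested number of samples across the pupil diameter (>= 128).
    psf_sampling_arcmin : float
        Angular pixel pitch of the PSF; must match the reference image
        pitch (2 deg / 512 px = 0.234375 arcmin/px).
    psf_support_px : int
        Side of the square window the PSF is cropped to (default 128 px,
        i.e. 30 arcmin at the default pitch).
    """

    wavelength_nm: float = 532.0
    pupil_diameter_mm: float = 3.0
    pupil_grid_n: int = 128
    psf_sampling_arcmin: float = 0.234375
    psf_support_px: int = 128

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")
        if self.pupil_diameter_mm <= 0:
            raise ValueError("pupil_diameter_mm must be positive")
        if self.pupil_grid_n < 128:
            raise ValueError("pupil_grid_n must be at least 128")
        if self.psf_sampling_arcmin <= 0:
            raise ValueError("psf_sampling_arcmin must be positive")
        if self.psf_support_px < 2:
            raise ValueError("psf_support_px must be at least 2")


@dataclass
class ImagingConfig:
    """Retinal-image simulation settings."""

    crop_margin_px: int = 64
    cutoff_definition: str = "half_amplitude"

    def __post_init__(self) -> None:
        if self.crop_margin_px < 0:
            raise ValueError("crop_margin_px must be non-negative")
        if self.cutoff_definition not in CUTOFF_DEFINITIONS:
            raise ValueError(
                f"cutoff_definition must be one of {CUTOFF_DEFINITIONS}"
            )


@dataclass
class MappingConfig:
    """Quality-map sampling and interpolation grid.

    The default sample locations mirror the 5-degree stepwise evaluation of
    the measured field: x in {-20..+20} every 5 deg on the five vertical
    fixation meridians y in {-20,-10,0,+10,+20} (45 locations), then
    interpolated to a 40 x 40 map at half-integer degrees.
    """

    sample_x_deg: tuple[float, ...] = tuple(float(v) for v in range(-20, 25, 5))
    sample_y_deg: tuple[float, ...] = (-20.0, -10.0, 0.0, 10.0, 20.0)

    def locations(self) -> list[tuple[float, float]]:
        return [(x, y) for y in self.sample_y_deg for x in self.sample_x_deg]


@dataclass
class SegmentationConfig:
    """Refraction-pattern classification thresholds (dioptres/degrees)."""

    skew_delta_D: float = 0.25
    central_halfwidth_deg: float = 5.0
    edge_window_deg: tuple[float, float] = (30.0, 40.0)

    def __post_init__(self) -> None:
        lo, hi = self.edge_window_deg
        if not 0 < lo < hi:
            raise ValueError("edge_window_deg must be an increasing positive pair")
        if self.skew_delta_D < 0:
            raise ValueError("skew_delta_D must be non-negative")


@dataclass
class StatsConfig:
    """Statistical-analysis settings."""

    alpha: float = 0.05
    alpha_strict: float = 0.01
    mwu_mode: str = "auto"  # auto | exact | approx
    fullfield_pooling: str = "cells"  # cells | subject_means
    paired_rmse_test: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.alpha_strict < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.mwu_mode not in ("auto", "exact", "approx"):
            raise ValueError("mwu_mode must be auto, exact or approx")
        if self.fullfield_pooling not in ("cells", "subject_means"):
            raise ValueError("fullfield_pooling must be 'cells' or 'subject_means'")


@dataclass
class PipelineConfig:
    """Top-level configuration tree; `seed` feeds every random draw."""

    optics: OpticsConfig = field(default_factory=OpticsConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    reference_seed: int = 0
    seed: int = 0

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        mapping = d.get("mapping", {})
        if "sample_x_deg" in mapping:
            mapping = dict(mapping)
            mapping["sample_x_deg"] = tuple(mapping["sample_x_deg"])
            mapping["sample_y_deg"] = tuple(mapping["sample_y_deg"])
        seg = d.get("segmentation", {})
        if "edge_window_deg" in seg:
            seg = dict(seg)
            seg["edge_window_deg"] = tuple(seg["edge_window_deg"])
        return cls(
            optics=OpticsConfig(**d.get("optics", {})),
            imaging=ImagingConfig(**d.get("imaging", {})),
            mapping=MappingConfig(**mapping),
            segmentation=SegmentationConfig(**seg),
            stats=StatsConfig(**d.get("stats", {})),
            reference_seed=d.get("reference_seed", 0),
            seed=d.get("seed", 0),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(s))

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
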