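"""Visual-field segmentation and peripheral-refraction classification.

Maps are segmented into four 45-degree sectors (nasal / temporal /
superior / inferior, split along the +/-45 degree diagonals) crossed with
concentric 5-degree annuli; subjects are classified into one of four
peripheral-refraction archetypes from their naked-eye refraction profile:

    PNS  nasal positively skewed        (nasal edge more hyperopic)
    PTS  temporal positively skewed     (temporal edge more hyperopic)
    RPM  relative peripheral myopia     (both edges more myopic)
    RPH  relative peripheral hyperopia  (both edges more hyperopic)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SegmentationConfig
from .mapping import DifferenceMap, QualityMap

__all__ = [
    "SECTORS",
    "ANNULI_DEG",
    "PATTERN_LABELS",
    "SegmentKey",
    "segment_cells",
    "segment_map",
    "classify_pattern",
]

SECTORS = ("nasal", "temporal", "superior", "inferior")
#: Inner radii of the half-open 5-degree annuli [r, r+5).
ANNULI_DEG = (0, 5, 10, 15)
PATTERN_LABELS = ("PNS", "RPM", "RPH", "PTS")


@dataclass(frozen=True)
class SegmentKey:
    """One of the 16 sector x annulus segments."""

    sector: str
    annulus_deg: int  # inner radius of the [r, r+5) band

    def __post_init__(self) -> None:
        if self.sector not in SECTORS:
            raise ValueError(f"unknown sector {self.sector!r}")
        if self.annulus_deg not in ANNULI_DEG:
            raise ValueError(f"annulus inner radius must be one of {ANNULI_DEG}")


def all_segment_keys() -> list[SegmentKey]:
    return [SegmentKey(s, a) for s in SECTORS for a in ANNULI_DEG]


def _sector_of(x: float, y: float) -> str | None:
    """Sector by strict dominance; None on the diagonals |x| == |y|."""
    ax, ay = abs(x), abs(y)
    if ax == ay:
        return None
    if x > ay:
        return "nasal"
    if -x > ay:
        return "temporal"
    if y > ax:
        return "superior"
    return "inferior"


def segment_cells(grid_deg: np.ndarray) -> dict[SegmentKey, list[tuple[int, int]]]:
    """Cell indices (i, j) of each segment on a square map grid.

    A cell at (x, y) with eccentricity e = sqrt(x^2 + y^2) belongs to the
    annulus [5*floor(e/5), ...) if e < 20 and to the sector that strictly
    dominates; cells exactly on the +/-45-degree diagonals and cells at
    e >= 20 are excluded from every segment.
    """
    grid = np.asarray(grid_deg, dtype=float)
    cells: dict[SegmentKey, list[tuple[int, int]]] = {k: [] for k in all_segment_keys()}
    for i, y in enumerate(grid):
        for j, x in enumerate(grid):
            e = float(np.hypot(x, y))
            if e >= 20.0:
                continue
            sector = _sector_of(x, y)
            if sector is None:
                continue
            annulus = int(5 * (e // 5))
            cells[SegmentKey(sector, annulus)].append((i, j))
    return cells


def segment_map(qmap: QualityMap | DifferenceMap) -> dict[SegmentKey, np.ndarray]:
    """Map cell values grouped by segment.

    Requires the standard half-integer 40 x 40 grid; under that convention
    the smallest segments (innermost annuli) hold exactly 16 cells.
    """
    grid = qmap.grid_deg
    if len(grid) != 40 or not np.allclose(grid, np.arange(-19.5, 20.0, 1.0)):
        raise ValueError("segmentation expects the standard 40x40 half-integer grid")
    cells = segment_cells(grid)
    return {
        key: np.array([qmap.values[i, j] for (i, j) in idx])
        for key, idx in cells.items()
    }


def classify_pattern(
    profile,
    config: SegmentationConfig | None = None,
) -> str:
    """Classify a refraction profile into one of the four archetypes.

    Compares the mean refraction of the nasal and temporal outer-edge
    windows against the central mean: a nasal-temporal asymmetry at least
    ``skew_delta_D`` dioptres labels the profile PNS or PTS (by sign);
    otherwise the sign of the mean relative peripheral refraction decides
    RPM (myopic shift) versus RPH (hyperopic shift).
    """
    config = config or SegmentationConfig()
    ecc = np.asarray(profile.eccentricity_deg, dtype=float)
    M = np.asarray(profile.M, dtype=float)
    lo, hi = config.edge_window_deg
    if ecc.min() > -hi or ecc.max() < hi:
        raise ValueError(f"profile must cover +/-{hi} degrees")
    central = M[np.abs(ecc) <= config.central_halfwidth_deg]
    nasal = M[(ecc >= lo) & (ecc <= hi)]
    temporal = M[(ecc <= -lo) & (ecc >= -hi)]
    if len(central) == 0 or len(nasal) == 0 or len(temporal) == 0:
        raise ValueError("profile sampling too sparse for classification windows")
    d_nasal = float(nasal.mean() - central.mean())
    d_temporal = float(temporal.mean() - central.mean())
    asymmetry = d_nasal - d_temporal
    if abs(asymmetry) >= config.skew_delta_D:
        return "PNS" if asymmetry > 0 else "PTS"
    return "RPM" if (d_nasal + d_temporal) / 2.0 < 0 else "RPH"
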