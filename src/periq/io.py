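"""File formats: Zernike-field CSV, map CSV, cutoff-anchor CSV, report JSON.

The Zernike CSV schema is tabular, one row per measured location:

    subject_id, condition, x_deg, y_deg, pupil_mm, c_2_0, c_2_m2, c_2_p2, ...

with one ``c_{n}_{m}`` column per term for radial orders 2..6 (negative m
encoded as ``m<k>``, positive as ``p<k>``).  Unknown columns are ignored
with a warning; missing term columns and duplicate locations are errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import MAP_GRID_DEG, DifferenceMap, QualityMap
from .optics import ZernikeField, ZernikeSample, zernike_nm_terms
from .segmentation import segment_cells
from .stats import StudyReport

__all__ = [
    "term_column",
    "zernike_columns",
    "write_zernike_csv",
    "read_zernike_csv",
    "write_map_csv",
    "read_map_csv",
    "write_segments_csv",
    "write_report_json",
    "read_report_json",
]

logger = logging.getLogger("periq")

_META_COLUMNS = ["subject_id", "condition", "x_deg", "y_deg", "pupil_mm"]


def term_column(n: int, m: int) -> str:
    """Column name of the (n, m) coefficient, e.g. (2, -2) -> ``c_2_m2``."""
    if m < 0:
        return f"c_{n}_m{-m}"
    if m > 0:
        return f"c_{n}_p{m}"
    return f"c_{n}_0"


def zernike_columns() -> list[str]:
    return [term_column(n, m) for n, m in zernike_nm_terms(6, min_order=2)]


def write_zernike_csv(fields: list[ZernikeField] | ZernikeField, path: str | Path) -> None:
    if isinstance(fields, ZernikeField):
        fields = [fields]
    terms = zernike_nm_terms(6, min_order=2)
    rows = []
    for zf in fields:
        for s in zf.samples:
            row = {
                "subject_id": zf.subject_id,
                "condition": zf.condition,
                "x_deg": s.x_deg,
                "y_deg": s.y_deg,
                "pupil_mm": s.pupil_diameter_mm,
            }
            for nm in terms:
                row[term_column(*nm)] = s.coeff(*nm)
            rows.append(row)
    # 17 significant digits so coefficients survive the round trip bit-exactly
    pd.DataFrame(rows, columns=_META_COLUMNS + zernike_columns()).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_zernike_csv(path: str | Path) -> list[ZernikeField]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = _META_COLUMNS + zernike_columns()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        logger.warning("ignoring unknown column(s): %s", ", ".join(unknown))
    dup = df.duplicated(subset=["subject_id", "condition", "x_deg", "y_deg"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate location row: "
            f"{first['subject_id']}/{first['condition']} at "
            f"({first['x_deg']}, {first['y_deg']})"
        )
    terms = zernike_nm_terms(6, min_order=2)
    fields = []
    for (sid, cond), grp in df.groupby(["subject_id", "condition"], sort=True):
        samples = [
            ZernikeSample(
                x_deg=float(r["x_deg"]),
                y_deg=float(r["y_deg"]),
                coeffs={nm: float(r[term_column(*nm)]) for nm in terms},
                pupil_diameter_mm=float(r["pupil_mm"]),
            )
            for _, r in grp.iterrows()
        ]
        fields.append(ZernikeField(subject_id=str(sid), condition=str(cond), samples=samples))
    return fields


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def write_map_csv(qmap: QualityMap | DifferenceMap, path: str | Path) -> None:
    """Write a map as a matrix CSV with a 2-line grid header."""
    grid = qmap.grid_deg
    with open(path, "w") as fh:
        fh.write(f"# origin_deg={float(grid[0])!r}\n")
        fh.write(f"# spacing_deg={float(grid[1] - grid[0])!r}\n")
        np.savetxt(fh, qmap.values, delimiter=",", fmt="%.17g")


def read_map_csv(path: str | Path, kind: str = "quality") -> QualityMap | DifferenceMap:
    with open(path) as fh:
        origin = float(fh.readline().split("=", 1)[1])
        spacing = float(fh.readline().split("=", 1)[1])
        values = np.loadtxt(fh, delimiter=",")
    grid = origin + spacing * np.arange(values.shape[0])
    if kind == "quality":
        return QualityMap(values=values, grid_deg=grid)
    if kind == "difference":
        return DifferenceMap(values=values, grid_deg=grid)
    raise ValueError("kind must be 'quality' or 'difference'")


def write_segments_csv(path: str | Path, grid_deg: np.ndarray = MAP_GRID_DEG) -> None:
    """Export the segment assignment of every map cell (x, y, sector, annulus)."""
    cells = segment_cells(grid_deg)
    rows = []
    for key, idx in cells.items():
        for (i, j) in idx:
            rows.append(
                {
                    "x_deg": grid_deg[j],
                    "y_deg": grid_deg[i],
                    "sector": key.sector,
                    "annulus_deg": key.annulus_deg,
                }
            )
    pd.DataFrame(rows).sort_values(["y_deg", "x_deg"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report_json(report: StudyReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json())


def read_report_json(path: str | Path) -> StudyReport:
    return StudyReport.from_json(Path(path).read_text())
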