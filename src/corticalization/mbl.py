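"""Marginal bone loss (MBL) measurement on calibrated radiographs.

MBL is the distance from the implant platform to the bottom of the
peri-implant bone defect, in millimetres.  The radiograph is calibrated by
marking two points a known physical distance apart (typically the implant
of known length), and MBL is then the Euclidean distance between the two
user-marked landmarks scaled by ``mm_per_pixel``.  A vertical-projection
mode is available for images with residual tilt conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "MBLMeasurement",
    "calibrate_mm_per_pixel",
    "measure_mbl",
    "measure_landmark_table",
    "per_implant_mbl",
]

Point = tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class MBLMeasurement:
    implant_id: str
    visit: int
    side: str  # mesial | distal
    platform_point: Point
    defect_bottom_point: Point
    mbl_mm: float

    def __post_init__(self) -> None:
        if self.mbl_mm < 0:
            raise ValueError("MBL cannot be negative")


def calibrate_mm_per_pixel(known_length_mm: float, p1: Point, p2: Point) -> float:
    """mm/px from two points a known physical distance apart.

    E.g. a 10 mm implant spanning 200 px gives 0.05 mm/px.
    """
    if known_length_mm <= 0:
        raise ValueError("known length must be positive")
    dist = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if dist == 0:
        raise ValueError("calibration endpoints coincide")
    return known_length_mm / dist


def measure_mbl(
    platform_point: Point,
    defect_bottom_point: Point,
    mm_per_pixel: float,
    *,
    implant_id: str = "",
    visit: int = 0,
    side: str = "mesial",
    projection: bool = False,
) -> MBLMeasurement:
    """Platform-to-defect-bottom distance in millimetres.

    Euclidean by default; with ``projection=True`` only the vertical (row)
    component is measured, assuming the image is aligned to the implant axis.
    Coincident points give 0 mm (bone at the platform level).
    """
    if mm_per_pixel is None or not mm_per_pixel > 0:
        raise ValueError("calibration (mm_per_pixel) must be set and positive")
    dr = defect_bottom_point[0] - platform_point[0]
    dc = defect_bottom_point[1] - platform_point[1]
    px = abs(dr) if projection else math.hypot(dr, dc)
    return MBLMeasurement(
        implant_id=implant_id,
        visit=visit,
        side=side,
        platform_point=tuple(platform_point),
        defect_bottom_point=tuple(defect_bottom_point),
        mbl_mm=px * mm_per_pixel,
    )


def measure_landmark_table(
    landmarks: pd.DataFrame | str | Path,
    mm_per_pixel: float,
    *,
    projection: bool = False,
) -> pd.DataFrame:
    """Apply :func:`measure_mbl` to a landmark CSV/DataFrame.

    Expected columns: implant_id, visit, side, platform_row, platform_col,
    defect_row, defect_col.
    """
    if not isinstance(landmarks, pd.DataFrame):
        landmarks = pd.read_csv(landmarks)
    required = {
        "implant_id", "visit", "side",
        "platform_row", "platform_col", "defect_row", "defect_col",
    }
    missing = required - set(landmarks.columns)
    if missing:
        raise ValueError(f"landmark table missing columns: {sorted(missing)}")
    rows = []
    for rec in landmarks.itertuples():
        m = measure_mbl(
            (rec.platform_row, rec.platform_col),
            (rec.defect_row, rec.defect_col),
            mm_per_pixel,
            implant_id=str(rec.implant_id),
            visit=int(rec.visit),
            side=str(rec.side),
            projection=projection,
        )
        rows.append(
            {
                "implant_id": m.implant_id,
                "visit": m.visit,
                "side": m.side,
                "mbl_mm": m.mbl_mm,
            }
        )
    return pd.DataFrame(rows)


def per_implant_mbl(measurements: pd.DataFrame, rule: str = "max") -> pd.DataFrame:
    """Reduce mesial/distal MBL to one value per (implant, visit).

    Default is the worst site (``max``); ``mean`` is available.
    """
    if rule not in ("max", "mean"):
        raise ValueError("rule must be 'max' or 'mean'")
    agg = (
        measurements.groupby(["implant_id", "visit"])["mbl_mm"]
        .agg(rule)
        .reset_index()
    )
    return agg
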