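"""Reading calibrated grayscale radiographs and extracting rectangular ROIs.

Intraoral radiographs arrive as 8-bit PNG, 8/16-bit grayscale TIFF, or
single-frame grayscale DICOM.  Before texture analysis the image is rotated so
the implant long axis is vertical; rectangular regions of interest (ROIs) are
then cut at the mesial and distal implant neck.

Conventions: 0-based row-major coordinates; ROI boxes are half-open
``[origin, origin + extent)``; positive rotation angles are counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "GreyImage",
    "ROISpec",
    "AxisAlignment",
    "read_image",
    "write_image",
    "align_to_implant_axis",
    "extract_roi",
    "read_roi_specs",
    "MIN_ROI_PIXELS",
]

#: minimum number of pixels for stable texture statistics
MIN_ROI_PIXELS = 64

#: ITU-R 601 luma weights used when an RGB image is explicitly converted
_LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GreyImage:
    """A calibrated 2D grayscale raster.

    Parameters
    ----------
    pixels : ndarray of int
        2D array of grey values, shape ``(rows, cols)``.
    bit_depth : int
        Declared depth, 8 or 12.  All values must lie in
        ``[0, 2**bit_depth - 1]``.
    mm_per_pixel : float or None
        Spatial calibration; ``None`` until set (see :mod:`.mbl`).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("image must be 2D with both dimensions >= 1")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"unsupported bit depth {self.bit_depth}")
        vmax = (1 << self.bit_depth) - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise ValueError(
                f"pixel values outside [0, {vmax}] for declared {self.bit_depth}-bit depth"
            )
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest at the implant neck.

    The box is half-open: rows ``origin_row .. origin_row + height - 1`` and
    likewise for columns.  ``label`` distinguishes the mesial and distal site.
    """

    label: str
    origin_row: int
    origin_col: int
    height: int = 50
    width: int = 30
    implant_id: str = ""
    visit: str = ""

    def __post_init__(self) -> None:
        if self.label not in ("mesial", "distal"):
            raise ValueError("ROI label must be 'mesial' or 'distal'")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI extent must be positive")
        if self.height * self.width < MIN_ROI_PIXELS:
            raise ValueError(
                f"ROI of {self.height * self.width} px is below the "
                f"{MIN_ROI_PIXELS}-pixel minimum for stable texture statistics"
            )


@dataclass(frozen=True)
class AxisAlignment:
    """Rotation that maps the implant long axis onto the image vertical.

    Either pass ``rotation_deg`` directly or derive it from the two implant
    platform endpoints via :meth:`from_platform_points`.
    """

    rotation_deg: float
    platform_points: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not (-90.0 < self.rotation_deg <= 90.0):
            raise ValueError("rotation_deg must lie in (-90, 90]")

    @classmethod
    def from_platform_points(
        cls,
        p1: tuple[float, float],
        p2: tuple[float, float],
    ) -> "AxisAlignment":
        """Rotation making the line p1-p2 (the implant platform) horizontal.

        The platform is perpendicular to the implant long axis, so levelling
        the platform verticalizes the axis.  Points are (row, col).
        """
        dr = p2[0] - p1[0]
        dc = p2[1] - p1[1]
        if dr == 0 and dc == 0:
            raise ValueError("platform endpoints coincide")
        angle = math.degrees(math.atan2(dr, dc))
        # fold to (-90, 90]: the platform line has no orientation
        if angle <= -90.0:
            angle += 180.0
        elif angle > 90.0:
            angle -= 180.0
        return cls(rotation_deg=angle, platform_points=(tuple(p1), tuple(p2)))


def _luminance(arr: np.ndarray) -> np.ndarray:
    w = np.asarray(_LUMA_WEIGHTS)
    return np.rint(arr[..., :3].astype(float) @ w).astype(np.int64)


def read_image(
    path: str | Path,
    format: str | None = None,
    *,
    bit_depth: int | None = None,
    convert_rgb: bool = False,
    mm_per_pixel: float | None = None,
) -> GreyImage:
    """Read a radiograph from PNG, TIFF, or DICOM.

    Parameters
    ----------
    path : str or Path
        Image file.  Must exist.
    format : {'PNG', 'TIFF', 'DICOM'}, optional
        Inferred from the suffix when omitted.
    bit_depth : int, optional
        Override the declared depth (e.g. 12-bit data stored in 16-bit TIFF
        containers).  Defaults to 8 for 8-bit storage, to the DICOM
        ``BitsStored`` tag, and to 16 for 16-bit PNG/TIFF.
    convert_rgb : bool
        Convert multi-channel input to luminance with fixed ITU-R 601
        weights (0.299, 0.587, 0.114).  Without this flag an RGB image is an
        error: silent conversion could hide an acquisition problem.
    mm_per_pixel : float, optional
        Spatial calibration to attach.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = {
            ".png": "PNG",
            ".tif": "TIFF",
            ".tiff": "TIFF",
            ".dcm": "DICOM",
            ".dicom": "DICOM",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer image format from suffix {suffix!r}")
    format = format.upper()

    if format == "DICOM":
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = np.asarray(ds.pixel_array)
        if arr.ndim == 3:
            raise ValueError("multi-frame or multi-channel DICOM is not supported")
        depth = bit_depth if bit_depth is not None else int(ds.BitsStored)
        return GreyImage(arr.astype(np.int64), bit_depth=depth, mm_per_pixel=mm_per_pixel)

    if format == "TIFF":
        import tifffile

        arr = np.asarray(tifffile.imread(str(path)))
    elif format == "PNG":
        with Image.open(path) as im:
            arr = np.asarray(im)
    else:
        raise ValueError(f"unsupported format {format!r}")

    if arr.ndim == 3:
        if not convert_rgb:
            raise ValueError(
                "multi-channel image: pass convert_rgb=True to reduce to luminance"
            )
        arr = _luminance(arr)
    if arr.size == 0:
        raise ValueError("zero-size image")
    if bit_depth is None:
        bit_depth = 8 if arr.dtype.itemsize == 1 else 16
    return GreyImage(arr.astype(np.int64), bit_depth=bit_depth, mm_per_pixel=mm_per_pixel)


def write_image(image: GreyImage, path: str | Path, format: str | None = None) -> None:
    """Write a :class:`GreyImage` to PNG or TIFF, preserving pixel values."""
    path = Path(path)
    if format is None:
        format = "TIFF" if path.suffix.lower() in (".tif", ".tiff") else "PNG"
    format = format.upper()
    arr = image.pixels
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    if format == "TIFF":
        import tifffile

        tifffile.imwrite(str(path), arr.astype(dtype))
    elif format == "PNG":
        mode = "L" if dtype is np.uint8 else "I;16"
        Image.fromarray(arr.astype(dtype), mode=mode).save(path, format="PNG")
    else:
        raise ValueError(f"unsupported format {format!r}")


def align_to_implant_axis(
    image: GreyImage,
    alignment: AxisAlignment,
    *,
    rois: list[ROISpec] | None = None,
) -> GreyImage:
    """Rotate the radiograph so the implant long axis is vertical.

    Bilinear interpolation; the output frame covers the full rotated image and
    out-of-frame pixels are filled with a -1 sentinel so that no fabricated
    texture can leak into an ROI.  Multiples of 90 degrees are remapped
    exactly (no interpolation).  ``mm_per_pixel`` is preserved — rotation is
    rigid.
    """
    angle = alignment.rotation_deg
    if angle == 0.0:
        out = GreyImage(image.pixels.copy(), image.bit_depth, image.mm_per_pixel)
    elif angle % 90.0 == 0.0:
        k = int(round(angle / 90.0)) % 4
        out = GreyImage(np.rot90(image.pixels, k=k).copy(), image.bit_depth, image.mm_per_pixel)
    else:
        rotated = ndimage.rotate(
            image.pixels.astype(float),
            angle,
            reshape=True,
            order=1,
            mode="constant",
            cval=-1.0,
        )
        vmax = (1 << image.bit_depth) - 1
        sentinel = rotated < -0.5
        rotated = np.clip(np.rint(rotated), 0, vmax).astype(np.int64)
        rotated[sentinel] = -1
        # bypass range validation for the sentinel fill
        out = GreyImage.__new__(GreyImage)
        out.pixels = rotated
        out.bit_depth = image.bit_depth
        out.mm_per_pixel = image.mm_per_pixel
    if rois is not None:
        for roi in rois:
            patch = extract_roi(out, roi)
            if (patch < 0).any():
                raise ValueError(
                    f"ROI {roi.label!r} falls on out-of-frame pixels after rotation"
                )
    return out


def extract_roi(image: GreyImage, roi: ROISpec) -> np.ndarray:
    """Cut the ROI patch out of the image; values are untouched.

    Returns exactly ``(roi.height, roi.width)`` pixels.  Raises if the box is
    not fully inside the image.
    """
    rows, cols = image.pixels.shape
    r0, c0 = roi.origin_row, roi.origin_col
    r1, c1 = r0 + roi.height, c0 + roi.width
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ValueError(
            f"ROI [{r0}:{r1}, {c0}:{c1}] exceeds image bounds {rows}x{cols}"
        )
    return image.pixels[r0:r1, c0:c1].copy()


def read_roi_specs(path: str | Path) -> list[ROISpec]:
    """Load ROI specifications from CSV.

    Expected columns: implant_id, visit, label, origin_row, origin_col,
    height, width.
    """
    df = pd.read_csv(path)
    required = {"implant_id", "visit", "label", "origin_row", "origin_col", "height", "width"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV missing columns: {sorted(missing)}")
    return [
        ROISpec(
            label=str(row.label),
            origin_row=int(row.origin_row),
            origin_col=int(row.origin_col),
            height=int(row.height),
            width=int(row.width),
            implant_id=str(row.implant_id),
            visit=str(row.visit),
        )
        for row in df.itertuples()
    ]
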