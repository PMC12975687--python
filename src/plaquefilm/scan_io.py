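"""Scanned-film image I/O and circular-ROI pixel statistics.

Films are digitised on a flatbed scanner (reflection mode, nominally
300 dpi) and analysed in physical millimetre coordinates.  The coordinate
convention used throughout the package is:

* origin at the **centre of the top-left pixel**,
* x increasing rightward (columns), y increasing downward (rows),
* ``mm = pixel_index * 25.4 / dpi``.

Only the red channel of an RGB scan is used for densitometry because of
its superior dose sensitivity for diacetylene-based radiochromic films.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

MM_PER_INCH = 25.4


class ScanReadError(ValueError):
    """Raised when a scan file cannot be read or is unsupported."""


@dataclass(frozen=True)
class ScanImage:
    """A scanner raster with physical-resolution metadata.

    Parameters
    ----------
    pixels
        2-D (grayscale) or 3-D ``(rows, cols, channels)`` unsigned-integer
        array of raw scanner pixel values.
    dpi
        Scan resolution in dots per inch; must be positive.
    bit_depth
        Scanner bit depth per channel, 8..16.  All pixel values must lie
        in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    dpi: float
    bit_depth: int

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if not (8 <= self.bit_depth <= 16):
            raise ScanReadError(f"unsupported bit depth {self.bit_depth}")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D or 3-D")
        pv_max = int(self.pixels.max(initial=0))
        if pv_max > 2**self.bit_depth - 1:
            raise ValueError("pixel values exceed bit depth")

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def mm_per_pixel(self) -> float:
        return MM_PER_INCH / self.dpi

    @property
    def extent_mm(self) -> tuple[float, float]:
        """(width, height) spanned by pixel centres, in mm."""
        rows, cols = self.pixels.shape[:2]
        return ((cols - 1) * self.mm_per_pixel, (rows - 1) * self.mm_per_pixel)


@dataclass(frozen=True)
class RoiCircle:
    """Circular region of interest in physical (mm) coordinates."""

    center_x_mm: float
    center_y_mm: float
    diameter_mm: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


@dataclass(frozen=True)
class RoiStat:
    """Mean / SD of the pixel values whose centres fall inside an ROI."""

    mean_pv: float
    sd_pv: float
    n_pixels: int

    def __post_init__(self) -> None:
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if self.sd_pv < 0:
            raise ValueError("sd_pv must be >= 0")


def _dpi_from_tags(tif: tifffile.TiffFile) -> float | None:
    page = tif.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is None or unit is None:
        return None
    unit_value = int(getattr(unit.value, "value", unit.value))
    if unit_value not in (2, 3):  # NONE: resolution tag carries no physical unit
        return None
    num, den = res.value if isinstance(res.value, tuple) else (res.value, 1)
    if den == 0 or num == 0:
        return None
    dpi = num / den
    if unit_value == 3:  # centimeter
        dpi *= 2.54
    return float(dpi)


def read_scan(path: str | Path, dpi: float | None = None) -> ScanImage:
    """Read a TIFF scan, taking dpi from the resolution tags.

    Parameters
    ----------
    path
        TIFF file, 8- or 16-bit, grayscale or RGB.
    dpi
        Explicit resolution override; required when the file carries no
        usable resolution tag.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pixels = tif.asarray()
            file_dpi = _dpi_from_tags(tif)
    except (OSError, ValueError, IndexError, tifffile.TiffFileError) as exc:
        raise ScanReadError(f"unreadable scan: {path} ({exc})") from exc
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ScanReadError(f"unreadable scan: {path} (no image data)")
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ScanReadError(f"unsupported pixel dtype {pixels.dtype}")
    bit_depth = pixels.dtype.itemsize * 8
    if bit_depth > 16:
        raise ScanReadError(f"unsupported bit depth {bit_depth}")
    resolved = dpi if dpi is not None else file_dpi
    if resolved is None:
        raise ScanReadError(f"no dpi metadata in {path}; pass dpi explicitly")
    return ScanImage(pixels=pixels, dpi=float(resolved), bit_depth=bit_depth)


def write_scan(img: ScanImage, path: str | Path) -> None:
    """Write a ScanImage as TIFF with resolution tags set from ``img.dpi``."""
    tifffile.imwrite(str(path), img.pixels, resolution=(img.dpi, img.dpi), resolutionunit="INCH")


def extract_red_channel(img: ScanImage) -> ScanImage:
    """Return the red plane of an RGB scan (identity for grayscale)."""
    if img.channels == 1:
        return img
    if img.channels != 3:
        raise ValueError(f"expected 1 or 3 channels, got {img.channels}")
    return ScanImage(pixels=img.pixels[:, :, 0], dpi=img.dpi, bit_depth=img.bit_depth)


def roi_mask(img: ScanImage, roi: RoiCircle) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the ROI circle.

    A pixel belongs to the ROI iff its centre is at distance <= radius
    from the ROI centre (ties at the exact radius are included).
    """
    if img.channels != 1:
        raise ValueError("roi statistics require a single-channel image")
    s = img.mm_per_pixel
    r = roi.diameter_mm / 2.0
    w_mm, h_mm = img.extent_mm
    if not (0.0 <= roi.center_x_mm - r and roi.center_x_mm + r <= w_mm and 0.0 <= roi.center_y_mm - r and roi.center_y_mm + r <= h_mm):
        raise ValueError(f"ROI {roi.label or roi} extends outside the image")
    rows, cols = img.pixels.shape
    # Restrict to the bounding box; the mask is exact within it.
    j0 = max(int(np.floor((roi.center_x_mm - r) / s)), 0)
    j1 = min(int(np.ceil((roi.center_x_mm + r) / s)), cols - 1)
    i0 = max(int(np.floor((roi.center_y_mm - r) / s)), 0)
    i1 = min(int(np.ceil((roi.center_y_mm + r) / s)), rows - 1)
    jj, ii = np.meshgrid(np.arange(j0, j1 + 1), np.arange(i0, i1 + 1))
    d2 = (jj * s - roi.center_x_mm) ** 2 + (ii * s - roi.center_y_mm) ** 2
    mask = np.zeros((rows, cols), dtype=bool)
    mask[i0 : i1 + 1, j0 : j1 + 1] = d2 <= r * r * (1 + 1e-12)
    return mask


def roi_stats(img: ScanImage, roi: RoiCircle) -> RoiStat:
    """Mean and population SD of pixel values inside a circular ROI."""
    mask = roi_mask(img, roi)
    values = img.pixels[mask].astype(np.float64)
    if values.size == 0:
        raise ValueError("ROI contains no pixel centres; enlarge it or increase dpi")
    return RoiStat(mean_pv=float(values.mean()), sd_pv=float(values.std(ddof=0)), n_pixels=int(values.size))


def read_roi_table(path: str | Path) -> list[RoiCircle]:
    """Read an ROI list from CSV (center_x_mm, center_y_mm, diameter_mm, label)."""
    df = pd.read_csv(path)
    required = {"center_x_mm", "center_y_mm", "diameter_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    labels = df["label"] if "label" in df.columns else [""] * len(df)
    return [
        RoiCircle(center_x_mm=float(x), center_y_mm=float(y), diameter_mm=float(d), label=str(lab))
        for x, y, d, lab in zip(df["center_x_mm"], df["center_y_mm"], df["diameter_mm"], labels)
    ]
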