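"""Planar dose verification at the 33 certified reference points.

Film ROI readings at the grid points are converted to absolute dose
through the densitometry + calibration chain and compared point by
point with the certified planar reference doses:

    diff% = 100 * (measured - reference) / reference

The 5 %-of-maximum exclusion filter is applied on the *reference*
doses, so the excluded point set is reproducible regardless of
measurement noise.  Region summaries (mean and population SD of the
absolute differences) are cumulative over the nested R1 / R2 / R3
point sets, and per-axis profiles can be extracted for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from plaquefilm.calibration import CalibrationCurve, dose_from_netod
from plaquefilm.densitometry import delta_net_od, net_od, reading_from_rois, sd_net_od
from plaquefilm.plaque_geometry import AXIS_VECTORS, ReferenceGrid, low_dose_filter
from plaquefilm.scan_io import RoiCircle, ScanImage, extract_red_channel, roi_stats

REGIONS = ("R1", "R2", "R3")


@dataclass(frozen=True)
class PointDoses:
    """Per-grid-point measured doses with their netOD statistics."""

    doses_Gy: tuple[float, ...]
    delta_netods: tuple[float, ...]
    sd_netods: tuple[float, ...]


@dataclass(frozen=True)
class PlanarComparison:
    """Measured-vs-reference planar comparison with region summaries."""

    per_point: pd.DataFrame  # point_id, axis, index, measured_Gy, reference_Gy, diff_pct, region, kept
    region_summary: pd.DataFrame  # region, n, mean_pct, sd_pct (cumulative point sets)
    excluded_points: tuple[int, ...]

    def region_stats(self, region: str) -> tuple[int, float, float]:
        row = self.region_summary.set_index("region").loc[region]
        return int(row["n"]), float(row["mean_pct"]), float(row["sd_pct"])


def measure_planar(
    pre: ScanImage,
    post: ScanImage,
    grid: ReferenceGrid,
    curve: CalibrationCurve,
    zero_film_netod: float = 0.0,
    p_bg: float = 0.0,
    roi_diameter_mm: float = 1.0,
    origin_mm: tuple[float, float] | None = None,
    rotation_deg: float = 0.0,
) -> PointDoses:
    """Convert ROI readings at every grid point into absolute dose.

    ``origin_mm`` is the image position of the grid centre (defaults to
    the image centre); grid y points up while image y points down, so
    grid coordinates are flipped in y when mapped onto the scan.
    ``origin_mm`` and ``rotation_deg`` together express the manual
    film-alignment offset (no automatic registration is attempted).
    """
    pre = extract_red_channel(pre)
    post = extract_red_channel(post)
    if pre.pixels.shape != post.pixels.shape:
        raise ValueError("pre and post scans must have identical shape")
    if origin_mm is None:
        w_mm, h_mm = post.extent_mm
        origin_mm = (w_mm / 2.0, h_mm / 2.0)
    cos_t, sin_t = np.cos(np.deg2rad(rotation_deg)), np.sin(np.deg2rad(rotation_deg))
    doses, dnetods, sds = [], [], []
    for point in grid.points:
        px = cos_t * point.x_mm - sin_t * point.y_mm
        py = sin_t * point.x_mm + cos_t * point.y_mm
        roi = RoiCircle(
            center_x_mm=origin_mm[0] + px,
            center_y_mm=origin_mm[1] - py,
            diameter_mm=roi_diameter_mm,
            label=f"{point.axis}{point.index:+d}",
        )
        reading = reading_from_rois(roi_stats(pre, roi), roi_stats(post, roi), p_bg=p_bg)
        # noise at unirradiated points can push dnetOD slightly negative;
        # such points read as zero dose (and fall to the 5 % filter anyway)
        x = max(delta_net_od(net_od(reading), zero_film_netod), 0.0)
        doses.append(dose_from_netod(curve, x))
        dnetods.append(x)
        sds.append(sd_net_od(reading))
    return PointDoses(doses_Gy=tuple(doses), delta_netods=tuple(dnetods), sd_netods=tuple(sds))


def compare_planar(measured, reference, grid: ReferenceGrid) -> PlanarComparison:
    """Point-by-point relative comparison with cumulative region summaries.

    ``measured`` and ``reference`` are 33-vectors aligned with the grid
    point order; ``reference`` is the certified planar dose set on
    which the 5 % filter operates.
    """
    m = np.asarray(measured, dtype=float)
    r = np.asarray(reference, dtype=float)
    if m.shape != r.shape or m.size != len(grid.points):
        raise ValueError("measured/reference must align with the 33 grid points")
    kept = set(int(i) for i in low_dose_filter(r))
    diff_pct = np.full(m.shape, np.nan)
    idx = np.array(sorted(kept))
    diff_pct[idx] = 100.0 * (m[idx] - r[idx]) / r[idx]
    per_point = pd.DataFrame(
        {
            "point_id": np.arange(len(grid.points)),
            "axis": [p.axis for p in grid.points],
            "index": [p.index for p in grid.points],
            "region": [p.region for p in grid.points],
            "measured_Gy": m,
            "reference_Gy": r,
            "diff_pct": diff_pct,
            "kept": [i in kept for i in range(len(grid.points))],
        }
    )
    rows = []
    for region in REGIONS:
        members = [i for i in grid.region_indices(region) if i in kept]
        a = np.abs(diff_pct[members])
        rows.append(
            {
                "region": region,
                "n": len(members),
                "mean_pct": float(a.mean()) if members else float("nan"),
                "sd_pct": float(a.std(ddof=0)) if members else float("nan"),
            }
        )
    excluded = tuple(i for i in range(len(grid.points)) if i not in kept)
    return PlanarComparison(per_point=per_point, region_summary=pd.DataFrame(rows), excluded_points=excluded)


def extract_axis_profile(measured, grid: ReferenceGrid, axis: str) -> list[tuple[float, float]]:
    """Ordered (signed position mm, dose) along one axis, centre included."""
    if axis not in AXIS_VECTORS:
        raise ValueError(f"unknown axis {axis!r}; expected one of {sorted(AXIS_VECTORS)}")
    m = np.asarray(measured, dtype=float)
    entries = []
    for i, p in enumerate(grid.points):
        if p.axis == axis or p.axis == "center":
            entries.append((p.index * grid.spacing_mm, float(m[i])))
    entries.sort(key=lambda t: t[0])
    return entries
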