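"""Plaque models, the 33-point certified reference grid, and the 5 % filter.

Three Ru-106 applicator geometries are built in:

* **CCA** — fully circular, 15.3 mm active diameter;
* **COB** — optic-nerve notch, 19.8 mm;
* **CIB** — iris notch, 20.2 mm.

The certified planar reference points are laid out along four axes
(x, y and the two diagonals d1, d2) through the plaque centre: one
shared centre point plus indices -4..+4 (excluding 0) on each axis at
multiples of the per-model point spacing, 33 points in all.  Nested
radial regions group them cumulatively:

* R1 (innermost): centre + |index| <= 2  -> 17 points,
* R2: adds |index| = 3                   -> 25 points,
* R3 (outermost): adds |index| = 4       -> 33 points.

Points receiving less than 5 % of the maximum planar dose are excluded
from comparisons; peripheral points of the notched models routinely
fall below that threshold.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: innermost region reached at |axis index| <= these bounds
_REGION_BOUNDS = {"R1": 2, "R2": 3, "R3": 4}

#: axis unit vectors (x rightward, y upward in plaque coordinates)
AXIS_VECTORS = {
    "x": (1.0, 0.0),
    "y": (0.0, 1.0),
    "d1": (math.sqrt(0.5), math.sqrt(0.5)),
    "d2": (-math.sqrt(0.5), math.sqrt(0.5)),
}


@dataclass(frozen=True)
class PlaqueModel:
    """Geometry and certified reference data for one applicator model."""

    name: str
    diameter_mm: float
    notch: str  # none | optic | iris
    point_spacing_mm: float
    film_radius_mm: float
    certified_ratio_pct: float | None = None
    certified_cax: tuple[tuple[float, float], ...] | None = None  # (depth_mm, normalised dose)
    certified_planar: tuple[float, ...] | None = None  # 33 doses in grid order
    notch_start_radius_mm: float | None = None
    notch_half_angle_deg: float = 25.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0 or self.point_spacing_mm <= 0:
            raise ValueError("diameter and point spacing must be positive")
        if self.notch not in ("none", "optic", "iris"):
            raise ValueError(f"unknown notch type {self.notch!r}")


@dataclass(frozen=True)
class GridPoint:
    axis: str  # x | y | d1 | d2 | center
    index: int  # -4..4; 0 only for the centre
    x_mm: float
    y_mm: float
    region: str  # innermost region containing the point


@dataclass(frozen=True)
class ReferenceGrid:
    """The 33 certified planar reference points of one plaque model."""

    points: tuple[GridPoint, ...]
    spacing_mm: float

    def __post_init__(self) -> None:
        if len(self.points) != 33:
            raise ValueError(f"reference grid must have 33 points, got {len(self.points)}")

    def region_indices(self, region: str) -> np.ndarray:
        """Cumulative point indices of a region (R1 subset of R2 subset of R3)."""
        bound = _REGION_BOUNDS[region]
        return np.array([i for i, p in enumerate(self.points) if abs(p.index) <= bound])

    def coordinates(self) -> np.ndarray:
        return np.array([[p.x_mm, p.y_mm] for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": [p.axis for p in self.points],
                "index": [p.index for p in self.points],
                "x_mm": [p.x_mm for p in self.points],
                "y_mm": [p.y_mm for p in self.points],
                "region": [p.region for p in self.points],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _innermost_region(index: int) -> str:
    a = abs(index)
    for region, bound in _REGION_BOUNDS.items():
        if a <= bound:
            return region
    raise ValueError(f"axis index {index} out of range")


def build_reference_grid(model: PlaqueModel) -> ReferenceGrid:
    """Lay out the 33-point grid: centre + indices +-1..4 on each of 4 axes.

    Point positions are in the flattened-film (arc-length) coordinate
    frame centred on the plaque axis.
    """
    s = model.point_spacing_mm
    if 4 * s > model.film_radius_mm:
        raise ValueError("grid exceeds film: 4 x spacing beyond the flattened film radius")
    points: list[GridPoint] = [GridPoint("center", 0, 0.0, 0.0, "R1")]
    for axis, (ux, uy) in AXIS_VECTORS.items():
        for idx in (-4, -3, -2, -1, 1, 2, 3, 4):
            points.append(GridPoint(axis, idx, idx * s * ux, idx * s * uy, _innermost_region(idx)))
    return ReferenceGrid(points=tuple(points), spacing_mm=s)


def low_dose_filter(doses, threshold_fraction: float = 0.05) -> np.ndarray:
    """Indices of points receiving at least ``threshold_fraction`` of the max dose.

    The rule is "exclude points receiving *less than* 5 % of the
    maximum", so a point exactly at the threshold is kept.  The
    maximum-dose point always survives.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size == 0:
        raise ValueError("empty dose vector")
    peak = doses.max()
    if peak <= 0:
        raise ValueError("no signal: all doses are zero or negative")
    return np.flatnonzero(doses >= threshold_fraction * peak - 1e-12 * peak)


def _model_from_payload(payload: dict) -> PlaqueModel:
    cax = payload.get("certified_cax")
    planar = payload.get("certified_planar")
    return PlaqueModel(
        name=payload["name"],
        diameter_mm=payload["diameter_mm"],
        notch=payload["notch"],
        point_spacing_mm=payload["point_spacing_mm"],
        film_radius_mm=payload["film_radius_mm"],
        certified_ratio_pct=payload.get("certified_ratio_pct"),
        certified_cax=tuple(tuple(row) for row in cax) if cax else None,
        certified_planar=tuple(planar) if planar else None,
        notch_start_radius_mm=payload.get("notch_start_radius_mm"),
        notch_half_angle_deg=payload.get("notch_half_angle_deg", 25.0),
    )


def load_model(name_or_path: str | Path) -> PlaqueModel:
    """Load a built-in model (``"CCA"``, ``"COB"``, ``"CIB"``) or a JSON file."""
    name = str(name_or_path)
    if name.upper() in ("CCA", "COB", "CIB"):
        text = resources.files("plaquefilm").joinpath("data", f"{name.lower()}.json").read_text()
    else:
        text = Path(name_or_path).read_text()
    return _model_from_payload(json.loads(text))
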