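"""Synthetic dose fields and scan pairs for end-to-end pipeline testing.

No public film-scan data exist for this measurement geometry, so the
package generates its own: ground-truth planar dose fields with the
qualitative structure of a Ru-106 plaque (central plateau, steep
peripheral fall-off, an attenuated notch sector for the COB/CIB
models), pushed through a film forward model

    dnetOD(D) = a*D + b*D**n          (true forward response)
    P = Pbg + (P0 - Pbg) * 10**(-dnetOD)

with additive, per-pixel Gaussian scanner noise on both the
pre-irradiation and post-irradiation images, quantised to the scanner
bit depth.  Identical seeds produce bit-identical images.

The same analytic field doubles as the *synthetic* certified planar
reference (the manufacturer's certificate values are not public), so
measured-vs-certified comparisons exercise real estimation error —
film noise, quantisation, calibration-form mismatch — against an
exactly known reference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from plaquefilm.calibration import CalibrationCurve
from plaquefilm.plaque_geometry import PlaqueModel, ReferenceGrid, build_reference_grid
from plaquefilm.scan_io import MM_PER_INCH, ScanImage, write_scan

#: radial width (mm) of the logistic dose fall-off at the plaque edge
FALLOFF_WIDTH_MM = 1.0

#: dose attenuation factor inside a notch sector (silver substrate only)
NOTCH_ATTENUATION = 0.02


def default_true_curve() -> CalibrationCurve:
    """The generator's true forward film response.

    A weakly saturating two-term power law: near-linear below ~3 Gy
    with a mild supralinear correction, typical of diacetylene-based
    radiochromic film read in reflection.  dnetOD(2.4 Gy) ~ 0.33.
    """
    return CalibrationCurve(form="forward", a=0.14, b=-0.002, n=2.2, dose_range_Gy=(0.0, 2.5))


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything that fixes one synthetic scan-pair realisation."""

    model: PlaqueModel
    true_curve: CalibrationCurve = field(default_factory=default_true_curve)
    p0_mean: float = 40000.0
    p_bg: float = 1000.0
    pixel_noise_sd: float = 200.0  # 0.5 % of p0_mean
    dpi: float = 300.0
    bit_depth: int = 16
    seed: int = 0
    exposure_minutes: float = 15.0
    dose_rate_mGy_per_min: float = 120.1

    def __post_init__(self) -> None:
        if self.p0_mean <= self.p_bg:
            raise ValueError("p0_mean must exceed p_bg")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.true_curve.form != "forward":
            raise ValueError("true_curve must be forward-form (dose -> dnetOD)")

    def with_seed(self, seed: int) -> "SyntheticSpec":
        return replace(self, seed=seed)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "model": self.model.name,
            "true_curve": json.loads(self.true_curve.to_json()),
            "p0_mean": self.p0_mean,
            "p_bg": self.p_bg,
            "pixel_noise_sd": self.pixel_noise_sd,
            "dpi": self.dpi,
            "bit_depth": self.bit_depth,
            "seed": self.seed,
            "exposure_minutes": self.exposure_minutes,
            "dose_rate_mGy_per_min": self.dose_rate_mGy_per_min,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def make_reference_cax(model: PlaqueModel):
    """Quartic fit through the model's certified CAX table (2-mm normalised)."""
    from plaquefilm.cax_analysis import DepthDoseProfile, fit_quartic

    if model.certified_cax is None:
        raise ValueError(f"model {model.name} carries no certified CAX table")
    depths, doses = zip(*model.certified_cax)
    return fit_quartic(DepthDoseProfile(depths_mm=tuple(depths), doses=tuple(doses)))


def planar_dose(model: PlaqueModel, x_mm, y_mm, center_dose_Gy: float = 1.8):
    """Analytic planar dose (Gy) at flattened-film coordinates (x, y).

    Radially symmetric logistic plateau/fall-off:

        D(r) = D0 * L(r) / L(0),   L(r) = 1 / (1 + exp((r - R) / w))

    with R the active radius and w = 1 mm, so the dose drops below 5 %
    of the centre value about 3 mm outside the active radius.  For the
    notched models a sector (centred on +y, beyond the notch start
    radius) is attenuated to the silver-substrate leakage level.
    """
    if center_dose_Gy <= 0:
        raise ValueError("center dose must be positive")
    x = np.asarray(x_mm, dtype=float)
    y = np.asarray(y_mm, dtype=float)
    r = np.hypot(x, y)
    R = model.diameter_mm / 2.0
    w = FALLOFF_WIDTH_MM
    level = 1.0 / (1.0 + np.exp((r - R) / w))
    level = level / (1.0 / (1.0 + np.exp(-R / w)))
    if model.notch != "none":
        rn = model.notch_start_radius_mm if model.notch_start_radius_mm is not None else R
        half = np.deg2rad(model.notch_half_angle_deg)
        theta = np.abs(np.arctan2(x, y))  # angle from the +y axis
        ramp_r = 1.0 / (1.0 + np.exp(-(r - rn) / 0.15))
        ramp_t = 1.0 / (1.0 + np.exp(-(half - theta) / np.deg2rad(2.0)))
        level = level * (1.0 - (1.0 - NOTCH_ATTENUATION) * ramp_r * ramp_t)
    return center_dose_Gy * level


def make_planar_field(model: PlaqueModel, center_dose_Gy: float = 1.8, size_mm: float = 36.0, dpi: float = 300.0) -> np.ndarray:
    """Raster of the analytic planar dose field, centred in a square image."""
    if size_mm <= 0:
        raise ValueError("extent must be positive")
    s = MM_PER_INCH / dpi
    n = int(round(size_mm / s)) + 1
    coords = np.arange(n) * s - (n - 1) * s / 2.0
    xx, yy = np.meshgrid(coords, coords)
    # image y (rows) points down; plaque y points up
    return planar_dose(model, xx, -yy, center_dose_Gy)


def synthetic_certified_planar(model: PlaqueModel, center_dose_Gy: float = 1.8, grid: ReferenceGrid | None = None) -> tuple[float, ...]:
    """Synthetic stand-in for the manufacturer's certified 33 planar doses.

    Evaluates the analytic planar field at the reference-grid points, in
    grid order.  These values are *generated*, not certified: they make
    the measured-vs-reference comparison well-posed in the absence of a
    public certificate.
    """
    if grid is None:
        grid = build_reference_grid(model)
    xy = grid.coordinates()
    return tuple(float(v) for v in planar_dose(model, xy[:, 0], xy[:, 1], center_dose_Gy))


def film_forward_model(dose_map: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator | None = None) -> tuple[ScanImage, ScanImage]:
    """Turn a dose map (Gy) into a pre/post scan-image pair.

    Per pixel: dnetOD from the true forward curve, then
    ``P = Pbg + (P0 - Pbg) * 10**(-dnetOD)``; seeded Gaussian noise is
    added to both images, which are clipped and quantised to the
    scanner bit depth.
    """
    dose_map = np.asarray(dose_map, dtype=float)
    if np.any(dose_map < 0):
        raise ValueError("negative doses in field")
    dnetod = spec.true_curve(dose_map)
    signal = (spec.p0_mean - spec.p_bg) * np.power(10.0, -dnetod)
    if np.any(signal < 0.5):
        raise ValueError("response saturated: post-irradiation signal below one count")
    post_clean = spec.p_bg + signal
    pre_clean = np.full_like(dose_map, spec.p0_mean)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    pv_max = 2**spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth <= 8 else np.uint16

    def digitise(clean: np.ndarray) -> np.ndarray:
        noisy = clean + rng.normal(0.0, spec.pixel_noise_sd, size=clean.shape) if spec.pixel_noise_sd > 0 else clean
        return np.clip(np.rint(noisy), 0, pv_max).astype(dtype)

    pre = ScanImage(pixels=digitise(pre_clean), dpi=spec.dpi, bit_depth=spec.bit_depth)
    post = ScanImage(pixels=digitise(post_clean), dpi=spec.dpi, bit_depth=spec.bit_depth)
    return pre, post


def uniform_dose_map(dose_Gy: float, size_mm: float = 8.0, dpi: float = 300.0) -> np.ndarray:
    """Square uniform dose map (e.g. a calibration-film centre region)."""
    s = MM_PER_INCH / dpi
    n = int(round(size_mm / s)) + 1
    return np.full((n, n), float(dose_Gy))


def simulate_dataset(spec: SyntheticSpec, out_dir: str | Path, center_dose_Gy: float = 1.8, size_mm: float = 36.0) -> dict:
    """Write a planar scan pair plus its truth to ``out_dir``.

    Emits ``pre.tif``, ``post.tif``, ``truth_dose.csv`` (the dose field
    raster) and ``spec.json``; returns the file paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    field_map = make_planar_field(spec.model, center_dose_Gy, size_mm=size_mm, dpi=spec.dpi)
    pre, post = film_forward_model(field_map, spec)
    paths = {
        "pre": out / "pre.tif",
        "post": out / "post.tif",
        "truth": out / "truth_dose.csv",
        "spec": out / "spec.json",
    }
    write_scan(pre, paths["pre"])
    write_scan(post, paths["post"])
    np.savetxt(paths["truth"], field_map, delimiter=",", fmt="%.6g")
    spec.to_json(paths["spec"])
    return {k: str(v) for k, v in paths.items()}
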