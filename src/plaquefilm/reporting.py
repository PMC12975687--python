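"""QA report assembly: orchestrates the full pipeline with pass/fail verdicts.

A QA run covers, for one plaque model:

* calibration — fit the inverse dose-response from calibration film
  readings (or load a saved curve);
* dual-depth check — the 3 mm / 1 mm central-axis dose ratio against
  the certified value;
* planar check — 33-point measured-vs-certified comparison summarised
  by region;
* uncertainty budget — experimental/fitting/total percentages with
  k = 2 expansion at representative doses.

Default tolerances: ratio within +-2 percentage points of certified,
cumulative region mean difference <= 5 %, expanded (k = 2) uncertainty
<= 11 % (the conventional certification bound this method aims to
improve on).  All are config-overridable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from plaquefilm import densitometry, synthetic_data
from plaquefilm.calibration import CalibrationCurve, build_schedule, fit_forward, fit_inverse, dose_from_netod, netod_from_dose
from plaquefilm.cax_analysis import dual_depth_ratio
from plaquefilm.plaque_geometry import PlaqueModel, build_reference_grid, load_model
from plaquefilm.planar_analysis import compare_planar, measure_planar
from plaquefilm.scan_io import RoiCircle, read_scan, roi_stats
from plaquefilm.synthetic_data import SyntheticSpec, film_forward_model, make_planar_field, synthetic_certified_planar, uniform_dose_map
from plaquefilm.uncertainty import budget_for_doses

logger = logging.getLogger("plaquefilm")

DEFAULT_TOLERANCES = {
    "ratio_pp": 2.0,
    "region_mean_pct": 5.0,
    "expanded_pct": 11.0,
}

DEFAULT_SCHEDULE_MIN = (2.5, 5.0, 10.0, 15.0, 20.0)
DEFAULT_RATE_MGY_PER_MIN = 120.1


@dataclass(frozen=True)
class Verdict:
    name: str
    value: float
    target: float
    tolerance: float
    passed: bool


def check_tolerance(value: float, target: float, tol: float, name: str = "") -> Verdict:
    """Pass iff |value - target| <= tol."""
    if tol < 0:
        raise ValueError("tolerance must be >= 0")
    return Verdict(name=name, value=float(value), target=float(target), tolerance=float(tol), passed=abs(value - target) <= tol)


@dataclass
class QaReport:
    plaque: str
    cax_ratio: dict  # measured_pct, certified_pct, difference_pp
    planar: list[dict]  # region summaries
    budget: list[dict]  # per-dose uncertainty budgets
    verdicts: list[Verdict]
    calibration: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(v.passed for v in self.verdicts)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        payload["passed"] = self.passed
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "QaReport":
        text = Path(str(source)).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload.pop("passed", None)
        payload["verdicts"] = [Verdict(**v) for v in payload["verdicts"]]
        return cls(**payload)

    def summary(self) -> str:
        lines = [f"QA report — plaque {self.plaque}: {'PASS' if self.passed else 'FAIL'}"]
        r = self.cax_ratio
        lines.append(
            f"  dual-depth ratio: measured {r['measured_pct']:.1f}% vs certified {r['certified_pct']:.1f}% "
            f"(diff {r['difference_pp']:+.1f} pp)"
        )
        for row in self.planar:
            lines.append(f"  planar {row['region']}: n={row['n']}, mean |diff| {row['mean_pct']:.1f}% +- {row['sd_pct']:.1f}%")
        for b in self.budget:
            lines.append(
                f"  budget @ {b['dose_Gy']:.2f} Gy: exp {b['sd_exp_pct']:.2f}%, fit {b['sd_fit_pct']:.2f}%, "
                f"total {b['sd_tot_pct']:.2f}%, expanded(k={b['k']:.0f}) {b['expanded_pct']:.2f}%"
            )
        for v in self.verdicts:
            lines.append(
                f"  [{'pass' if v.passed else 'FAIL'}] {v.name}: {v.value:.2f} vs {v.target:.2f} (tol {v.tolerance:.2f})"
            )
        return "\n".join(lines)


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def calibrate_from_synthetic(spec: SyntheticSpec, times_min=DEFAULT_SCHEDULE_MIN, roi_diameter_mm: float = 4.0):
    """Generate calibration films at the schedule doses and fit both curve forms.

    Returns ``(inverse_curve, forward_curve, table)`` where ``table``
    lists (time_min, dose_Gy, delta_netod, sd_netod) per film, the 0 Gy
    control included as the exact (0, 0) anchor.
    """
    schedule = build_schedule(times_min, spec.dose_rate_mGy_per_min)
    rng = np.random.default_rng(spec.seed)
    size_mm = roi_diameter_mm + 2.0
    center = size_mm / 2.0
    roi = RoiCircle(center_x_mm=center, center_y_mm=center, diameter_mm=roi_diameter_mm)

    def read_pair(dose: float):
        pre, post = film_forward_model(uniform_dose_map(dose, size_mm=size_mm, dpi=spec.dpi), spec, rng=rng)
        return densitometry.reading_from_rois(roi_stats(pre, roi), roi_stats(post, roi), p_bg=spec.p_bg)

    zero_reading = read_pair(0.0)
    netod_zero = densitometry.net_od(zero_reading)
    doses = [0.0]
    dnetods = [0.0]  # exact anchor from the 0 Gy normalisation
    sds = [densitometry.sd_net_od(zero_reading)]
    table = [{"time_min": 0.0, "dose_Gy": 0.0, "delta_netod": 0.0, "sd_netod": sds[0]}]
    for t, dose in zip(schedule.times_min, schedule.doses_Gy):
        reading = read_pair(dose)
        x = densitometry.delta_net_od(densitometry.net_od(reading), netod_zero)
        s = densitometry.sd_net_od(reading)
        doses.append(dose)
        dnetods.append(x)
        sds.append(s)
        table.append({"time_min": t, "dose_Gy": dose, "delta_netod": x, "sd_netod": s})
    inverse = fit_inverse(dnetods, doses)
    forward = fit_forward(doses, dnetods)
    logger.info("calibration fitted: inverse r2=%.6f, forward r2=%.6f", inverse.r2, forward.r2)
    return inverse, forward, table


def measure_dual_depth_ratio(spec: SyntheticSpec, curve: CalibrationCurve, dose_1mm_Gy: float, roi_diameter_mm: float = 1.0):
    """Simulate the two stacked films (1 mm and 3 mm depth) and measure the ratio.

    The true 3-mm dose follows the model's certified dual-depth ratio;
    doses are scaled into the calibrated range for film measurement and
    the (scale-invariant) ratio is computed from the measured pair.
    """
    certified = spec.model.certified_ratio_pct
    if certified is None:
        raise ValueError(f"model {spec.model.name} has no certified dual-depth ratio")
    true_doses = {"1mm": dose_1mm_Gy, "3mm": dose_1mm_Gy * certified / 100.0}
    rng = np.random.default_rng(spec.seed + 1)
    size_mm = roi_diameter_mm + 2.0
    center = size_mm / 2.0
    roi = RoiCircle(center_x_mm=center, center_y_mm=center, diameter_mm=roi_diameter_mm)
    measured = {}
    for key, dose in true_doses.items():
        pre, post = film_forward_model(uniform_dose_map(dose, size_mm=size_mm, dpi=spec.dpi), spec, rng=rng)
        reading = densitometry.reading_from_rois(roi_stats(pre, roi), roi_stats(post, roi), p_bg=spec.p_bg)
        measured[key] = dose_from_netod(curve, densitometry.net_od(reading))
    ratio = dual_depth_ratio(measured["1mm"], measured["3mm"])
    return ratio, measured


def run_qa(config: dict) -> QaReport:
    """Execute the full QA workflow from a structured config.

    Config sections (synthetic mode):

    * ``model`` — plaque name (CCA/COB/CIB) or model-JSON path;
    * ``seed`` — master seed for the synthetic scans;
    * ``synthetic`` — ``center_dose_Gy``, optional noise/pixel levels;
    * ``calibration`` — ``times_min`` and ``rate_mGy_per_min``, or a
      ``curve`` path to a saved inverse fit;
    * ``scans`` — ``pre``/``post`` TIFF paths for a measured planar
      pair (omitted in synthetic mode: the pair is generated);
    * ``tolerances`` — overrides of :data:`DEFAULT_TOLERANCES`;
    * ``budget_doses_Gy`` — doses at which the budget is reported.
    """
    model = config["model"]
    model = load_model(model) if isinstance(model, str) else model
    seed = int(config.get("seed", 0))
    syn = dict(config.get("synthetic", {}))
    center_dose = float(syn.pop("center_dose_Gy", 1.8))
    spec = SyntheticSpec(model=model, seed=seed, **syn)
    tolerances = {**DEFAULT_TOLERANCES, **config.get("tolerances", {})}
    provenance = {"seed": seed, "model": model.name, "tolerances": tolerances}

    # --- calibration ------------------------------------------------------
    cal_cfg = config.get("calibration", {})
    if "curve" in cal_cfg:
        curve = CalibrationCurve.from_json(cal_cfg["curve"])
        cal_info = {"source": str(cal_cfg["curve"])}
    else:
        times = tuple(cal_cfg.get("times_min", DEFAULT_SCHEDULE_MIN))
        rate = float(cal_cfg.get("rate_mGy_per_min", DEFAULT_RATE_MGY_PER_MIN))
        spec_cal = dataclasses.replace(spec, dose_rate_mGy_per_min=rate)
        curve, _forward, table = calibrate_from_synthetic(spec_cal, times)
        cal_info = {"times_min": list(times), "rate_mGy_per_min": rate, "r2": curve.r2, "a": curve.a, "b": curve.b, "n": curve.n}

    # --- dual-depth ratio -------------------------------------------------
    ratio_dose = min(1.8, curve.dose_range_Gy[1])
    ratio_measured, _ = measure_dual_depth_ratio(spec, curve, ratio_dose)
    certified = model.certified_ratio_pct
    ratio_injection = float(config.get("inject_ratio_error_pp", 0.0))  # fault injection for self-tests
    ratio_measured += ratio_injection
    cax_ratio = {
        "measured_pct": ratio_measured,
        "certified_pct": certified,
        "difference_pp": ratio_measured - certified,
    }

    # --- planar comparison ------------------------------------------------
    grid = build_reference_grid(model)
    if "scans" in config:
        pre = read_scan(config["scans"]["pre"])
        post = read_scan(config["scans"]["post"])
    else:
        field_map = make_planar_field(model, center_dose, dpi=spec.dpi)
        pre, post = film_forward_model(field_map, spec.with_seed(seed + 2))
    reference = config.get("reference_planar")
    if reference is None:
        reference = model.certified_planar or synthetic_certified_planar(model, center_dose, grid)
    point_doses = measure_planar(pre, post, grid, curve, p_bg=spec.p_bg)
    planar = compare_planar(point_doses.doses_Gy, reference, grid)
    provenance["planar_scan_hash"] = _hash_array(post.pixels)

    # --- uncertainty budget ------------------------------------------------
    # budgets reported at the doses this QA session actually delivers
    budget_doses = config.get("budget_doses_Gy", [1.2, 1.8, 2.4])
    budget_doses = [d for d in budget_doses if curve.dose_range_Gy[0] - 1e-9 <= d <= curve.dose_range_Gy[1] + 1e-9]
    sd_netod_typ = float(np.median(point_doses.sd_netods))
    budgets = budget_for_doses(curve, budget_doses, sd_netod_typ)

    # --- verdicts -----------------------------------------------------------
    verdicts = [check_tolerance(ratio_measured, certified, tolerances["ratio_pp"], name="dual_depth_ratio")]
    for _, row in planar.region_summary.iterrows():
        if row["n"] > 0 and np.isfinite(row["mean_pct"]):
            verdicts.append(
                check_tolerance(row["mean_pct"], 0.0, tolerances["region_mean_pct"], name=f"planar_mean_{row['region']}")
            )
    for b in budgets:
        verdicts.append(check_tolerance(b.expanded_pct, 0.0, tolerances["expanded_pct"], name=f"expanded_at_{b.dose_Gy:.2f}Gy"))

    report = QaReport(
        plaque=model.name,
        cax_ratio=cax_ratio,
        planar=planar.region_summary.to_dict("records"),
        budget=[b.as_dict() for b in budgets],
        verdicts=verdicts,
        calibration=cal_info,
        provenance=provenance,
    )
    logger.info("QA run complete: %s", "PASS" if report.passed else "FAIL")
    return report
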