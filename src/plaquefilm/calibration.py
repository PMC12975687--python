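"""Dose schedules and the power-law dose-response calibration.

The calibration films are exposed for a schedule of durations at a
dose rate obtained by decay-correcting the source certificate to the
experiment date (Ru-106 half-life 373.6 days):

    rate(t) = certified_rate * 2**(-elapsed_days / half_life_days)
    D = rate [mGy/min] * minutes / 1000   [Gy]

The film response is modelled in both directions with a two-term
power law:

    forward :  dnetOD = a * D + b * D**n
    inverse :  D      = a * dnetOD + b * dnetOD**n

The two parameter triples are distinct (the inverse is fitted directly,
not obtained by numerically inverting the forward fit) and are kept
apart by the curve's ``form`` flag.  The inverse form is the one used to
convert measured dnetOD into absolute dose.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit

RU106_HALF_LIFE_DAYS = 373.6

#: bounds for the power-law exponent; n > 1 keeps the second term
#: super-linear so the curve stays smooth and monotone near zero
N_BOUNDS = (1.0 + 1e-9, 5.0)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SourceCert:
    """A source calibration certificate: dose rate at a reference date."""

    certified_rate_mGy_per_min: float
    cert_date: _dt.date | None = None
    half_life_days: float = RU106_HALF_LIFE_DAYS

    def __post_init__(self) -> None:
        if self.certified_rate_mGy_per_min <= 0:
            raise ValueError("certified rate must be positive")
        if self.half_life_days <= 0:
            raise ValueError("half-life must be positive")


@dataclass(frozen=True)
class DoseSchedule:
    """Irradiation durations and the doses they deliver at a fixed rate."""

    times_min: tuple[float, ...]
    rate_mGy_per_min: float
    doses_Gy: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly positive and increasing")
        object.__setattr__(self, "times_min", tuple(float(v) for v in t))
        object.__setattr__(self, "doses_Gy", tuple(delivered_dose(self.rate_mGy_per_min, v) for v in t))


@dataclass
class CalibrationCurve:
    """A fitted two-term power law, forward or inverse.

    ``dose_range_Gy`` is the dose window spanned by the calibration
    points; conversions outside it are flagged (no extrapolated
    uncertainty claims are made below the smallest calibration dose).
    """

    form: str  # "forward" | "inverse"
    a: float
    b: float
    n: float
    sd_a: float = 0.0
    sd_b: float = 0.0
    dose_range_Gy: tuple[float, float] = (0.0, np.inf)
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if self.form not in ("forward", "inverse"):
            raise ValueError("form must be 'forward' or 'inverse'")
        if not (self.n > 1.0):
            raise ValueError("exponent n must exceed 1")

    def __call__(self, x):
        """Evaluate a*x + b*x**n elementwise (x >= 0)."""
        x = np.asarray(x, dtype=float)
        return self.a * x + self.b * np.power(x, self.n)

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return self.a + self.n * self.b * np.power(x, self.n - 1.0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["dose_range_Gy"] = list(self.dose_range_Gy)
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationCurve":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["dose_range_Gy"] = tuple(payload["dose_range_Gy"])
        return cls(**payload)


def decay_corrected_rate(cert: SourceCert, elapsed_days: float | None = None, on_date: _dt.date | None = None) -> float:
    """Dose rate decayed from the certificate to the experiment date.

    Either ``elapsed_days`` or ``on_date`` (with ``cert.cert_date`` set)
    must be given.  Negative elapsed times are allowed with a warning
    (rate *before* certification).
    """
    if elapsed_days is None:
        if on_date is None or cert.cert_date is None:
            raise ValueError("give elapsed_days, or on_date together with cert_date")
        elapsed_days = (on_date - cert.cert_date).days
    if elapsed_days < 0:
        warnings.warn("experiment date precedes certification date; extrapolating backwards", stacklevel=2)
    return cert.certified_rate_mGy_per_min * 2.0 ** (-elapsed_days / cert.half_life_days)


def delivered_dose(rate_mGy_per_min: float, minutes: float) -> float:
    """Delivered dose in Gy = rate [mGy/min] x time [min] / 1000."""
    if rate_mGy_per_min < 0 or minutes < 0:
        raise ValueError("rate and time must be non-negative")
    return rate_mGy_per_min * minutes / 1000.0


def build_schedule(times_min, rate_mGy_per_min: float) -> DoseSchedule:
    return DoseSchedule(times_min=tuple(times_min), rate_mGy_per_min=rate_mGy_per_min)


def _power_law(x, a, b, n):
    return a * x + b * np.power(np.abs(x), n)


def _fit_power_law(x: np.ndarray, y: np.ndarray, form: str, weights: np.ndarray | None) -> CalibrationCurve:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError("input vectors must have equal length")
    if np.unique(x).size < 4:
        raise CalibrationError("need at least 4 distinct points for a 3-parameter fit")
    if np.any(x < 0):
        raise CalibrationError("independent variable must be non-negative")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    if np.any(np.diff(ys) <= 0):
        raise CalibrationError("calibration not monotone")

    # linear pre-fit of (a, b) with n pinned at 2 gives a deterministic start
    basis = np.column_stack([xs, xs**2])
    a0, b0 = np.linalg.lstsq(basis, ys, rcond=None)[0]
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights, dtype=float)[order])
    popt, pcov = curve_fit(
        _power_law,
        xs,
        ys,
        p0=[a0, b0, 2.0],
        sigma=sigma,
        bounds=([-np.inf, -np.inf, N_BOUNDS[0]], [np.inf, np.inf, N_BOUNDS[1]]),
        maxfev=20000,
    )
    a, b, n = (float(v) for v in popt)
    sd_a, sd_b = (float(np.sqrt(pcov[i, i])) if np.isfinite(pcov[i, i]) else 0.0 for i in (0, 1))
    resid = ys - _power_law(xs, *popt)
    ss_tot = float(np.sum((ys - ys.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    doses = ys if form == "inverse" else xs
    curve = CalibrationCurve(
        form=form,
        a=a,
        b=b,
        n=n,
        sd_a=sd_a,
        sd_b=sd_b,
        dose_range_Gy=(float(doses.min()), float(doses.max())),
        r2=r2,
    )
    # monotone-increasing on the fitted domain, as required of a usable response
    grid = np.linspace(0.0, xs.max(), 256)
    if np.any(curve.derivative(grid[1:]) <= 0):
        raise CalibrationError("fitted curve is not monotone on the calibration domain")
    return curve


def fit_inverse(delta_netods, doses_Gy, weights=None) -> CalibrationCurve:
    """Fit D = a*dnetOD + b*dnetOD**n (the dose-conversion direction).

    The input should include the (0, 0) anchor from the 0 Gy
    normalisation.  ``weights`` (optional) are relative inverse-variance
    weights for a weighted fit; the default is unweighted.
    """
    return _fit_power_law(np.asarray(delta_netods, float), np.asarray(doses_Gy, float), "inverse", weights)


def fit_forward(doses_Gy, delta_netods, weights=None) -> CalibrationCurve:
    """Fit dnetOD = a*D + b*D**n (the physical response direction)."""
    return _fit_power_law(np.asarray(doses_Gy, float), np.asarray(delta_netods, float), "forward", weights)


def dose_from_netod(curve: CalibrationCurve, delta_netod: float) -> float:
    """Convert a re-zeroed netOD to absolute dose via the inverse curve.

    Small negative inputs (above -1e-6, pure noise at 0 Gy) are clamped
    to zero; larger negative values are an error.  A warning is emitted
    when the implied dose falls outside the fitted dose range.
    """
    if curve.form != "inverse":
        raise CalibrationError("dose conversion requires an inverse-form curve")
    x = float(delta_netod)
    if x < -1e-6:
        raise CalibrationError(f"negative delta netOD {x!r}")
    x = max(x, 0.0)
    dose = float(curve(x))
    lo, hi = curve.dose_range_Gy
    if dose < lo - 1e-9 or dose > hi + 1e-9:
        warnings.warn(
            f"dose {dose:.3g} Gy outside calibrated range [{lo:.3g}, {hi:.3g}] Gy; "
            "no uncertainty claim is valid here",
            stacklevel=2,
        )
    return dose


def netod_from_dose(curve: CalibrationCurve, dose_Gy: float) -> float:
    """Invert the inverse-form curve numerically (dose -> dnetOD)."""
    from scipy.optimize import brentq

    if curve.form != "inverse":
        raise CalibrationError("requires an inverse-form curve")
    if dose_Gy < 0:
        raise CalibrationError("dose must be >= 0")
    if dose_Gy == 0:
        return 0.0
    hi = 1.0
    while curve(hi) < dose_Gy:
        hi *= 2.0
        if hi > 1e6:
            raise CalibrationError("dose beyond representable response")
    return float(brentq(lambda x: curve(x) - dose_Gy, 0.0, hi, xtol=1e-12))
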