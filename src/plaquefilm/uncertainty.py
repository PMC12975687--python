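"""Dose uncertainty budget for the film calibration chain.

The budget follows the classical film-dosimetry error-propagation
formalism.  With ``x`` the measured dnetOD and ``D_fit = a x + b x^n``
the fitted dose (inverse-form curve):

    SDfit% = sqrt( x^2 SDa^2 + x^(2n) SDb^2 ) / D_fit * 100
    SDexp% = (a + n b x^(n-1)) * SD(dnetOD) / D_fit * 100
    SDtot% = sqrt( SDexp%^2 + SDfit%^2 )

The expanded uncertainty multiplies SDtot% by a coverage factor
(k = 2 for an approximate 95 % interval).  ``a`` and ``b`` are treated
as uncorrelated and ``n`` as exact, exactly as the formulas are written.

Budgets are refused below the smallest calibration dose: the response
is not characterised there and no extrapolation is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from plaquefilm.calibration import CalibrationCurve, CalibrationError, dose_from_netod


class ExtrapolationError(CalibrationError):
    """Raised when a budget is requested outside the calibrated dose range."""


@dataclass(frozen=True)
class UncertaintyBudget:
    """Experimental / fitting / total dose uncertainty at one dose point."""

    dose_Gy: float
    sd_exp_pct: float
    sd_fit_pct: float
    sd_tot_pct: float
    k: float = 2.0

    @property
    def expanded_pct(self) -> float:
        return self.k * self.sd_tot_pct

    def as_dict(self) -> dict:
        d = asdict(self)
        d["expanded_pct"] = self.expanded_pct
        return d


def _check_point(curve: CalibrationCurve, delta_netod: float) -> float:
    if curve.form != "inverse":
        raise CalibrationError("uncertainty budget requires an inverse-form curve")
    if delta_netod <= 0:
        raise CalibrationError("undefined at zero dose (0/0); need delta_netod > 0")
    d_fit = float(curve(delta_netod))
    lo = curve.dose_range_Gy[0]
    if d_fit < lo - 1e-9:
        raise ExtrapolationError(f"dose {d_fit:.3g} Gy below calibrated minimum {lo:.3g} Gy; no extrapolation")
    return d_fit


def sd_fit_percent(curve: CalibrationCurve, delta_netod: float) -> float:
    """Fitting component: propagated SDs of the curve parameters a and b."""
    x = float(delta_netod)
    d_fit = _check_point(curve, x)
    return math.sqrt(x**2 * curve.sd_a**2 + x ** (2 * curve.n) * curve.sd_b**2) / d_fit * 100.0


def sd_exp_percent(curve: CalibrationCurve, delta_netod: float, sd_netod: float) -> float:
    """Experimental component: the netOD SD pushed through the curve slope."""
    x = float(delta_netod)
    if sd_netod < 0:
        raise ValueError("sd_netod must be >= 0")
    d_fit = _check_point(curve, x)
    slope = curve.a + curve.n * curve.b * x ** (curve.n - 1.0)
    return slope * sd_netod / d_fit * 100.0


def sd_total_percent(sd_exp_pct: float, sd_fit_pct: float) -> float:
    """Quadrature sum of the experimental and fitting components."""
    if sd_exp_pct < 0 or sd_fit_pct < 0:
        raise ValueError("components must be >= 0")
    return math.hypot(sd_exp_pct, sd_fit_pct)


def expanded_uncertainty(sd_tot_pct: float, k: float = 2.0) -> float:
    """Expanded uncertainty = coverage factor x total 1-sigma percentage."""
    if sd_tot_pct < 0 or k <= 0:
        raise ValueError("sd_tot_pct must be >= 0 and k > 0")
    return k * sd_tot_pct


def budget_at(curve: CalibrationCurve, delta_netod: float, sd_netod: float, k: float = 2.0) -> UncertaintyBudget:
    """Full budget at one measured dnetOD."""
    fit = sd_fit_percent(curve, delta_netod)
    exp = sd_exp_percent(curve, delta_netod, sd_netod)
    return UncertaintyBudget(
        dose_Gy=dose_from_netod(curve, delta_netod),
        sd_exp_pct=exp,
        sd_fit_pct=fit,
        sd_tot_pct=sd_total_percent(exp, fit),
        k=k,
    )


def budget_for_doses(curve: CalibrationCurve, doses_Gy, sd_netod, k: float = 2.0) -> list[UncertaintyBudget]:
    """Budgets at a list of doses (dnetOD recovered by inverting the curve).

    ``sd_netod`` is either a scalar applied at every dose or a callable
    ``sd_netod(dnetOD) -> float``.
    """
    from plaquefilm.calibration import netod_from_dose

    out = []
    for dose in doses_Gy:
        x = netod_from_dose(curve, float(dose))
        s = sd_netod(x) if callable(sd_netod) else float(sd_netod)
        out.append(budget_at(curve, x, s, k=k))
    return out
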