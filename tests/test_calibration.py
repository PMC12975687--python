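"""Decay-corrected schedules and the forward/inverse power-law fits."""

import numpy as np
import pytest

from plaquefilm.calibration import (
    CalibrationCurve,
    CalibrationError,
    SourceCert,
    build_schedule,
    decay_corrected_rate,
    delivered_dose,
    dose_from_netod,
    fit_forward,
    fit_inverse,
    netod_from_dose,
)

SCHEDULE_MIN = (2.5, 5.0, 10.0, 15.0, 20.0)
RATE = 120.1


class TestDecayAndSchedule:
    @pytest.mark.parametrize("elapsed, expected", [(0.0, 200.0), (373.6, 100.0), (747.2, 50.0)])
    def test_halving_per_half_life(self, elapsed, expected):
        cert = SourceCert(certified_rate_mGy_per_min=200.0)
        assert decay_corrected_rate(cert, elapsed) == pytest.approx(expected)

    def test_pre_certification_date_warns(self):
        with pytest.warns(UserWarning):
            decay_corrected_rate(SourceCert(200.0), -10.0)

    @pytest.mark.parametrize("minutes, gy", [(2.5, 0.30025), (20.0, 2.402), (0.0, 0.0)])
    def test_delivered_dose_rate_times_time(self, minutes, gy):
        assert delivered_dose(RATE, minutes) == pytest.approx(gy)

    def test_delivered_dose_linear_in_rate_and_time(self):
        assert delivered_dose(2 * RATE, 10.0) == pytest.approx(2 * delivered_dose(RATE, 10.0))
        assert delivered_dose(RATE, 14.0) == pytest.approx(delivered_dose(RATE, 10.0) + delivered_dose(RATE, 4.0))

    def test_schedule_doses_and_ordering(self):
        sched = build_schedule(SCHEDULE_MIN, RATE)
        assert sched.doses_Gy == pytest.approx(tuple(RATE * t / 1000 for t in SCHEDULE_MIN))
        with pytest.raises(ValueError):
            build_schedule((5.0, 2.5), RATE)


def truth_samples(a, b, n, doses):
    doses = np.asarray(doses)
    return a * doses + b * doses**n


class TestPowerLawFits:
    TRUTH = (5.0, 40.0, 2.2)  # inverse-form truth: D = 5 x + 40 x^2.2

    def dnetods(self):
        # dose values at the 5-point schedule plus the (0,0) anchor,
        # mapped back through the known inverse truth
        doses = np.array([0.0] + [RATE * t / 1000 for t in SCHEDULE_MIN])
        xs = np.array([netod_from_dose(CalibrationCurve("inverse", *self.TRUTH), d) for d in doses])
        return xs, doses

    def test_inverse_recovers_known_parameters(self):
        xs, doses = self.dnetods()
        curve = fit_inverse(xs, doses)
        for got, want in zip((curve.a, curve.b, curve.n), self.TRUTH):
            assert got == pytest.approx(want, rel=1e-4)
        assert curve.r2 >= 0.9999
        assert curve.dose_range_Gy == pytest.approx((0.0, 2.402))

    def test_forward_recovers_known_parameters(self):
        a, b, n = 0.14, -0.002, 2.2
        doses = np.array([0.0] + [RATE * t / 1000 for t in SCHEDULE_MIN])
        curve = fit_forward(doses, truth_samples(a, b, n, doses))
        for got, want in zip((curve.a, curve.b, curve.n), (a, b, n)):
            assert got == pytest.approx(want, rel=1e-4)

    def test_forward_then_inverse_roundtrip_within_point1_percent(self):
        # physical truth in the forward form; the directly fitted inverse
        # form must agree with the exact inverse across the fitted range
        a, b, n = 0.14, -0.002, 2.2
        doses = np.array([0.0] + [RATE * t / 1000 for t in SCHEDULE_MIN])
        inverse = fit_inverse(truth_samples(a, b, n, doses), doses)
        dense = np.linspace(0.30025, 2.402, 100)
        recovered = np.array([dose_from_netod(inverse, x) for x in truth_samples(a, b, n, dense)])
        assert np.max(np.abs(recovered - dense) / dense) < 1e-3

    def test_underdetermined_and_empty_inputs_rejected(self):
        with pytest.raises(CalibrationError):
            fit_inverse([0.0, 0.1, 0.2], [0.0, 1.0, 2.0])
        with pytest.raises(CalibrationError):
            fit_forward([], [])

    def test_non_monotone_data_rejected(self):
        with pytest.raises(CalibrationError, match="monotone"):
            fit_inverse([0.0, 0.1, 0.2, 0.15, 0.3], [0.0, 0.5, 1.0, 1.5, 2.0])

    def test_noisy_recovery_median_error_below_two_percent(self):
        # 1 % multiplicative noise at the five schedule doses; over 200
        # seeded replicates the median absolute dose-recovery error
        # across the range stays below 2 %
        a, b, n = 0.14, -0.002, 2.2
        doses = np.array([0.0] + [RATE * t / 1000 for t in SCHEDULE_MIN])
        clean = truth_samples(a, b, n, doses)
        dense = np.linspace(0.30025, 2.402, 25)
        dense_x = truth_samples(a, b, n, dense)
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(200):
            noisy = clean * (1.0 + rng.normal(0.0, 0.01, size=clean.shape))
            noisy[0] = 0.0  # the 0 Gy anchor stays exact
            try:
                curve = fit_inverse(noisy, doses)
            except CalibrationError:
                continue  # a noise draw may break monotonicity; skip it
            rec = curve(dense_x)
            errs.append(np.max(np.abs(rec - dense) / dense))
        assert len(errs) > 150
        assert np.median(errs) < 0.02


class TestDoseConversion:
    def test_zero_netod_is_zero_dose(self, inverse_curve):
        assert dose_from_netod(inverse_curve, 0.0) == 0.0

    def test_direct_evaluation(self, inverse_curve):
        assert dose_from_netod(inverse_curve, 0.1) == pytest.approx(5.0 * 0.1 + 40.0 * 0.1**2.2)

    def test_negative_netod_rejected(self, inverse_curve):
        with pytest.raises(CalibrationError):
            dose_from_netod(inverse_curve, -0.01)

    def test_out_of_range_dose_warns(self):
        curve = CalibrationCurve("inverse", 5.0, 40.0, 2.2, dose_range_Gy=(0.3, 2.4))
        with pytest.warns(UserWarning, match="outside calibrated range"):
            dose_from_netod(curve, 0.5)

    def test_strictly_increasing_on_domain(self, inverse_curve):
        xs = np.linspace(0.0, 0.2, 200)
        doses = [dose_from_netod(inverse_curve, x) for x in xs]
        assert all(b > a for a, b in zip(doses, doses[1:]))

    def test_numeric_inversion_roundtrip(self, inverse_curve):
        for d in (0.3, 1.0, 2.4):
            assert dose_from_netod(inverse_curve, netod_from_dose(inverse_curve, d)) == pytest.approx(d, rel=1e-9)


class TestCurveSerialisation:
    def test_json_roundtrip(self, tmp_path, inverse_curve):
        path = tmp_path / "curve.json"
        inverse_curve.to_json(path)
        back = CalibrationCurve.from_json(path)
        assert back == inverse_curve
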