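"""Synthetic dose fields and the film forward model."""

import numpy as np
import pytest

from plaquefilm.calibration import CalibrationCurve
from plaquefilm.densitometry import FilmReading, net_od
from plaquefilm.plaque_geometry import build_reference_grid, low_dose_filter
from plaquefilm.synthetic_data import (
    SyntheticSpec,
    default_true_curve,
    film_forward_model,
    make_planar_field,
    planar_dose,
    simulate_dataset,
    synthetic_certified_planar,
    uniform_dose_map,
)


class TestPlanarField:
    def test_maximal_at_centre(self, cca):
        field = make_planar_field(cca, center_dose_Gy=1.8)
        centre = field[field.shape[0] // 2, field.shape[1] // 2]
        assert centre == pytest.approx(field.max(), rel=1e-6)
        assert centre == pytest.approx(1.8, rel=1e-3)

    def test_below_five_percent_outside_active_region(self, cca):
        # 3 mm outside the active radius the dose has fallen below 5 %
        r = cca.diameter_mm / 2 + 3.0
        assert planar_dose(cca, r, 0.0) < 0.05 * 1.8

    def test_radially_symmetric_without_notch(self, cca):
        angles = np.linspace(0, 2 * np.pi, 13)
        vals = planar_dose(cca, 6.0 * np.cos(angles), 6.0 * np.sin(angles))
        assert np.ptp(vals) < 1e-12

    def test_notch_attenuates_one_sector_only(self, cib):
        r = 10.0
        in_notch = planar_dose(cib, 0.0, r)  # +y direction
        off_notch = planar_dose(cib, 0.0, -r)
        assert in_notch < 0.1 * off_notch

    def test_cib_notch_removes_one_r2_point(self, cib):
        # the kept-point pattern of the iris-notched plaque: 17 / 24
        grid = build_reference_grid(cib)
        ref = np.array(synthetic_certified_planar(cib, 1.8, grid))
        kept = set(low_dose_filter(ref).tolist())
        counts = [sum(1 for i in grid.region_indices(r) if i in kept) for r in ("R1", "R2", "R3")]
        assert counts[:2] == [17, 24]

    def test_cca_field_keeps_all_33(self, cca):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        assert low_dose_filter(ref).size == 33

    def test_nonpositive_inputs_rejected(self, cca):
        with pytest.raises(ValueError):
            planar_dose(cca, 0.0, 0.0, center_dose_Gy=0.0)
        with pytest.raises(ValueError):
            make_planar_field(cca, size_mm=-1.0)


class TestFilmForwardModel:
    def test_zero_dose_noise_off_pre_equals_post(self, cca):
        spec = SyntheticSpec(model=cca, pixel_noise_sd=0.0)
        pre, post = film_forward_model(uniform_dose_map(0.0, size_mm=3.0), spec)
        assert np.array_equal(pre.pixels, post.pixels)

    def test_algebraic_inversion_noise_off(self, cca):
        # net_od of a noiseless pixel equals the true forward response
        # to quantisation precision
        spec = SyntheticSpec(model=cca, pixel_noise_sd=0.0)
        dose = 1.5
        pre, post = film_forward_model(uniform_dose_map(dose, size_mm=2.0), spec)
        reading = FilmReading(p0=float(pre.pixels[0, 0]), p=float(post.pixels[0, 0]), p_bg=spec.p_bg)
        truth = float(spec.true_curve(dose))
        assert net_od(reading) == pytest.approx(truth, abs=2e-5)

    def test_identical_seeds_bit_identical_tiffs(self, cca, tmp_path):
        from plaquefilm.scan_io import read_scan

        spec = SyntheticSpec(model=cca, seed=77)
        p1 = simulate_dataset(spec, tmp_path / "a", center_dose_Gy=1.2, size_mm=12.0)
        p2 = simulate_dataset(spec, tmp_path / "b", center_dose_Gy=1.2, size_mm=12.0)
        for key in ("pre", "post"):
            assert np.array_equal(read_scan(p1[key]).pixels, read_scan(p2[key]).pixels)
        assert (tmp_path / "a" / "spec.json").read_text() == (tmp_path / "b" / "spec.json").read_text()

    def test_saturating_dose_rejected(self, cca):
        hot = CalibrationCurve(form="forward", a=3.0, b=0.1, n=2.0, dose_range_Gy=(0.0, 100.0))
        spec = SyntheticSpec(model=cca, true_curve=hot, pixel_noise_sd=0.0)
        with pytest.raises(ValueError, match="saturated"):
            film_forward_model(uniform_dose_map(10.0, size_mm=2.0), spec)

    def test_quantisation_only_recovery_below_half_percent(self, cca):
        # noise off: the only pipeline error sources are 16-bit
        # quantisation and the inverse-fit form mismatch
        from plaquefilm.reporting import calibrate_from_synthetic
        from plaquefilm.calibration import dose_from_netod
        from plaquefilm.densitometry import reading_from_rois
        from plaquefilm.scan_io import RoiCircle, roi_stats

        spec = SyntheticSpec(model=cca, pixel_noise_sd=0.0, seed=5)
        curve, _, _ = calibrate_from_synthetic(spec)
        roi = RoiCircle(1.5, 1.5, 1.0)
        for dose in (0.3, 0.9, 1.5, 2.4):
            pre, post = film_forward_model(uniform_dose_map(dose, size_mm=3.0), spec)
            reading = reading_from_rois(roi_stats(pre, roi), roi_stats(post, roi), p_bg=spec.p_bg)
            recovered = dose_from_netod(curve, net_od(reading))
            assert abs(recovered - dose) / dose < 0.005

    def test_roundtrip_error_shrinks_with_noise(self, cca):
        # expectation over seeds: less pixel noise, less dose error
        from plaquefilm.calibration import dose_from_netod, netod_from_dose
        from plaquefilm.densitometry import reading_from_rois
        from plaquefilm.reporting import calibrate_from_synthetic
        from plaquefilm.scan_io import RoiCircle, roi_stats

        dose = 1.5
        roi = RoiCircle(1.5, 1.5, 1.0)
        mean_errs = []
        for noise in (400.0, 100.0, 25.0):
            errs = []
            for seed in range(12):
                spec = SyntheticSpec(model=cca, pixel_noise_sd=noise, seed=900 + seed)
                curve, _, _ = calibrate_from_synthetic(spec)
                pre, post = film_forward_model(uniform_dose_map(dose, size_mm=3.0), spec)
                reading = reading_from_rois(roi_stats(pre, roi), roi_stats(post, roi), p_bg=spec.p_bg)
                errs.append(abs(dose_from_netod(curve, net_od(reading)) - dose) / dose)
            mean_errs.append(np.mean(errs))
        assert mean_errs[0] > mean_errs[2]


class TestDefaultTrueCurve:
    def test_forward_form_and_monotone(self):
        curve = default_true_curve()
        assert curve.form == "forward"
        grid = np.linspace(0.0, 2.4, 200)
        assert np.all(np.diff(curve(grid)) > 0)
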