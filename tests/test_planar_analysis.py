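"""Planar dose measurement at the 33 grid points and region summaries."""

import numpy as np
import pytest

from plaquefilm.plaque_geometry import build_reference_grid
from plaquefilm.planar_analysis import compare_planar, extract_axis_profile, measure_planar
from plaquefilm.reporting import calibrate_from_synthetic
from plaquefilm.synthetic_data import (
    SyntheticSpec,
    film_forward_model,
    make_planar_field,
    synthetic_certified_planar,
    uniform_dose_map,
)


@pytest.fixture(scope="module")
def cca_curve():
    from plaquefilm.plaque_geometry import load_model

    spec = SyntheticSpec(model=load_model("CCA"), seed=2024)
    curve, _, _ = calibrate_from_synthetic(spec)
    return spec, curve


class TestMeasurePlanar:
    def test_uniform_field_recovered_within_two_percent(self, cca, cca_curve):
        spec, curve = cca_curve
        grid = build_reference_grid(cca)
        pre, post = film_forward_model(uniform_dose_map(1.8, size_mm=30.0), spec.with_seed(7))
        doses = measure_planar(pre, post, grid, curve, p_bg=spec.p_bg)
        assert np.allclose(doses.doses_Gy, 1.8, rtol=0.02)

    def test_noise_free_recovery_sub_half_percent(self, cca, cca_curve):
        spec, curve = cca_curve
        grid = build_reference_grid(cca)
        quiet = SyntheticSpec(model=cca, pixel_noise_sd=0.0)
        pre, post = film_forward_model(uniform_dose_map(1.8, size_mm=30.0), quiet)
        doses = measure_planar(pre, post, grid, curve, p_bg=quiet.p_bg)
        assert np.allclose(doses.doses_Gy, 1.8, rtol=0.005)

    def test_rotation_offset_invariant_on_symmetric_field(self, cca, cca_curve):
        spec, curve = cca_curve
        grid = build_reference_grid(cca)
        quiet = SyntheticSpec(model=cca, pixel_noise_sd=0.0)
        pre, post = film_forward_model(make_planar_field(cca, 1.8, size_mm=32.0), quiet)
        a = measure_planar(pre, post, grid, curve, p_bg=quiet.p_bg)
        b = measure_planar(pre, post, grid, curve, p_bg=quiet.p_bg, rotation_deg=90.0)
        assert np.allclose(a.doses_Gy, b.doses_Gy, rtol=0.01)

    def test_grid_outside_image_rejected(self, cca, cca_curve):
        spec, curve = cca_curve
        grid = build_reference_grid(cca)
        pre, post = film_forward_model(uniform_dose_map(1.0, size_mm=8.0), spec)
        with pytest.raises(ValueError, match="outside"):
            measure_planar(pre, post, grid, curve, p_bg=spec.p_bg)


class TestComparePlanar:
    def test_identity_gives_zero_everywhere(self, cca):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        cmp = compare_planar(ref, ref, grid)
        for region in ("R1", "R2", "R3"):
            n, mean, sd = cmp.region_stats(region)
            assert mean == 0.0 and sd == 0.0

    def test_uniform_three_percent_offset(self, cca):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        cmp = compare_planar(1.03 * ref, ref, grid)
        for region in ("R1", "R2", "R3"):
            n, mean, sd = cmp.region_stats(region)
            assert mean == pytest.approx(3.0)
            assert sd == pytest.approx(0.0, abs=1e-9)

    def test_region_counts_cumulative_and_filter_respected(self, cib):
        grid = build_reference_grid(cib)
        ref = np.array(synthetic_certified_planar(cib, 1.8, grid))
        cmp = compare_planar(ref, ref, grid)
        ns = [cmp.region_stats(r)[0] for r in ("R1", "R2", "R3")]
        assert ns[0] == 17 and ns[1] == 24  # iris-notch pattern
        assert ns[0] <= ns[1] <= ns[2]
        assert len(cmp.excluded_points) == 33 - ns[2]

    def test_common_rescale_invariance(self, cca, rng):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        measured = ref * (1 + rng.normal(0, 0.02, ref.shape))
        a = compare_planar(measured, ref, grid)
        b = compare_planar(measured * 100.0, ref * 100.0, grid)
        assert np.allclose(
            a.per_point["diff_pct"].to_numpy(), b.per_point["diff_pct"].to_numpy(), equal_nan=True
        )

    def test_misaligned_lengths_rejected(self, cca):
        grid = build_reference_grid(cca)
        with pytest.raises(ValueError):
            compare_planar(np.ones(32), np.ones(33), grid)


class TestAxisProfiles:
    def test_each_axis_has_nine_entries_centre_shared(self, cca):
        grid = build_reference_grid(cca)
        doses = np.arange(33, dtype=float) + 1
        for axis in ("x", "y", "d1", "d2"):
            profile = extract_axis_profile(doses, grid, axis)
            assert len(profile) == 9
            positions = [p for p, _ in profile]
            assert positions == sorted(positions)
            assert 0.0 in positions

    def test_symmetric_field_gives_symmetric_profiles(self, cca):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        for axis in ("x", "y", "d1", "d2"):
            profile = extract_axis_profile(ref, grid, axis)
            vals = [v for _, v in profile]
            assert np.allclose(vals, vals[::-1], rtol=1e-9)

    def test_radially_decreasing_field_peaks_at_centre(self, cca):
        grid = build_reference_grid(cca)
        ref = np.array(synthetic_certified_planar(cca, 1.8, grid))
        profile = extract_axis_profile(ref, grid, "x")
        assert max(v for _, v in profile) == pytest.approx(ref[0])

    def test_unknown_axis_rejected(self, cca):
        grid = build_reference_grid(cca)
        with pytest.raises(ValueError, match="unknown axis"):
            extract_axis_profile(np.ones(33), grid, "z")
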