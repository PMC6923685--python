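"""Focused-bowl field: closed-form oracle, Rayleigh integral, plane extraction."""

import numpy as np
import pytest

from tmaskit import (
    CartesianGrid,
    ConfigurationError,
    GridError,
    Medium,
    TransducerSpec,
    calibrate_drive,
    extract_plane,
    oneil_axial_pressure,
    rayleigh_field,
)
from tmaskit.acoustic import cap_source_points

from conftest import axis_indices


def brute_force_axial(spec, medium, y, n_theta=200_000):
    """Independent oracle: dense trapezoid quadrature of the on-axis
    Rayleigh integral over the cap's polar angle."""
    f, a = spec.geometric_focus, spec.aperture_diameter / 2
    k = 2 * np.pi * spec.carrier_frequency / medium.sound_speed
    theta = np.linspace(0.0, np.arcsin(a / f), n_theta)
    r = np.sqrt((f * np.sin(theta)) ** 2 + (y - f * (1 - np.cos(theta))) ** 2)
    integrand = np.exp(1j * k * r) / r * f * f * np.sin(theta)
    integral = 2 * np.pi * np.trapezoid(integrand, theta)
    return abs(-1j * k * spec.surface_drive / (2 * np.pi) * integral)


class TestOneil:
    def test_focal_limit_equals_k_times_cap_depth(self, spec, medium):
        # hand-derived: k = 2*pi*1e6/1450 = 4333.2 rad/m, h = 3.2279 mm
        val = oneil_axial_pressure(spec, medium, [spec.geometric_focus])[0]
        assert val == pytest.approx(13.987, rel=1e-3)

    def test_matches_brute_force_quadrature(self, spec, medium):
        for y in (0.010, 0.018, 0.0225, 0.028, 0.0345):
            closed = oneil_axial_pressure(spec, medium, [y])[0]
            brute = brute_force_axial(spec, medium, y)
            assert closed == pytest.approx(brute, rel=1e-3)

    def test_beyond_focus_weaker_than_focus(self, spec, medium):
        f = spec.geometric_focus
        p_f, p_far = oneil_axial_pressure(spec, medium, [f, 1.5 * f])
        assert p_far < p_f

    def test_drive_linearity(self, spec, medium):
        y = np.linspace(0.005, 0.04, 50)
        doubled = TransducerSpec(
            spec.carrier_frequency,
            spec.geometric_focus,
            spec.aperture_diameter,
            2 * spec.surface_drive,
        )
        np.testing.assert_allclose(
            oneil_axial_pressure(doubled, medium, y),
            2 * oneil_axial_pressure(spec, medium, y),
            rtol=1e-14,
        )

    def test_negative_position_rejected(self, spec, medium):
        with pytest.raises(ValueError):
            oneil_axial_pressure(spec, medium, [-0.001])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"carrier_frequency": -1e6},
            {"geometric_focus": 0.0},
            {"aperture_diameter": 0.05},  # exceeds 2*focus
            {"surface_drive": 0.0},
        ],
    )
    def test_degenerate_spec_rejected(self, kwargs):
        base = dict(
            carrier_frequency=1e6,
            geometric_focus=0.023,
            aperture_diameter=0.0235,
            surface_drive=1.0,
        )
        with pytest.raises(ConfigurationError):
            TransducerSpec(**{**base, **kwargs})


class TestRayleighField:
    def test_on_axis_agrees_with_oneil_near_focus(self, spec, medium, small_field):
        g = small_field.grid
        ix, iz = axis_indices(g)
        num = np.abs(small_field.amplitude[ix, :, iz])
        oracle = oneil_axial_pressure(spec, medium, g.y)
        mask = np.abs(g.y - spec.geometric_focus) <= 0.008
        rel = np.abs(num - oracle)[mask] / oracle[mask]
        assert rel.max() < 0.01

    def test_axial_peak_near_geometric_focus(self, spec, medium, small_field):
        g = small_field.grid
        ix, iz = axis_indices(g)
        onax = np.abs(small_field.amplitude[ix, :, iz])
        y_peak = g.y[onax.argmax()]
        assert abs(y_peak - spec.geometric_focus) <= 0.1 * spec.geometric_focus
        # focusing gain of the fixture bowl is ~ k*h ~ 14 per unit drive
        assert 12.0 < onax.max() / spec.surface_drive < 16.0

    def test_axisymmetry_under_x_flip(self, small_field):
        mag = small_field.magnitude()
        np.testing.assert_allclose(mag, mag[::-1, :, :], rtol=1e-10)
        np.testing.assert_allclose(mag, mag[:, :, ::-1], rtol=1e-10)

    def test_field_linear_in_drive(self, spec, medium):
        g = CartesianGrid(np.array([0.0]), np.linspace(0.02, 0.026, 18), np.array([0.0]))
        f1 = rayleigh_field(spec, medium, g)
        spec2 = TransducerSpec(
            spec.carrier_frequency, spec.geometric_focus, spec.aperture_diameter, 3.5
        )
        f2 = rayleigh_field(spec2, medium, g)
        np.testing.assert_allclose(f2.amplitude, 3.5 * f1.amplitude, rtol=1e-13)

    def test_source_refinement_converged(self, spec, medium):
        g = CartesianGrid(np.array([0.0]), np.array([0.023]), np.array([0.0]))
        coarse = rayleigh_field(spec, medium, g, elements_per_wavelength=6)
        fine = rayleigh_field(spec, medium, g, elements_per_wavelength=12)
        change = np.abs(np.abs(fine.amplitude) - np.abs(coarse.amplitude)) / np.abs(
            fine.amplitude
        )
        assert change.max() < 0.005

    def test_coarse_grid_refused_or_warned(self, spec, medium):
        g = CartesianGrid(
            np.array([0.0]), np.linspace(0.02, 0.026, 5), np.array([0.0])
        )  # 1.5 mm step >> lambda/4
        with pytest.raises(GridError):
            rayleigh_field(spec, medium, g)
        with pytest.warns(UserWarning):
            rayleigh_field(spec, medium, g, coarse_grid="warn")

    def test_grid_touching_source_rejected(self, spec, medium):
        lam = medium.wavelength(spec.carrier_frequency)
        g = CartesianGrid.centered(0.002, (0.0, 0.004), 0.002, lam / 4)
        with pytest.raises(GridError):
            rayleigh_field(spec, medium, g)

    def test_calibrated_drive_hits_target_peak(self, spec, medium):
        spec3 = calibrate_drive(spec, medium, 3e6)
        y = np.linspace(0.015, 0.031, 2001)
        assert oneil_axial_pressure(spec3, medium, y).max() == pytest.approx(3e6, rel=1e-4)

    def test_source_area_covers_cap(self, spec, medium):
        _, _, w, _ = cap_source_points(spec, medium)
        f, a = spec.geometric_focus, spec.aperture_diameter / 2
        exact = 2 * np.pi * f * (f - np.sqrt(f * f - a * a))  # spherical-cap area
        assert w.sum() == pytest.approx(exact, rel=1e-4)


class TestExtractPlane:
    def test_focal_plane_peak_on_axis(self, small_field):
        m = extract_plane(small_field, "xz", 0.023)
        i, j = m.peak_index()
        step = np.diff(m.coords[0]).max()
        assert abs(m.coords[0][i]) <= step
        assert abs(m.coords[1][j]) <= step

    def test_xy_plane_shape_and_labels(self, small_field):
        m = extract_plane(small_field, "xy", 0.0)
        g = small_field.grid
        assert m.amplitude.shape == (g.x.size, g.y.size)
        assert m.coord_labels == ("x_mm", "y_mm")

    def test_offset_outside_grid_errors(self, small_field):
        with pytest.raises(ValueError):
            extract_plane(small_field, "xz", 0.2)

    def test_nearest_node_tie_breaks_low(self):
        from tmaskit import ComplexPressureField

        g = CartesianGrid(np.array([0.0]), np.array([1.0, 2.0]), np.array([0.0]))
        f = ComplexPressureField(g, np.zeros((1, 2, 1), dtype=complex), 1e6)
        m = extract_plane(f, "xz", 1.5)  # equidistant: lower index wins
        assert m.plane == "xz@1000.000mm"

    def test_plane_through_zero_padding_is_zero(self):
        from tmaskit import ComplexPressureField

        g = CartesianGrid(
            np.arange(3.0), np.arange(4.0), np.arange(3.0)
        )
        amp = np.zeros((3, 4, 3), dtype=complex)
        amp[:, :2, :] = 1.0  # nonzero only in the first two y-slabs
        f = ComplexPressureField(g, amp, 1e6)
        m = extract_plane(f, "xz", 3.0)
        assert np.all(m.amplitude == 0.0)


def test_medium_validation():
    with pytest.raises(ConfigurationError):
        Medium(density=-1)
    assert Medium().wavelength(1e6) == pytest.approx(1.45e-3)
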