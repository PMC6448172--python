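"""TG-43 line-source kernel against independent numerical oracles."""

from datetime import date

import numpy as np
import pytest

from brachydv.tg43 import (
    DwellPosition,
    Plan,
    SingularGeometryError,
    SourceDescription,
    decayed_strength,
    dose_rate_at_point,
    geometry_function_line,
    interpolate_anisotropy,
    interpolate_radial,
    total_dose,
)


def line_integration_oracle(r_cm, theta_deg, L_cm, n=10_001):
    """G_L via brute-force superposition of point sources on the segment."""
    th = np.radians(theta_deg)
    p = np.array([r_cm * np.sin(th), r_cm * np.cos(th)])  # (rho, z)
    zs = np.linspace(-L_cm / 2, L_cm / 2, n)
    d2 = p[0] ** 2 + (p[1] - zs) ** 2
    return np.trapezoid(1.0 / d2, zs) / L_cm


class TestGeometryFunction:
    def test_point_source_limit(self):
        for r, th in [(0.5, 30.0), (1.0, 90.0), (2.5, 120.0)]:
            assert geometry_function_line(r, th, 1e-9) == pytest.approx(1.0 / r**2, rel=1e-6)

    def test_matches_line_integration_oracle_at_reference(self):
        got = geometry_function_line(1.0, 90.0, 0.35)
        want = line_integration_oracle(1.0, 90.0, 0.35)
        assert got == pytest.approx(want, rel=1e-6)

    def test_matches_oracle_on_r_theta_sample(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            r = rng.uniform(0.3, 8.0)
            th = rng.uniform(1.0, 179.0)
            got = geometry_function_line(r, th, 0.35)
            want = line_integration_oracle(r, th, 0.35, n=200_001)
            assert got == pytest.approx(want, rel=1e-5)

    def test_mirror_symmetry(self):
        for r, th in [(1.0, 30.0), (2.0, 75.0), (0.7, 10.0)]:
            assert geometry_function_line(r, th, 0.35) == pytest.approx(
                geometry_function_line(r, 180.0 - th, 0.35), rel=1e-12
            )

    def test_on_axis_limit_continuous(self):
        L = 0.35
        on_axis = geometry_function_line(1.0, 0.0, L)
        assert on_axis == pytest.approx(1.0 / (1.0 - L**2 / 4), rel=1e-12)
        near_axis = geometry_function_line(1.0, 1e-4, L)
        assert near_axis == pytest.approx(on_axis, rel=1e-6)

    def test_point_on_active_segment_is_singular(self):
        with pytest.raises(SingularGeometryError):
            geometry_function_line(0.1, 0.0, 0.35)
        with pytest.raises(SingularGeometryError):
            geometry_function_line(0.17, 180.0, 0.35)


class TestTableInterpolation:
    def test_radial_nodes_midpoints_and_clamp(self, source):
        r = source.radial_r_cm
        g = source.radial_g
        for i in (0, 3, len(r) - 1):
            assert interpolate_radial(source, r[i]) == pytest.approx(g[i])
        mid = 0.5 * (r[2] + r[3])
        assert interpolate_radial(source, mid) == pytest.approx(0.5 * (g[2] + g[3]))
        assert interpolate_radial(source, r[-1] + 5.0) == pytest.approx(g[-1])
        assert interpolate_radial(source, r[0] / 10) == pytest.approx(g[0])

    def test_anisotropy_nodes_and_normalization_row(self, source):
        ar, at, af = source.aniso_r_cm, source.aniso_theta_deg, source.aniso_f
        assert interpolate_anisotropy(source, ar[2], at[3]) == pytest.approx(af[2, 3])
        for r in [0.3, 1.7, 6.0]:
            assert interpolate_anisotropy(source, r, 90.0) == pytest.approx(1.0, abs=1e-12)

    def test_anisotropy_interior_matches_sequential_1d_oracle(self, source):
        ar, at, af = source.aniso_r_cm, source.aniso_theta_deg, source.aniso_f
        rng = np.random.default_rng(7)
        for _ in range(25):
            r = rng.uniform(ar[0], ar[-1])
            t = rng.uniform(at[0], at[-1])
            # oracle: interpolate along theta at each r node, then along r
            along_theta = np.array([np.interp(t, at, af[i]) for i in range(len(ar))])
            want = np.interp(r, ar, along_theta)
            assert interpolate_anisotropy(source, r, t) == pytest.approx(want, rel=1e-12)

    def test_nonrectangular_grid_rejected(self):
        with pytest.raises(ValueError):
            SourceDescription(
                "bad", 3.5, 1.1,
                np.array([1.0]), np.array([1.0]),
                np.array([1.0, 2.0]), np.array([0.0, 90.0, 180.0]),
                np.ones((3, 2)),
            )


class TestDecay:
    def _plan(self, days):
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        return Plan([dwell], 1000.0, date(2017, 1, 1), date(2017, 1, 1) + __import__("datetime").timedelta(days=days))

    def test_no_decay_and_half_life(self, source):
        assert decayed_strength(self._plan(0), source) == 1000.0
        src_73 = SourceDescription(
            "t", 3.5, 1.1, source.radial_r_cm, source.radial_g,
            source.aniso_r_cm, source.aniso_theta_deg, source.aniso_f, half_life_days=73.0,
        )
        assert decayed_strength(self._plan(73), src_73) == pytest.approx(500.0)

    def test_ten_days_matches_exponential_form(self, source):
        got = decayed_strength(self._plan(10), source)
        assert got == pytest.approx(1000.0 * 2 ** (-10 / 73.83), rel=1e-12)
        assert got == pytest.approx(1000.0 * np.exp(-np.log(2) * 10 / 73.83), rel=1e-12)


class TestDoseRate:
    def test_reference_point_returns_dose_rate_constant(self, source):
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        rate, near = dose_rate_at_point(dwell, [10.0, 0.0, 0.0], source, 1.0)
        assert rate == pytest.approx(source.dose_rate_constant, rel=1e-12)
        assert not near

    def test_transverse_plane_mirror_symmetry(self, flat_source):
        # geometric symmetry of the kernel: holds exactly for a
        # pole-symmetric anisotropy table (the packaged tables are
        # cable-asymmetric, as physical sources are)
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        up, _ = dose_rate_at_point(dwell, [7.0, 2.0, 5.0], flat_source, 100.0)
        down, _ = dose_rate_at_point(dwell, [7.0, 2.0, -5.0], flat_source, 100.0)
        assert up == pytest.approx(down, rel=1e-9)

    def test_flat_source_reduces_to_geometry_ratio(self, flat_source):
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        g0 = geometry_function_line(1.0, 90.0, flat_source.active_length_cm)
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(-30, 30, 3)
            r = np.linalg.norm(p) / 10.0
            th = np.degrees(np.arccos(p[2] / np.linalg.norm(p)))
            want = line_integration_oracle(r, th, flat_source.active_length_cm, 50_001) / g0
            rate, _ = dose_rate_at_point(dwell, p, flat_source, 1.0)
            assert rate == pytest.approx(want, rel=1e-5)

    def test_near_source_flag(self, source):
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 1.0)
        _, near = dose_rate_at_point(dwell, [0.3, 0.0, 0.0], source, 1.0)
        assert near
        _, near = dose_rate_at_point(dwell, [0.3, 0.0, 5.0], source, 1.0)
        assert not near


class TestTotalDose:
    def _toy_plan(self, times):
        dwells = [
            DwellPosition(np.array([0.0, 0.0, -5.0]), np.array([0, 0, 1.0]), times[0]),
            DwellPosition(np.array([3.0, 1.0, 0.0]), np.array([0, 0.1, 1.0]), times[1]),
            DwellPosition(np.array([-4.0, 2.0, 6.0]), np.array([0.1, 0, 1.0]), times[2]),
        ]
        return Plan(dwells, 10_000.0, date(2017, 1, 1), date(2017, 1, 1))

    def test_zero_time_dwell_contributes_nothing(self, source):
        pts = np.random.default_rng(0).uniform(-20, 20, (50, 3))
        with_zero = total_dose(self._toy_plan([1.0, 2.0, 0.0]), source, pts)
        without = total_dose(
            Plan(self._toy_plan([1.0, 2.0, 0.0]).dwells[:2], 10_000.0, date(2017, 1, 1), date(2017, 1, 1)),
            source, pts,
        )
        np.testing.assert_allclose(with_zero, without, rtol=1e-12)

    def test_linearity_in_dwell_times(self, source):
        pts = np.random.default_rng(1).uniform(-20, 20, (100, 3))
        base = total_dose(self._toy_plan([1.0, 0.5, 2.0]), source, pts)
        doubled = total_dose(self._toy_plan([2.0, 1.0, 4.0]), source, pts)
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-12)

    def test_additivity_against_per_dwell_oracle(self, source):
        plan = self._toy_plan([1.0, 2.0, 3.0])
        pts = np.random.default_rng(2).uniform(-25, 25, (40, 3))
        total = total_dose(plan, source, pts)
        strength = decayed_strength(plan, source)
        acc = np.zeros(len(pts))
        for d in plan.dwells:
            for i, p in enumerate(pts):
                rate, _ = dose_rate_at_point(d, p, source, strength)
                acc[i] += rate * d.dwell_time_s * 0.01 / 3600.0
        np.testing.assert_allclose(total, acc, rtol=1e-9)

    def test_rigid_rotation_invariance(self, source):
        plan = self._toy_plan([1.0, 2.0, 3.0])
        pts = np.random.default_rng(4).uniform(-25, 25, (60, 3))
        dose = total_dose(plan, source, pts)
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
        ) @ np.array([[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)], [0, np.sin(0.3), np.cos(0.3)]])
        rotated = Plan(
            [
                DwellPosition(R @ d.position_mm, R @ d.axis_direction, d.dwell_time_s)
                for d in plan.dwells
            ],
            plan.air_kerma_strength_U, plan.calibration_date, plan.treatment_date,
        )
        dose_rot = total_dose(rotated, source, pts @ R.T)
        np.testing.assert_allclose(dose_rot, dose, rtol=1e-9)

    def test_point_source_limit_closed_form(self, flat_source):
        """With L -> 0 and flat tables the dose rate is Lambda / r^2."""
        tiny = SourceDescription(
            "tiny", 1e-4, 1.0,
            flat_source.radial_r_cm, flat_source.radial_g,
            flat_source.aniso_r_cm, flat_source.aniso_theta_deg, flat_source.aniso_f,
        )
        dwell = DwellPosition(np.zeros(3), np.array([0, 0, 1.0]), 3600.0 * 100.0)
        plan = Plan([dwell], 1.0, date(2017, 1, 1), date(2017, 1, 1))
        pts = np.random.default_rng(5).uniform(-30, 30, (30, 3))
        r_cm = np.linalg.norm(pts, axis=1) / 10.0
        dose = total_dose(plan, tiny, pts)
        np.testing.assert_allclose(dose, 1.0 / r_cm**2, rtol=1e-6)

    def test_near_identical_sources_give_near_identical_dose(self, source):
        """Continuity across a source-model swap: a table perturbation below
        eps changes any point dose by a comparably bounded amount."""
        eps = 1e-3
        perturbed = SourceDescription(
            "pert", source.active_length_mm, source.dose_rate_constant * (1 + eps),
            source.radial_r_cm, source.radial_g * (1 + eps),
            source.aniso_r_cm, source.aniso_theta_deg, source.aniso_f,
            source.half_life_days,
        )
        plan = self._toy_plan([1.0, 2.0, 3.0])
        pts = np.random.default_rng(6).uniform(-25, 25, (50, 3))
        a = total_dose(plan, source, pts)
        b = total_dose(plan, perturbed, pts)
        assert np.max(np.abs(b / a - 1.0)) < 3 * eps
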