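"""Wall-kinematics contracts: exact volume conservation, consistency of the
prescribed velocity with the wall position, periodicity, and the
occlusion-ratio inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumenflow.kinematics import (
    INTENSITY_LEVELS,
    MotilityCase,
    WallGeometry,
    check_volume_conservation,
    derive_geometry,
    wall_radius,
    wall_velocity,
)


class TestDeriveGeometry:
    def test_rest_radius_holds_pocket_volume(self, seg_geom, seg_geom_10ml):
        # r0 = sqrt(V / (pi * lambda)); cross-check by integrating the rest
        # cylinder volume over one wavelength
        for geom, vol in ((seg_geom, 2.0), (seg_geom_10ml, 10.0)):
            assert math.pi * geom.r0**2 * geom.wavelength == pytest.approx(vol)
        assert seg_geom.r0 == pytest.approx(0.5150, abs=1e-4)
        assert seg_geom_10ml.r0 == pytest.approx(0.8811, abs=1e-4)

    def test_volume_recovered_by_quadrature_at_t0(self, seg_geom):
        # at t = 0 the wall is the undeformed cylinder
        z = np.linspace(0.0, seg_geom.wavelength, 4001)
        h = seg_geom.radius(z, 0.0)
        vol = np.trapezoid(math.pi * h**2, z)
        assert vol == pytest.approx(2.0, rel=1e-10)

    def test_min_cycle_radius_defines_occlusion_ratio(self, seg_geom):
        # dense scan over one cycle must attain OR * r0 as its minimum
        z = np.linspace(0.0, seg_geom.wavelength, 801)
        t = np.linspace(0.0, seg_geom.period, 801)
        h = seg_geom.radius(z[None, :], t[:, None])
        assert h.min() == pytest.approx(0.3 * seg_geom.r0, rel=1e-5)

    def test_excursion_ratio_large_vs_small_pocket(self, seg_geom, seg_geom_10ml):
        # the 10 mL epithelium travels ~1.7x the radial distance per cycle
        ratio = seg_geom_10ml.delta / seg_geom.delta
        assert ratio == pytest.approx(1.711, abs=0.002)
        assert ratio == pytest.approx(seg_geom_10ml.r0 / seg_geom.r0)

    def test_peristalsis_amplitude_without_offset(self, peri_geom):
        assert peri_geom.delta == pytest.approx(0.7 * peri_geom.r0)
        assert peri_geom.min_radius() == pytest.approx(0.3 * peri_geom.r0)

    @pytest.mark.parametrize("bad_or", [0.0, 1.0, -0.2, 1.4])
    def test_rejects_nonphysical_occlusion_ratio(self, bad_or):
        with pytest.raises(ValueError, match="occlusion ratio"):
            derive_geometry(2.0, 2.4, bad_or, "segmentation", period=5.0)

    def test_rejects_overlarge_amplitude(self):
        with pytest.raises(ValueError, match="sqrt"):
            WallGeometry(
                motility="segmentation",
                r0=0.5,
                delta=0.75,
                wavelength=2.4,
                period=5.0,
            )


class TestSegmentationWaveform:
    def test_correction_term_vanishes_at_t0(self, seg_geom):
        assert seg_geom.correction_velocity(0.0) == pytest.approx(0.0, abs=1e-15)

    def test_velocity_at_quarter_wavelength_is_pure_correction(self, seg_geom):
        # cos(2 pi z / lambda) = 0 at z = lambda/4: only f(t) remains
        t = np.linspace(0.1, 4.9, 23)
        v = seg_geom.velocity(seg_geom.wavelength / 4.0, t)
        assert v == pytest.approx(seg_geom.correction_velocity(t), rel=1e-12)

    def test_correction_integrates_to_zero_over_period(self, seg_geom):
        from scipy.integrate import quad

        val, _ = quad(
            lambda t: float(seg_geom.correction_velocity(t)),
            0.0,
            seg_geom.period,
            limit=200,
        )
        assert abs(val) < 1e-12

    def test_wall_velocity_is_time_derivative_of_radius(self, seg_geom):
        z = np.linspace(0.0, 3 * seg_geom.wavelength, 61)
        eps = 1e-6
        for t in np.linspace(0.05, 9.95, 13):
            fd = (seg_geom.radius(z, t + eps) - seg_geom.radius(z, t - eps)) / (2 * eps)
            v = seg_geom.velocity(z, t)
            scale = np.abs(v).max() + 1e-3
            assert np.abs(fd - v).max() / scale < 1e-6

    def test_volume_conserved_at_many_times(self, seg_geom):
        errs = [
            check_volume_conservation(seg_geom, t)
            for t in np.linspace(0.0, seg_geom.period, 40)
        ]
        assert max(errs) < 1e-10

    def test_volume_error_without_correction_matches_expansion(self):
        # with the conservation offset disabled the relative volume error at
        # peak deformation is delta^2 / (2 r0^2)
        geom = derive_geometry(
            2.0, 2.4, 0.3, "segmentation", period=5.0, volume_offset=False
        )
        err = check_volume_conservation(geom, geom.period / 4.0)
        assert err == pytest.approx(geom.delta**2 / (2 * geom.r0**2), rel=1e-6)

    def test_zero_amplitude_is_a_static_cylinder(self):
        geom = WallGeometry(
            motility="segmentation", r0=0.5, delta=0.0, wavelength=2.4, period=5.0
        )
        assert check_volume_conservation(geom, 1.23) < 1e-14
        assert np.all(geom.velocity(np.linspace(0, 2.4, 11), 0.7) == 0.0)

    @settings(max_examples=25, deadline=None)
    @given(
        t=st.floats(0.0, 5.0),
        z=st.floats(0.0, 7.2),
    )
    def test_periodicity_in_space_and_time(self, t, z):
        geom = derive_geometry(2.0, 2.4, 0.3, "segmentation", period=5.0)
        h = geom.radius(z, t)
        assert geom.radius(z + geom.wavelength, t) == pytest.approx(h, rel=1e-12)
        assert geom.radius(z, t + geom.period) == pytest.approx(h, rel=1e-9)


class TestPeristalsisWaveform:
    def test_pure_travelling_wave(self, peri_geom):
        z = np.linspace(0.0, 2.4, 31)
        for dtau in (0.3, 1.1):
            lhs = peri_geom.radius(z, 1.0)
            rhs = peri_geom.radius(z + peri_geom.wave_speed * dtau, 1.0 + dtau)
            assert np.abs(lhs - rhs).max() < 1e-12

    def test_effective_period_is_wavelength_over_speed(self, peri_geom):
        assert peri_geom.period == pytest.approx(2.4 / 1.0)

    def test_travelling_wave_conserves_volume(self, peri_geom):
        for t in (0.0, 0.77, 1.9):
            assert check_volume_conservation(peri_geom, t) < 1e-10


class TestMotilityCase:
    def test_intensity_map(self):
        assert INTENSITY_LEVELS == {
            "light": (7.0, 0.5),
            "moderate": (5.0, 1.0),
            "vigorous": (3.0, 1.5),
        }

    def test_pocket_wavelength_pairing(self):
        assert MotilityCase(motility="segmentation", pocket_volume=2.0).resolved_wavelength == 2.4
        assert MotilityCase(motility="segmentation", pocket_volume=10.0).resolved_wavelength == 4.1

    def test_wavelength_override_and_missing_pairing(self):
        case = MotilityCase(motility="segmentation", pocket_volume=5.0, wavelength=3.0)
        assert case.resolved_wavelength == 3.0
        with pytest.raises(ValueError, match="wavelength"):
            MotilityCase(motility="segmentation", pocket_volume=5.0).resolved_wavelength

    def test_default_pocket_counts(self):
        seg = MotilityCase(motility="segmentation").geometry()
        per = MotilityCase(motility="peristalsis").geometry()
        assert seg.n_pockets == 3
        assert per.n_pockets == 30

    def test_functional_aliases(self, seg_geom):
        assert wall_radius(seg_geom, 0.3, 0.9) == seg_geom.radius(0.3, 0.9)
        assert wall_velocity(seg_geom, 0.3, 0.9) == seg_geom.velocity(0.3, 0.9)
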