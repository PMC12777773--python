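"""Fast flow-solver contracts (the quantitative verification fixtures —
rigid-tube flow, manufactured solution, lubrication limit — run in
tests/test_acceptance.py)."""

import numpy as np
import pytest

from lumenflow.flow import (
    FlowSolver,
    SegmentationWall,
    SolverConfig,
    StaticTube,
    WaveFrameWall,
    solve_peristalsis_flow,
    wall_shear_stress,
)
from lumenflow.fluids import FluidModel, get_fluid
from lumenflow.grid import AxialGrid
from lumenflow.kinematics import WallGeometry, derive_geometry


@pytest.fixture(scope="module")
def small_cfg():
    return SolverConfig(nr=12, nz_per_wave=16)


class TestTrivialStates:
    def test_zero_amplitude_segmentation_stays_at_rest(self, small_cfg):
        geom = WallGeometry(
            motility="segmentation", r0=0.5, delta=0.0, wavelength=2.4, period=5.0
        )
        ax = AxialGrid(nz=48, length=3 * 2.4)
        solver = FlowSolver(
            SegmentationWall(geom), get_fluid("water_37C"), ax, small_cfg, period=5.0
        )
        for _ in range(5):
            state = solver.step(0.02)
        assert np.abs(state.u).max() < 1e-14
        assert np.abs(state.v).max() < 1e-14

    def test_zero_amplitude_peristalsis_is_rigid_translation(self, small_cfg):
        geom = WallGeometry(
            motility="peristalsis",
            r0=0.5,
            delta=0.0,
            wavelength=2.4,
            period=2.4,
            wave_speed=1.0,
        )
        state = solve_peristalsis_flow(geom, get_fluid("water_37C"), small_cfg)
        # wave frame: uniform -c; lab frame: fluid at rest
        assert np.abs(state.u + 1.0).max() < 1e-10
        assert np.abs(state.v).max() < 1e-10

    def test_zero_flow_has_zero_wall_shear(self, small_cfg):
        geom = WallGeometry(
            motility="segmentation", r0=0.5, delta=0.0, wavelength=2.4, period=5.0
        )
        ax = AxialGrid(nz=48, length=3 * 2.4)
        solver = FlowSolver(
            SegmentationWall(geom), get_fluid("water_37C"), ax, small_cfg, period=5.0
        )
        state = solver.step(0.02)
        tau, tau_avg, tau_max = wall_shear_stress(
            state, get_fluid("water_37C"), solver.rad, ax.dz
        )
        assert tau_avg == pytest.approx(0.0, abs=1e-12)
        assert tau_max == pytest.approx(0.0, abs=1e-12)


class TestSegmentationStepping:
    def test_divergence_free_and_finite(self, seg_geom, small_cfg):
        ax = AxialGrid(nz=48, length=3 * seg_geom.wavelength)
        solver = FlowSolver(
            SegmentationWall(seg_geom),
            get_fluid("water_37C"),
            ax,
            small_cfg,
            period=seg_geom.period,
        )
        for _ in range(25):
            state = solver.step(solver.suggest_dt())
        assert state.div_norm < small_cfg.pressure_tol * 10
        assert np.isfinite(state.u).all()
        # velocities in the physiological range reported for these waves
        assert 0.05 < np.abs(state.speed()).max() < 10.0

    def test_power_law_viscosity_field_tracks_shear(self, seg_geom, small_cfg):
        fluid = get_fluid("nutridrink_default").with_ref_shear_rate(1.0)
        ax = AxialGrid(nz=48, length=3 * seg_geom.wavelength)
        solver = FlowSolver(
            SegmentationWall(seg_geom), fluid, ax, small_cfg, period=seg_geom.period
        )
        for _ in range(10):
            state = solver.step(solver.suggest_dt())
        lo, hi = fluid.shear_clamp
        mu_min = fluid.viscosity(hi)
        mu_max = fluid.viscosity(lo)
        assert np.all(state.mu >= mu_min - 1e-12)
        assert np.all(state.mu <= mu_max + 1e-12)
        assert state.mu.std() > 0  # genuinely shear-dependent

    def test_nonfinite_blowup_aborts_with_diagnostics(self, seg_geom, small_cfg):
        ax = AxialGrid(nz=48, length=3 * seg_geom.wavelength)
        solver = FlowSolver(
            SegmentationWall(seg_geom),
            get_fluid("water_37C"),
            ax,
            small_cfg,
            period=seg_geom.period,
        )
        with pytest.raises(RuntimeError, match="non-finite|inadequate"):
            for _ in range(300):
                solver.step(1.5)  # grossly CFL-violating step


class TestWaveFrame:
    @pytest.fixture(scope="class")
    def steady(self, peri_geom, small_cfg):
        # a viscous fluid reaches steady state quickly; the wave-frame
        # contracts are fluid-independent
        fluid = FluidModel(name="syrup", density=1.0, rheology="newtonian", mu=30.0)
        ax = AxialGrid(nz=small_cfg.nz_per_wave, length=peri_geom.wavelength)
        solver = FlowSolver(
            WaveFrameWall(peri_geom),
            fluid,
            ax,
            small_cfg,
            period=peri_geom.period,
            u0=-peri_geom.wave_speed,
        )
        return solver, solver.run_to_steady()

    def test_steady_state_is_stationary(self, steady):
        solver, state = steady
        u0 = state.u.copy()
        for _ in range(40):
            state2 = solver.step()
        scale = max(np.abs(u0).max(), 1e-12)
        assert np.abs(state2.u - u0).max() / scale < 1e-4

    def test_lab_frame_adds_wave_speed(self, steady, peri_geom):
        from lumenflow.flow import lab_frame_velocity

        _, state = steady
        u_lab, v_lab = lab_frame_velocity(state, peri_geom)
        assert np.allclose(u_lab - state.u, peri_geom.wave_speed)
        assert v_lab is state.v

    def test_wave_frame_wall_is_impermeable(self, peri_geom, small_cfg):
        # u_wall = -c, v_wall = -c h' gives zero normal flux through the wall
        ax = AxialGrid(nz=32, length=peri_geom.wavelength)
        wall = WaveFrameWall(peri_geom)
        z = ax.zc
        un = -wall.u_wall(z, 0.0) * wall.dradius_dz(z, 0.0) + wall.v_wall(z, 0.0)
        assert np.abs(un).max() < 1e-14
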