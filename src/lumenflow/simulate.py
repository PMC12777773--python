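"""End-to-end simulation of one motility case.

``run_case`` couples the flow solver and the scalar transport step by step,
collects the delivery metrics each step, and returns a
:class:`~lumenflow.metrics.DeliveryMetrics` plus peak bookkeeping for the
colocalisation score.

Segmentation: transient flow and transport share a 3-wavelength periodic
grid (transport ends open); release in the middle pocket.

Peristalsis: the steady wave-frame flow over one wavelength is tiled over a
30-pocket domain; transport runs in the wave frame with a fixed step.  The
release pocket is placed so the wave-frame drift of the bolus (estimated
from the computed wave-frame flux) stays inside the domain for the full
simulated duration; lab-frame peak positions are recovered by adding c*t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fluids import FluidModel, get_fluid, get_species
from .flow import (
    FlowSolver,
    RESOLUTIONS,
    SegmentationWall,
    SolverConfig,
    WaveFrameWall,
    solve_peristalsis_flow,
    wall_shear_stress,
)
from .grid import AxialGrid, RadialGrid
from .kinematics import MotilityCase, WallGeometry
from .metrics import (
    DeliveryMetrics,
    PeakInfo,
    escape_fraction,
    near_wall_fraction,
    wall_concentration,
)
from .transport import (
    ConcentrationHistory,
    ReleaseSpec,
    TransportSolver,
    bundle_from_state,
    initialize_bolus,
    tile_peristalsis_state,
    _volumes,
)

__all__ = ["CaseResult", "run_case", "characteristic_shear_rate"]


def characteristic_shear_rate(geom: WallGeometry) -> float:
    """Reference shear rate (2*pi*delta/tp)/r0 for diffusivity rescaling."""
    return (2.0 * math.pi * geom.delta / geom.period) / geom.r0


@dataclass
class CaseResult:
    case: MotilityCase
    geom: WallGeometry
    metrics: DeliveryMetrics
    history: ConcentrationHistory
    duration: float
    released_moles: dict
    final_moles: dict

    def peak_summary(self) -> dict:
        return {
            "peaks": self.metrics.peaks,
            "duration": self.duration,
            "wavelength": self.geom.wavelength,
            "r0": self.geom.r0,
        }


def _resolve_fluid(case: MotilityCase, geom: WallGeometry) -> FluidModel:
    fluid = get_fluid(case.fluid_id)
    if fluid.rheology == "power_law":
        fluid = fluid.with_ref_shear_rate(characteristic_shear_rate(geom))
    return fluid


def _metric_collector(case: MotilityCase, geom: WallGeometry) -> DeliveryMetrics:
    D_rest = 2.0 * geom.r0
    thick = {"D15": D_rest / 15.0, "D30": D_rest / 30.0}
    m = DeliveryMetrics(case_label=case.label(), thicknesses=thick)
    for s in case.species:
        m.near_wall_pct[s] = {k: [] for k in thick}
        m.escape_pct[s] = []
        m.wall_max_trace[s] = []
        m.peaks[s] = PeakInfo()
        m.onset[s] = None
        m.profiles[s] = []
    return m


def _collect(
    m: DeliveryMetrics,
    hist: ConcentrationHistory,
    V: np.ndarray,
    hc: np.ndarray,
    ax: AxialGrid,
    rad: RadialGrid,
    geom: WallGeometry,
    t: float,
    z_window: tuple[float, float] | None,
    lab_shift: float,
    tau: tuple[float, float],
    record_profile: bool,
) -> None:
    m.times.append(t)
    m.tau_avg.append(tau[0])
    m.tau_max.append(tau[1])
    for sp in hist.species:
        name = sp.name
        c = hist.c[name]
        total = hist.released_moles[name]
        for label, a in m.thicknesses.items():
            m.near_wall_pct[name][label].append(
                near_wall_fraction(c, V, hc, rad, a, total)
            )
        if z_window is not None:
            m.escape_pct[name].append(
                escape_fraction(c, V, ax, z_window[0], z_window[1], total)
            )
        wall = wall_concentration(c) / sp.initial_concentration
        i_pk = int(np.argmax(wall))
        val = float(wall[i_pk])
        m.wall_max_trace[name].append(max(val, m.wall_max_trace[name][-1] if m.wall_max_trace[name] else 0.0))
        z_lab = ax.zc[i_pk] + lab_shift
        m.peaks[name].update(val, t, z_lab, float(hc[i_pk]))
        if m.onset[name] is None and val > 1e-3:
            m.onset[name] = t
        if record_profile:
            m.profiles[name].append((t, wall.copy()))


def run_case(
    case: MotilityCase,
    resolution: str | SolverConfig = "coarse",
    *,
    n_periods: float | None = None,
    release: ReleaseSpec | None = None,
    collect_every: int = 1,
    profile_every_periods: float = 2.0,
    snapshot_every_periods: float | None = None,
) -> CaseResult:
    """Simulate one case end to end and collect delivery metrics."""
    cfg = RESOLUTIONS[resolution] if isinstance(resolution, str) else resolution
    geom = case.geometry()
    fluid = _resolve_fluid(case, geom)
    species = [get_species(s) for s in case.species]
    n_per = float(n_periods if n_periods is not None else case.n_periods)
    if release is None:
        release = ReleaseSpec(position=case.release_position)
    if case.motility == "segmentation":
        return _run_segmentation(
            case, geom, fluid, species, cfg, n_per, release,
            collect_every, profile_every_periods, snapshot_every_periods,
        )
    return _run_peristalsis(
        case, geom, fluid, species, cfg, n_per, release,
        collect_every, profile_every_periods, snapshot_every_periods,
    )


def _run_segmentation(
    case, geom, fluid, species, cfg, n_per, release,
    collect_every, profile_every_periods, snapshot_every_periods,
):
    ax = AxialGrid(nz=cfg.nz_per_wave * geom.n_pockets, length=geom.domain_length)
    rad = RadialGrid(cfg.nr, cfg.beta_stretch)
    solver = FlowSolver(SegmentationWall(geom), fluid, ax, cfg, rad=rad, period=geom.period)
    ts = TransportSolver(ax, rad, species, fluid, end_bc="open")

    z0 = release.axial_position(geom)
    hist = initialize_bolus(ax, rad, solver.wa.hc, species, z0, release.sigma_or_default(geom))
    hist.record()
    m = _metric_collector(case, geom)
    zc_pocket = geom.pocket_center(geom.n_pockets // 2)
    z_window = (zc_pocket - geom.wavelength / 2.0, zc_pocket + geom.wavelength / 2.0)

    t_end = n_per * geom.period
    t_profile = profile_every_periods * geom.period
    t_snap = None if snapshot_every_periods is None else snapshot_every_periods * geom.period
    next_profile, next_snap = 0.0, 0.0
    n = 0
    # first sample at t=0
    V0 = _volumes(ax, rad, solver.wa.hc)
    tau0 = (0.0, 0.0)
    _collect(m, hist, V0, solver.wa.hc, ax, rad, geom, 0.0, z_window, 0.0, tau0, True)
    next_profile = t_profile
    while solver.t < t_end - 1e-12:
        dt = min(solver.suggest_dt(), t_end - solver.t)
        state = solver.step(dt)
        b = bundle_from_state(state, ax, rad)
        ts.step(hist, b)
        n += 1
        if n % collect_every == 0 or solver.t >= t_end - 1e-12:
            rec_prof = solver.t >= next_profile
            if rec_prof:
                next_profile += t_profile
            tau, tau_avg, tau_mx = wall_shear_stress(
                state, fluid, rad, ax.dz, wall_v=state.wa.ht_c
            )
            V1 = _volumes(ax, rad, state.wa.hc)
            _collect(
                m, hist, V1, state.wa.hc, ax, rad, geom, solver.t,
                z_window, 0.0, (tau_avg, tau_mx), rec_prof,
            )
        if t_snap is not None and solver.t >= next_snap:
            hist.record()
            next_snap += t_snap

    umax = float(np.hypot(solver.u, solver.v).max())
    m.reynolds = fluid.density * umax * geom.r0 / (fluid.reference_viscosity * 0.01)
    for sp in species:
        D = float(np.min(sp.diffusivity(sp.initial_concentration, fluid)))
        m.peclet[sp.name] = umax * geom.r0 / D
    Vf = _volumes(ax, rad, solver.wa.hc)
    return CaseResult(
        case=case, geom=geom, metrics=m, history=hist,
        duration=t_end, released_moles=dict(hist.released_moles),
        final_moles=hist.total_moles(Vf),
    )


def _run_peristalsis(
    case, geom, fluid, species, cfg, n_per, release,
    collect_every, profile_every_periods, snapshot_every_periods,
):
    # steady wave-frame flow over one wavelength
    ax_wave = AxialGrid(nz=cfg.nz_per_wave, length=geom.wavelength)
    rad = RadialGrid(cfg.nr, cfg.beta_stretch)
    wsolver = FlowSolver(
        WaveFrameWall(geom), fluid, ax_wave, cfg, rad=rad,
        period=geom.period, u0=-geom.wave_speed,
    )
    wstate = wsolver.run_to_steady()
    ax, bundle = tile_peristalsis_state(wstate, geom, ax_wave, rad)
    ts = TransportSolver(ax, rad, species, fluid, end_bc="open")

    # wave-frame bolus drift: mean wave-frame flux (< 0) over the mean area
    F_wave = float(wstate.F[:, :].sum(axis=1).mean())
    area = math.pi * geom.r0**2
    drift_speed = abs(F_wave) / area
    t_end = n_per * geom.period
    drift = 1.5 * drift_speed * t_end + 2.0 * geom.wavelength
    k_rel = min(geom.n_pockets - 2, int(math.ceil(drift / geom.wavelength)))
    z0 = release.axial_position(geom, pocket=k_rel)
    # the bolus must fit inside the locally occluded lumen of the static
    # wave: shrink it to the release-station radius where necessary
    i0 = int(np.argmin(np.abs(ax.zc - z0)))
    h_local = float(bundle.hc[max(0, i0 - 2) : i0 + 3].min())
    sigma = min(release.sigma_or_default(geom), 0.95 * h_local / 4.0)
    hist = initialize_bolus(ax, rad, bundle.hc, species, z0, sigma)
    hist.record()
    m = _metric_collector(case, geom)

    # fixed transport step from the wave-frame CFL; the scalar-only update
    # (flux-limited upwind, explicit) is stable to CFL 1/2, so it may step
    # faster than the momentum solver's conservative setting
    vmax = max(float(np.abs(wstate.u).max()), 1e-9)
    wmax = max(float(np.abs(wstate.v).max()), 1e-9)
    dr_min = float((rad.deta * bundle.hc.min()).min())
    dt = max(cfg.cfl, 0.45) * min(ax.dz / vmax, dr_min / wmax)
    n_steps = int(math.ceil(t_end / dt))
    dt = t_end / n_steps

    tau, tau_avg, tau_mx = wall_shear_stress(
        wstate, fluid, rad, ax_wave.dz,
        wall_u=np.full(ax_wave.nz, -geom.wave_speed),
        wall_v=-geom.wave_speed * wstate.wa.dhz_c,
    )
    V = bundle.V0
    _collect(m, hist, V, bundle.hc, ax, rad, geom, 0.0, None, geom.wave_speed * 0.0, (tau_avg, tau_mx), True)
    t_profile = profile_every_periods * geom.period
    next_profile = t_profile
    t_snap = None if snapshot_every_periods is None else snapshot_every_periods * geom.period
    next_snap = t_snap if t_snap is not None else None
    for n in range(1, n_steps + 1):
        ts.step(hist, bundle, dt)
        t = n * dt
        # guard: bolus must stay inside the wave-frame domain
        c0 = hist.c[species[0].name]
        com = float((c0 * V * ax.zc[:, None]).sum() / max((c0 * V).sum(), 1e-300))
        if com < 1.5 * geom.wavelength:
            raise RuntimeError(
                "peristalsis bolus is reaching the upstream domain end; "
                "increase n_pockets for this configuration"
            )
        if n % collect_every == 0 or n == n_steps:
            rec_prof = t >= next_profile
            if rec_prof:
                next_profile += t_profile
            _collect(
                m, hist, V, bundle.hc, ax, rad, geom, t, None,
                geom.wave_speed * t, (tau_avg, tau_mx), rec_prof,
            )
        if next_snap is not None and t >= next_snap:
            hist.record()
            next_snap += t_snap

    u_lab = wstate.u + geom.wave_speed
    umax = float(np.hypot(u_lab, wstate.v).max())
    m.reynolds = fluid.density * umax * geom.r0 / (fluid.reference_viscosity * 0.01)
    for sp in species:
        D = float(np.min(sp.diffusivity(sp.initial_concentration, fluid)))
        m.peclet[sp.name] = umax * geom.r0 / D
    return CaseResult(
        case=case, geom=geom, metrics=m, history=hist,
        duration=t_end, released_moles=dict(hist.released_moles),
        final_moles=hist.total_moles(V),
    )
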