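"""Transient axisymmetric laminar flow in a deforming lumen.

The incompressible Navier-Stokes equations are solved on the boundary-fitted
map ``eta = r/h(z, t)`` (an arbitrary Lagrangian-Eulerian formulation in
mapped coordinates; the mesh follows the wall exactly, no remeshing) with a
semi-implicit pressure-projection scheme:

1. momentum advection — explicit two-stage Runge-Kutta with a second-order
   linear-upwind face reconstruction, using the divergence-free face fluxes
   of the previous step (relative to the mesh motion);
2. viscous terms — the stress divergence is split *exactly* into a
   direction-wise diffusion operator (implicit, sparse direct solves; axial
   coefficient 2*mu for u and mu for v, radial coefficient mu for u and 2*mu
   for v, plus the -2*mu*v/r^2 geometric term) and a single mixed-derivative
   remainder per component (explicit):
       remainder_z = (1/r) d/dr ( r * mu * dv/dz ),
       remainder_r =       d/dz (     mu * du/dr );
   metric cross-derivative fluxes of the implicit operator are applied as
   explicit deferred corrections;
3. projection — face volume fluxes built from the provisional velocity are
   projected onto a discretely divergence-free space; the metric cross terms
   of the pressure operator are converged by a deferred-correction iteration,
   so the final face fluxes are divergence-free to the solver tolerance.

Generalised-Newtonian (power-law) rheology enters through a lagged
shear-rate-dependent viscosity field.  The same stepper serves the moving
segmentation problem, the steady peristaltic problem in the wave frame
(stationary wall, ``u_wall = -c``, ``v_wall = -c dh/dz``), and rigid-tube
verification fixtures with body forces.

Units: CGS (cm, s, g); viscosities are converted from mPa*s internally;
pressures are reported in Pa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
from scipy.sparse.linalg import splu

from .fluids import FluidModel, MPAS_TO_POISE
from .grid import AxialGrid, FVOperators, RadialGrid, WallArrays
from .kinematics import WallGeometry

__all__ = [
    "SolverConfig",
    "FieldState",
    "FlowSolver",
    "SegmentationWall",
    "WaveFrameWall",
    "StaticTube",
    "solve_segmentation_flow",
    "solve_peristalsis_flow",
    "wall_shear_stress",
    "RESOLUTIONS",
]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings of the flow/transport solvers."""

    nz_per_wave: int = 32
    nr: int = 16
    beta_stretch: float = 1.8
    cfl: float = 0.3
    dt_max_frac: float = 1.0 / 160.0  # dt <= frac * period
    pressure_tol: float = 1e-10  # relative divergence tolerance
    pressure_max_iter: int = 40
    steady_tol: float = 1e-5  # relative velocity change per characteristic time
    steady_max_steps: int = 20000
    filter_alpha: float = 0.2  # 4th-difference axial filter on cell velocities


#: Named resolution presets.  "production" mirrors a grid-converged setting;
#: "coarse" is the scaled-down preset used for tests and sweeps.
RESOLUTIONS: dict[str, SolverConfig] = {
    "coarse": SolverConfig(nz_per_wave=32, nr=16),
    "medium": SolverConfig(nz_per_wave=64, nr=32),
    "production": SolverConfig(nz_per_wave=128, nr=64, beta_stretch=2.6),
}


# ---------------------------------------------------------------------------
# Wall adapters: geometry + fluid boundary values in the solver frame.


class SegmentationWall:
    """Moving wall of a segmenting segment (lab frame)."""

    moving = True

    def __init__(self, geom: WallGeometry):
        if geom.motility != "segmentation":
            raise ValueError("SegmentationWall requires a segmentation geometry")
        self.geom = geom

    def radius(self, z, t):
        return self.geom.radius(z, t)

    def dradius_dz(self, z, t):
        return self.geom.dradius_dz(z, t)

    def velocity_c(self, z, t):  # mesh (= wall) radial velocity
        return self.geom.velocity(z, t)

    def u_wall(self, z, t):
        return np.zeros_like(np.asarray(z, dtype=float))

    def v_wall(self, z, t):
        return self.geom.velocity(z, t)


class WaveFrameWall:
    """Static wall of a peristaltic wave seen from the wave frame."""

    moving = False

    def __init__(self, geom: WallGeometry):
        if geom.motility != "peristalsis":
            raise ValueError("WaveFrameWall requires a peristalsis geometry")
        self.geom = geom
        self.c = geom.wave_speed

    def radius(self, z, t):
        return self.geom.radius(z, 0.0)

    def dradius_dz(self, z, t):
        return self.geom.dradius_dz(z, 0.0)

    def velocity_c(self, z, t):
        return np.zeros_like(np.asarray(z, dtype=float))

    def u_wall(self, z, t):
        return np.full_like(np.asarray(z, dtype=float), -self.c)

    def v_wall(self, z, t):
        # material wall point: lab velocity (0, dh/dt) = (0, -c h'); minus
        # the frame translation (c, 0) gives (-c, -c h')
        return -self.c * self.geom.dradius_dz(np.asarray(z, dtype=float), 0.0)


class StaticTube:
    """Rigid straight tube (verification fixtures)."""

    moving = False

    def __init__(self, radius: float, u_wall: float = 0.0):
        self.R = radius
        self._uw = u_wall

    def radius(self, z, t):
        return np.full_like(np.asarray(z, dtype=float), self.R)

    def dradius_dz(self, z, t):
        return np.zeros_like(np.asarray(z, dtype=float))

    def velocity_c(self, z, t):
        return np.zeros_like(np.asarray(z, dtype=float))

    def u_wall(self, z, t):
        return np.full_like(np.asarray(z, dtype=float), self._uw)

    def v_wall(self, z, t):
        return np.zeros_like(np.asarray(z, dtype=float))


# ---------------------------------------------------------------------------


@dataclass
class FieldState:
    """Axisymmetric fields on the mapped grid at one instant.

    ``F``/``G`` are the projected (divergence-free) face volume fluxes
    through xi- and eta-faces; ``Gmesh`` the discrete mesh-motion flux, so
    ``G - Gmesh`` advects material quantities relative to the moving mesh.
    """

    t: float
    dt: float
    u: np.ndarray  # axial velocity, cm/s
    v: np.ndarray  # radial velocity, cm/s
    p: np.ndarray  # pressure, Pa (up to a constant)
    gamma_dot: np.ndarray  # shear-rate magnitude, 1/s
    mu: np.ndarray  # effective viscosity, mPa*s
    wa: WallArrays  # wall geometry at time t
    hc_old: np.ndarray  # wall radius at t - dt (for ALE transport volumes)
    F: np.ndarray  # (nz, nr) xi-face fluxes, cm^3/s
    G: np.ndarray  # (nz, nr+1) eta-face fluxes, cm^3/s
    Gmesh: np.ndarray  # (nz, nr+1) mesh-motion fluxes, cm^3/s
    div_norm: float = 0.0

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def _lud_faces_xi(phi: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Second-order linear-upwind face values at xi-faces (periodic)."""
    pm1 = np.roll(phi, 1, axis=0)
    pm2 = np.roll(phi, 2, axis=0)
    pp1 = np.roll(phi, -1, axis=0)
    up_pos = 1.5 * pm1 - 0.5 * pm2
    up_neg = 1.5 * phi - 0.5 * pp1
    return np.where(F >= 0.0, up_pos, up_neg)


def _lud_faces_eta(phi: np.ndarray, G_in: np.ndarray, rad: RadialGrid) -> np.ndarray:
    """Linear-upwind values at interior eta-faces j=1..nr-1, shape (nz, nr-1)."""
    ec, ef = rad.ec, rad.ef
    nz, nr = phi.shape
    # upwind from below (G >= 0): cell j-1, slope from (j-2, j-1);
    # the axis-adjacent face falls back to the downwind-side slope (Fromm)
    slope_lo = np.zeros((nz, nr - 1))
    slope_lo[:, 1:] = (phi[:, 1:-1] - phi[:, :-2]) / (ec[1:-1] - ec[:-2])
    slope_lo[:, 0] = (phi[:, 1] - phi[:, 0]) / (ec[1] - ec[0])
    val_lo = phi[:, :-1] + slope_lo * (ef[1:-1] - ec[:-1])[None, :]
    # upwind from above (G < 0): cell j, slope from (j, j+1)
    slope_hi = np.zeros((nz, nr - 1))
    slope_hi[:, :-1] = (phi[:, 2:] - phi[:, 1:-1]) / (ec[2:] - ec[1:-1])
    slope_hi[:, -1] = (phi[:, -1] - phi[:, -2]) / (ec[-1] - ec[-2])
    val_hi = phi[:, 1:] + slope_hi * (ef[1:-1] - ec[1:])[None, :]
    return np.where(G_in >= 0.0, val_lo, val_hi)


def _advect(
    phi: np.ndarray,
    F: np.ndarray,
    Gr_full: np.ndarray,
    V: np.ndarray,
    rad: RadialGrid,
) -> np.ndarray:
    """Advective tendency -(1/V) * sum_faces F_out * (phi_face - phi_c)."""
    pf = _lud_faces_xi(phi, F)
    out = np.roll(F, -1, axis=0) * (np.roll(pf, -1, axis=0) - phi) - F * (pf - phi)
    G_in = Gr_full[:, 1:-1]
    pg = _lud_faces_eta(phi, G_in, rad)
    out[:, 1:] -= G_in * (pg - phi[:, 1:])  # bottom faces of cells j>=1
    out[:, :-1] += G_in * (pg - phi[:, :-1])  # top faces of cells j<=nr-2
    # axis face flux is zero; wall-face relative flux is zero (impermeable)
    return -out / V


class FlowSolver:
    """Semi-implicit projection solver on the mapped moving grid."""

    def __init__(
        self,
        wall,
        fluid: FluidModel,
        ax: AxialGrid,
        cfg: SolverConfig,
        *,
        rad: RadialGrid | None = None,
        period: float | None = None,
        body_accel: Callable | None = None,
        u0: float = 0.0,
    ):
        self.wall = wall
        self.fluid = fluid
        self.ax = ax
        self.rad = rad or RadialGrid(cfg.nr, cfg.beta_stretch)
        self.cfg = cfg
        self.ops = FVOperators(ax, self.rad)
        self.period = period
        self.body_accel = body_accel
        self.rho = fluid.density

        nz, nr = ax.nz, self.rad.nr
        self.t = 0.0
        self.u = np.full((nz, nr), float(u0))
        self.v = np.zeros((nz, nr))
        self.p = np.zeros((nz, nr))
        self.wa = WallArrays.sample(wall, ax, 0.0)
        self.gamma_dot = np.zeros((nz, nr))
        self.mu = np.asarray(
            fluid.viscosity(np.zeros((nz, nr))), dtype=float
        )  # clamped zero-shear value for power law
        self.F = self._face_flux_xi(self.u, self.wa)
        self.G = self._face_flux_eta(self.u, self.v, self.wa)
        self.Gmesh = np.zeros((nz, nr + 1))
        self.hc_old = self.wa.hc.copy()
        self._plu = None  # cached pressure factorisation (static walls)
        self._vlu = None  # cached viscous factorisations (static Newtonian)
        self._dt_pinned = None
        self.n_steps = 0

    # -- flux builders -----------------------------------------------------

    def _face_flux_xi(self, u: np.ndarray, wa: WallArrays) -> np.ndarray:
        uf = 0.5 * (u + np.roll(u, 1, axis=0))
        return (
            2.0
            * np.pi
            * self.ops.ec2
            * self.ops.deta2
            * wa.hf[:, None] ** 2
            * uf
        )

    def _face_flux_eta(
        self, u: np.ndarray, v: np.ndarray, wa: WallArrays
    ) -> np.ndarray:
        rad = self.rad
        nz, nr = u.shape
        G = np.zeros((nz, nr + 1))
        w = (rad.ef[1:-1] - rad.ec[:-1]) / rad.dec  # interp weights to faces
        uf = (1 - w)[None, :] * u[:, :-1] + w[None, :] * u[:, 1:]
        vf = (1 - w)[None, :] * v[:, :-1] + w[None, :] * v[:, 1:]
        ef = rad.ef[1:-1]
        G[:, 1:-1] = (
            2.0
            * np.pi
            * ef[None, :]
            * wa.hc[:, None]
            * (vf - uf * ef[None, :] * wa.dhz_c[:, None])
            * self.ax.dz
        )
        return G

    # -- time step ---------------------------------------------------------

    def suggest_dt(self) -> float:
        cfg, rad, ax = self.cfg, self.rad, self.ax
        wa = self.wa
        vr_rel = self.v - self.ops.ec2 * wa.ht_c[:, None]
        dr = rad.deta[None, :] * wa.hc[:, None]
        with np.errstate(divide="ignore"):
            dt_z = ax.dz / np.maximum(np.abs(self.u), 1e-12)
            dt_r = dr / np.maximum(np.abs(vr_rel), 1e-12)
        dt = cfg.cfl * min(dt_z.min(), dt_r.min())
        if self.period is not None:
            dt = min(dt, cfg.dt_max_frac * self.period)
        return dt

    def step(self, dt: float | None = None) -> FieldState:
        cfg, ops, rad, ax = self.cfg, self.ops, self.rad, self.ax
        rho = self.rho
        if dt is None:
            dt = self._dt_pinned if self._dt_pinned is not None else self.suggest_dt()
        t0, t1 = self.t, self.t + dt
        wa0 = self.wa
        wa1 = WallArrays.sample(self.wall, ax, t1) if self.wall.moving else wa0
        V0 = ops.volumes(wa0.hc)
        V1 = ops.volumes(wa1.hc) if self.wall.moving else V0

        # ---- explicit advection (RK2, frozen divergence-free fluxes) ----
        Gmesh_adv = (
            2.0
            * np.pi
            * rad.ef[None, :] ** 2
            * (wa0.hc * wa0.ht_c)[:, None]
            * ax.dz
        )
        Gr = self.G - Gmesh_adv
        Gr[:, 0] = 0.0
        Gr[:, -1] = 0.0
        # _advect returns the signed tendency d(phi)/dt; midpoint RK2
        k1u = _advect(self.u, self.F, Gr, V0, rad)
        k1v = _advect(self.v, self.F, Gr, V0, rad)
        k2u = _advect(self.u + 0.5 * dt * k1u, self.F, Gr, V0, rad)
        k2v = _advect(self.v + 0.5 * dt * k1v, self.F, Gr, V0, rad)
        ua = self.u + dt * k2u
        va = self.v + dt * k2v

        # ---- explicit viscous pieces at t0 ------------------------------
        nu = self.mu * MPAS_TO_POISE / rho  # cm^2/s
        du_dz, du_dr = ops.physical_gradients(self.u, wa0.hc, wa0.dhz_c)
        dv_dz, dv_dr = ops.physical_gradients(self.v, wa0.hc, wa0.dhz_c)
        r_c = ops.radii(wa0.hc)
        mvz = nu * dv_dz
        _, d_mvz_dr = ops.physical_gradients(mvz, wa0.hc, wa0.dhz_c)
        Ez = d_mvz_dr + mvz / r_c  # (1/r) d/dr (r mu v_z) / rho
        mur = nu * du_dr
        d_mur_dz, _ = ops.physical_gradients(mur, wa0.hc, wa0.dhz_c)
        Er = d_mur_dz
        ua += dt * Ez
        va += dt * Er
        if self.body_accel is not None:
            z2 = np.broadcast_to(ax.zc[:, None], self.u.shape)
            az, ar = self.body_accel(z2, r_c, t0)
            ua += dt * az
            va += dt * ar

        # deferred metric cross terms of the implicit operators (at t0)
        nf = 0.5 * (nu + np.roll(nu, 1, axis=0))
        ng = np.empty((ax.nz, rad.nr + 1))
        ng[:, 1:-1] = 0.5 * (nu[:, 1:] + nu[:, :-1])
        ng[:, 0] = nu[:, 0]
        ng[:, -1] = nu[:, -1]
        uw0 = np.asarray(self.wall.u_wall(ax.zc, t0), dtype=float)
        vw0 = np.asarray(self.wall.v_wall(ax.zc, t0), dtype=float)
        Xf, Xg = ops.cross_fluxes(
            wa0.hf, wa0.hc, wa0.dhz_c, wa0.dhz_f, 2 * nf, 2 * ng, self.u, uw0
        )
        ua += dt * ops.flux_divergence(Xf, Xg) / V0
        Xf, Xg = ops.cross_fluxes(
            wa0.hf, wa0.hc, wa0.dhz_c, wa0.dhz_f, nf, ng, self.v, vw0
        )
        va += dt * ops.flux_divergence(Xf, Xg) / V0

        # ---- previous pressure in the predictor (incremental projection:
        # the steady state then satisfies the unsplit momentum balance) ----
        if self._plu is None or self.wall.moving:
            ones = np.ones_like(self.u)
            onesg = np.ones((ax.nz, rad.nr + 1))
            Cf_p = ops.face_coeff_xi(wa1.hf, ones)
            Cg_p, _ = ops.face_coeff_eta(wa1.dhz_c, onesg, onesg)
            A_p = ops.poisson(Cf_p, Cg_p)
            plu = splu(A_p.tocsc())
            if not self.wall.moving:
                self._plu = (plu, Cf_p, Cg_p)
        else:
            plu, Cf_p, Cg_p = self._plu

        pt_old = getattr(self, "_pt_prev", None)
        if pt_old is None:
            pt_old = np.zeros_like(self.u)
        else:
            pt_old = pt_old * (dt / self._dt_prev)
        dF_old, dG_old = self._pressure_face_corrections(pt_old, Cf_p, Cg_p, wa1)
        du_old, dv_old = self._pressure_cell_corrections(dF_old, dG_old, wa1)
        ua -= du_old
        va -= dv_old

        # ---- implicit directional viscosity at t1 ------------------------
        uw1 = np.asarray(self.wall.u_wall(ax.zc, t1), dtype=float)
        vw1 = np.asarray(self.wall.v_wall(ax.zc, t1), dtype=float)
        if self._vlu is not None and self._dt_pinned == dt:
            lu_u, lu_v, wCu, wCv = self._vlu
        else:
            Cf_u = ops.face_coeff_xi(wa1.hf, 2 * nf)
            Cg_u, wCu = ops.face_coeff_eta(wa1.dhz_c, ng, 2 * ng)
            A_u = ops.helmholtz(V1 / dt, Cf_u, Cg_u, wCu)
            Cf_v = ops.face_coeff_xi(wa1.hf, nf)
            Cg_v, wCv = ops.face_coeff_eta(wa1.dhz_c, 2 * ng, ng)
            r1 = ops.radii(wa1.hc)
            extra_v = 2.0 * nu * V1 / r1**2
            A_v = ops.helmholtz(V1 / dt, Cf_v, Cg_v, wCv, diag_extra=extra_v)
            lu_u, lu_v = splu(A_u.tocsc()), splu(A_v.tocsc())
            if (not self.wall.moving) and self.fluid.rheology == "newtonian":
                self._vlu = (lu_u, lu_v, wCu, wCv)
                self._dt_pinned = dt
        rhs_u = (V1 / dt) * ua
        rhs_u[:, -1] += wCu[0] * uw1
        u2 = lu_u.solve(rhs_u.ravel()).reshape(ua.shape)
        rhs_v = (V1 / dt) * va
        rhs_v[:, -1] += wCv[0] * vw1
        v2 = lu_v.solve(rhs_v.ravel()).reshape(va.shape)

        # ---- projection of the pressure increment -------------------------
        # the predictor carries grad(p_old) (through ua/va and the implicit
        # solve), so only the increment needs projecting here
        Fs = self._face_flux_xi(u2, wa1)
        Gs = self._face_flux_eta(u2, v2, wa1)
        # volume-consistent wall flux (exact discrete GCL)
        Gs[:, -1] = np.pi * ax.dz * (wa1.hc**2 - wa0.hc**2) / dt
        div = ops.flux_divergence(Fs, Gs)
        total = div.sum()
        div -= V1 * (total / V1.sum())

        scale = max(np.abs(Fs).max(), np.abs(Gs).max(), 1e-30)
        dpt = np.zeros_like(div)
        dFd = np.zeros_like(Fs)
        dGd = np.zeros_like(Gs)
        div_norm = np.inf
        for _ in range(cfg.pressure_max_iter):
            # deferred-correction iteration: orthogonal part implicit (in the
            # factorised operator), metric cross part from the last iterate
            dFd, dGd = self._pressure_face_corrections(dpt, Cf_p, Cg_p, wa1)
            cross_div = ops.flux_divergence(dFd, dGd) - self._ortho_divergence(
                dpt, Cf_p, Cg_p
            )
            rhs = -(div - cross_div).ravel()
            rhs[0] = 0.0
            dpt = plu.solve(rhs).reshape(div.shape)
            dFd, dGd = self._pressure_face_corrections(dpt, Cf_p, Cg_p, wa1)
            res = div - ops.flux_divergence(dFd, dGd)
            div_norm = np.abs(res).max() / scale
            if div_norm < cfg.pressure_tol:
                break
        Fn = Fs - dFd
        Gn = Gs - dGd
        # correct cell velocities by averaging the face-normal corrections
        # (discretely consistent with the face projection; a cell-gradient
        # correction is not and lets divergence modes grow at boundaries)
        du, dv = self._pressure_cell_corrections(dFd, dGd, wa1)
        u2 = u2 - du
        v2 = v2 - dv
        pt = pt_old + dpt
        # weak 4th-difference axial filter: cell velocities at odd-even z
        # wavelengths are invisible to the face-averaged fluxes, so the
        # projection cannot control them; this O(dz^3) background
        # dissipation removes them without degrading smooth modes
        if cfg.filter_alpha > 0:
            for f2 in (u2, v2):
                d4 = (
                    -np.roll(f2, 2, axis=0)
                    + 4 * np.roll(f2, 1, axis=0)
                    - 6 * f2
                    + 4 * np.roll(f2, -1, axis=0)
                    - np.roll(f2, -2, axis=0)
                )
                f2 += cfg.filter_alpha / 16.0 * d4

        # ---- bookkeeping --------------------------------------------------
        if not (np.isfinite(u2).all() and np.isfinite(v2).all()):
            raise RuntimeError(
                f"flow solver produced non-finite fields at t={t1:.4g} s "
                f"(dt={dt:.3g}); the time step or resolution is inadequate"
            )
        self._pt_prev = pt
        self._dt_prev = dt
        self.u, self.v = u2, v2
        self.p = pt * rho / dt * 0.1  # dyn/cm^2 -> Pa
        self.F, self.G = Fn, Gn
        self.Gmesh = (
            np.pi * ax.dz * rad.ef[None, :] ** 2 * ((wa1.hc**2 - wa0.hc**2) / dt)[:, None]
        )
        self.hc_old = wa0.hc.copy()
        self.wa = wa1
        self.t = t1
        self.n_steps += 1
        self._update_rheology(wa1)
        return FieldState(
            t=self.t,
            dt=dt,
            u=self.u,
            v=self.v,
            p=self.p,
            gamma_dot=self.gamma_dot,
            mu=self.mu,
            wa=wa1,
            hc_old=self.hc_old,
            F=self.F,
            G=self.G,
            Gmesh=self.Gmesh,
            div_norm=float(div_norm),
        )

    # -- pressure-correction helpers ----------------------------------------

    def _pressure_face_corrections(self, pt, Cf_p, Cg_p, wa):
        """Oriented face-flux corrections implied by the (scaled) pressure."""
        ops, rad, ax = self.ops, self.rad, self.ax
        onesf = np.ones((ax.nz, rad.nr))
        onesg = np.ones((ax.nz, rad.nr + 1))
        Xfp, Xgp = ops.cross_fluxes(
            wa.hf, wa.hc, wa.dhz_c, wa.dhz_f, onesf, onesg, pt
        )
        Xgp[:, -1] = 0.0  # zero-flux wall for pressure
        dF = Cf_p * (pt - np.roll(pt, 1, axis=0)) + Xfp
        dG = np.zeros((ax.nz, rad.nr + 1))
        dG[:, 1:-1] = Cg_p * (pt[:, 1:] - pt[:, :-1]) + Xgp[:, 1:-1]
        return dF, dG

    def _ortho_divergence(self, pt, Cf_p, Cg_p):
        """Divergence of the compact (orthogonal) pressure fluxes only."""
        dF = Cf_p * (pt - np.roll(pt, 1, axis=0))
        dG = np.zeros((self.ax.nz, self.rad.nr + 1))
        dG[:, 1:-1] = Cg_p * (pt[:, 1:] - pt[:, :-1])
        return self.ops.flux_divergence(dF, dG)

    def _pressure_cell_corrections(self, dF, dG, wa):
        """Cell-velocity corrections from averaged face-normal corrections."""
        ops, rad, ax = self.ops, self.rad, self.ax
        Af = 2.0 * np.pi * ops.ec2 * ops.deta2 * wa.hf[:, None] ** 2
        duf = dF / Af
        du = 0.5 * (duf + np.roll(duf, -1, axis=0))
        ef_in = rad.ef[1:-1]
        dvn = dG[:, 1:-1] / (
            2.0 * np.pi * ef_in[None, :] * wa.hc[:, None] * ax.dz
        )
        duf_g = 0.5 * (du[:, 1:] + du[:, :-1])  # du at interior eta-faces
        dvf = dvn + ef_in[None, :] * wa.dhz_c[:, None] * duf_g
        dv = np.zeros_like(du)
        dv[:, 1:] += 0.5 * dvf
        dv[:, :-1] += 0.5 * dvf  # boundary faces carry zero correction
        return du, dv

    def _update_rheology(self, wa: WallArrays) -> None:
        ops = self.ops
        du_dz, du_dr = ops.physical_gradients(self.u, wa.hc, wa.dhz_c)
        dv_dz, dv_dr = ops.physical_gradients(self.v, wa.hc, wa.dhz_c)
        r_c = ops.radii(wa.hc)
        s_tt = self.v / r_c
        s_rz = 0.5 * (du_dr + dv_dz)
        self.gamma_dot = np.sqrt(
            2.0 * (du_dz**2 + dv_dr**2 + s_tt**2) + 4.0 * s_rz**2
        )
        self.mu = np.asarray(self.fluid.viscosity(self.gamma_dot), dtype=float)

    # -- drivers ------------------------------------------------------------

    def run_to_steady(self, dt: float | None = None) -> FieldState:
        """March a static-wall problem to steady state."""
        if self.wall.moving:
            raise ValueError("run_to_steady requires a static wall")
        cfg = self.cfg
        if dt is None:
            # scale the first step from the boundary/body forcing, not the
            # (possibly quiescent) initial field
            ax = self.ax
            zc = ax.zc
            v_scale = max(
                np.abs(self.wall.u_wall(zc, 0.0)).max(),
                np.abs(self.wall.v_wall(zc, 0.0)).max(),
                np.abs(self.u).max(),
                1e-9,
            )
            if self.body_accel is not None:
                r_c = self.ops.radii(self.wa.hc)
                z2 = np.broadcast_to(zc[:, None], r_c.shape)
                az, ar = self.body_accel(z2, r_c, 0.0)
                amax = max(np.abs(az).max(), np.abs(ar).max())
                v_scale = max(v_scale, math.sqrt(amax * ax.dz))
            dr_min = (self.rad.deta * self.wa.hc.min()).min()
            dt = cfg.cfl * min(ax.dz, dr_min) / v_scale
            dt = min(dt, self.suggest_dt())
        self._dt_pinned = dt
        state = None
        for n in range(cfg.steady_max_steps):
            u_old = self.u.copy()
            v_old = self.v.copy()
            state = self.step(dt)
            # keep the step advectively stable as the flow develops
            if self.suggest_dt() < 0.75 * dt:
                dt = 0.5 * dt
                self._dt_pinned = dt
                self._vlu = None
                continue
            if not np.isfinite(self.u).all():
                raise RuntimeError(
                    "steady solve diverged (non-finite velocities); reduce dt"
                )
            umax = max(np.abs(self.u).max(), np.abs(self.v).max(), 1e-12)
            delta = max(
                np.abs(self.u - u_old).max(), np.abs(self.v - v_old).max()
            )
            # residual-rate criterion: velocity change per characteristic
            # transit time must be a negligible fraction of the velocity scale
            t_scale = self.period if self.period else self.ax.length / umax
            at_floor = delta < 1e-9 * umax  # round-off plateau
            if (delta / dt < cfg.steady_tol * umax / t_scale or at_floor) and n > 10:
                break
        else:
            raise RuntimeError(
                f"steady solve did not converge in {cfg.steady_max_steps} steps "
                f"(last relative change {delta / umax:.2e})"
            )
        return state


# ---------------------------------------------------------------------------
# High-level entry points


def _segmentation_axial_grid(geom: WallGeometry, cfg: SolverConfig) -> AxialGrid:
    return AxialGrid(nz=cfg.nz_per_wave * geom.n_pockets, length=geom.domain_length)


def solve_segmentation_flow(
    geom: WallGeometry,
    fluid: FluidModel,
    cfg: SolverConfig,
    n_periods: float,
) -> Iterator[FieldState]:
    """Yield time-resolved fields of a segmenting segment over ``n_periods``.

    The domain spans ``n_pockets`` wavelengths with axially periodic flow
    boundaries; the fluid starts at rest and the start-up transient of the
    first period is retained.
    """
    if geom.motility != "segmentation":
        raise ValueError("expected a segmentation geometry")
    ax = _segmentation_axial_grid(geom, cfg)
    solver = FlowSolver(
        SegmentationWall(geom), fluid, ax, cfg, period=geom.period
    )
    t_end = n_periods * geom.period
    while solver.t < t_end - 1e-12:
        dt = min(solver.suggest_dt(), t_end - solver.t)
        yield solver.step(dt)


def solve_peristalsis_flow(
    geom: WallGeometry, fluid: FluidModel, cfg: SolverConfig
) -> FieldState:
    """Steady wave-frame flow over one wavelength (free pumping).

    Periodic ends and a fully periodic pressure imply zero net pressure rise
    per wavelength.  The lab-frame field is the wave-frame field plus the
    wave speed ``c`` on the axial component.
    """
    if geom.motility != "peristalsis":
        raise ValueError("expected a peristalsis geometry")
    ax = AxialGrid(nz=cfg.nz_per_wave, length=geom.wavelength)
    solver = FlowSolver(
        WaveFrameWall(geom),
        fluid,
        ax,
        cfg,
        period=geom.period,
        u0=-geom.wave_speed,
    )
    return solver.run_to_steady()


def lab_frame_velocity(state: FieldState, geom: WallGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Lab-frame (u, v) of a wave-frame peristaltic solution."""
    return state.u + geom.wave_speed, state.v


def wall_shear_stress(
    state: FieldState, fluid: FluidModel, rad: RadialGrid, dz: float, wall_u=None, wall_v=None
):
    """Wall shear stress profile and summaries.

    Computes the tangential velocity gradient normal to the wall from a
    one-sided quadratic through the wall value and the two wall-nearest cell
    centres, evaluates the effective viscosity at that shear rate, and
    returns ``(tau_profile_mPa, tau_avg_mPa, tau_max_mPa)`` with the average
    weighted by wall area.
    """
    wa = state.wa
    nz, nr = state.u.shape
    slope = wa.dhz_c
    norm = np.sqrt(1.0 + slope**2)
    if wall_u is None:
        wall_u = np.zeros(nz)
    if wall_v is None:
        wall_v = wa.ht_c
    ut_wall = (wall_u + wall_v * slope) / norm
    ut1 = (state.u[:, -1] + state.v[:, -1] * slope) / norm
    ut2 = (state.u[:, -2] + state.v[:, -2] * slope) / norm
    d1 = (1.0 - rad.ec[-1]) * wa.hc
    d2 = (1.0 - rad.ec[-2]) * wa.hc
    dudn = ((ut_wall - ut1) * d2**2 - (ut_wall - ut2) * d1**2) / (
        d1 * d2 * (d2 - d1)
    )
    gamma_w = np.abs(dudn) / norm  # radial to wall-normal distance correction
    tau = np.asarray(fluid.viscosity(gamma_w), dtype=float) * gamma_w  # mPa
    wts = wa.hc * norm
    tau_avg = float((tau * wts).sum() / wts.sum())
    return tau, tau_avg, float(tau.max())
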