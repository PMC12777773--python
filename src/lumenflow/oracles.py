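"""Independent verification oracles and fixture generators.

Every solver claim in this package is checked against an implementation
that shares no discretisation code with the production solvers:

* :func:`poiseuille_fixture` — steady pressure-driven flow in a rigid tube
  against the analytic parabolic profile and tau_w = 4 mu U / R;
* :func:`lubrication_mean_flow` — classical long-wavelength (lubrication)
  theory for free peristaltic pumping in an axisymmetric tube, solved by
  quadrature; the 2-D wave-frame solver must agree in its long-wavelength,
  low-Reynolds limit;
* :func:`manufactured_solution_orders` — method of manufactured solutions:
  a solenoidal analytic field (built from a Stokes streamfunction, sympy-
  differentiated source terms) is forced into the solver and the observed
  spatial convergence order is measured under grid refinement;
* :func:`diffusion_fixture` — free Gaussian spreading against
  sigma^2(t) = sigma_0^2 + 2 D t;
* :func:`synthetic_sweep` — factorial sweep tables with planted factor
  effects and noise, for end-to-end tests of clustering and attribution;
* :func:`kmeans_1d_optimal` — exact dynamic-programming 1-D clustering, the
  optimality oracle for K-means on CS.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .fluids import FluidModel, SpeciesModel, get_fluid
from .flow import FlowSolver, SolverConfig, StaticTube, wall_shear_stress
from .grid import AxialGrid, RadialGrid
from .kinematics import WallGeometry

__all__ = [
    "poiseuille_fixture",
    "lubrication_mean_flow",
    "wave_frame_mean_flow",
    "manufactured_solution_orders",
    "diffusion_fixture",
    "synthetic_sweep",
    "kmeans_1d_optimal",
]


def poiseuille_fixture(
    nr: int = 16, nz: int = 8, radius: float = 0.5, u_target: float = 1.0
) -> dict:
    """Rigid-tube pressure-driven flow vs the analytic solution.

    Returns relative errors of the velocity profile and the wall shear.
    """
    fluid = get_fluid("water_37C")
    mu_p = fluid.mu * 0.01
    rho = fluid.density
    accel = 4.0 * mu_p * u_target / (rho * radius**2)
    cfg = SolverConfig(nr=nr, nz_per_wave=nz, steady_tol=1e-9)
    ax = AxialGrid(nz=nz, length=4.0 * radius)
    solver = FlowSolver(
        StaticTube(radius),
        fluid,
        ax,
        cfg,
        body_accel=lambda z, r, t: (np.full_like(r, accel), np.zeros_like(r)),
    )
    state = solver.run_to_steady()
    r = solver.ops.radii(state.wa.hc)
    u_exact = rho * accel / (4.0 * mu_p) * (radius**2 - r**2)
    vel_err = float(np.abs(state.u - u_exact).max() / u_exact.max())
    _, tau_avg, _ = wall_shear_stress(state, fluid, solver.rad, ax.dz)
    band = solver.rad.ef[1:] ** 2 - solver.rad.ef[:-1] ** 2
    u_mean = float((state.u[0] * band).sum())  # area-weighted mean
    tau_exact = 4.0 * fluid.mu * u_mean / radius  # mPa
    return {
        "velocity_rel_err": vel_err,
        "tau_rel_err": abs(tau_avg - tau_exact) / tau_exact,
        "v_spurious": float(np.abs(state.v).max()),
        "divergence": state.div_norm,
    }


# ---------------------------------------------------------------------------
# Lubrication theory for peristaltic free pumping (axisymmetric)


def lubrication_mean_flow(geom: WallGeometry) -> float:
    """Time-mean lab-frame flow rate (cm^3/s) from lubrication theory.

    Wave frame, Stokes lubrication: ubar(r) = (p'/(4 mu)) (r^2 - h^2) - c,
    flux F = -p' pi h^4/(8 mu) - c pi h^2.  Zero net pressure rise per
    wavelength (free pumping) fixes F = -c pi I2/I4 with
    I_n = integral h^-n dz; the time-mean lab flow is F + c pi <h^2>.
    Newtonian and viscosity-independent in this limit.
    """
    lam = geom.wavelength
    c = geom.wave_speed

    def h(z):
        return geom.radius(z, 0.0)

    i2, _ = quad(lambda z: h(z) ** -2, 0.0, lam, limit=200)
    i4, _ = quad(lambda z: h(z) ** -4, 0.0, lam, limit=200)
    h2, _ = quad(lambda z: h(z) ** 2, 0.0, lam, limit=200)
    F = -c * math.pi * i2 / i4
    return F + c * math.pi * (h2 / lam)


def wave_frame_mean_flow(state, geom: WallGeometry) -> float:
    """Time-mean lab-frame flow rate implied by a wave-frame solution."""
    F_wave = float(state.F.sum(axis=1).mean())
    lam = geom.wavelength
    h2, _ = quad(lambda z: geom.radius(z, 0.0) ** 2, 0.0, lam, limit=200)
    return F_wave + geom.wave_speed * math.pi * (h2 / lam)


# ---------------------------------------------------------------------------
# Method of manufactured solutions


def _manufactured_problem(radius: float, length: float, mu_mpas: float, rho: float):
    """Sympy-derived exact fields and momentum sources (lazy import)."""
    import sympy as sp

    z, r = sp.symbols("z r", real=True)
    R, L = sp.Float(radius), sp.Float(length)
    A = sp.Float(0.8) / R**4  # sets u ~ O(0.1-1)
    k = 2 * sp.pi / L
    psi = A * r**2 * (R**2 - r**2) ** 2 * sp.sin(k * z)
    u = sp.simplify(sp.diff(psi, r) / r)
    v = sp.simplify(-sp.diff(psi, z) / r)
    p = sp.Float(0.3) * sp.cos(k * z) * sp.cos(sp.pi * r / (2 * R))
    mu = sp.Float(mu_mpas * 0.01)
    rho_ = sp.Float(rho)
    lap = lambda f: sp.diff(f, z, 2) + sp.diff(r * sp.diff(f, r), r) / r
    fz = rho_ * (u * sp.diff(u, z) + v * sp.diff(u, r)) + sp.diff(p, z) - mu * lap(u)
    fr = (
        rho_ * (u * sp.diff(v, z) + v * sp.diff(v, r))
        + sp.diff(p, r)
        - mu * (lap(v) - v / r**2)
    )
    fz_c, fr_c = sp.simplify(fz / rho_), sp.simplify(fr / rho_)
    fns = [sp.lambdify((z, r), e, "numpy") for e in (u, v, fz_c, fr_c)]
    return fns


def manufactured_solution_orders(
    levels: tuple[tuple[int, int], ...] = ((12, 6), (24, 12), (48, 24)),
    radius: float = 0.5,
    length: float = 2.0,
    mu_mpas: float = 8.0,
    dt_coarsest: float = 0.016,
) -> dict:
    """March the forced problem to steady state on refined grids.

    The steady state of the time-split scheme carries a small O(dt)
    residual from the explicit advection stages, so the step is refined
    *quadratically* with the mesh (dt proportional to h^2): the time bias
    then converges at the same second order as the spatial truncation and
    the observed order measures the scheme as a whole.

    Returns the max-norm velocity errors per level and the observed
    convergence orders between consecutive refinements.
    """
    rho = 1.0
    fluid = FluidModel(name="mms", density=rho, rheology="newtonian", mu=mu_mpas)
    u_fn, v_fn, fz_fn, fr_fn = _manufactured_problem(radius, length, mu_mpas, rho)
    errors = []
    hs = []
    nz0 = levels[0][0]
    for nz, nr in levels:
        cfg = SolverConfig(
            nr=nr, nz_per_wave=nz, beta_stretch=0.0, steady_tol=1e-8
        )
        ax = AxialGrid(nz=nz, length=length)
        solver = FlowSolver(
            StaticTube(radius),
            fluid,
            ax,
            cfg,
            body_accel=lambda zz, rr, t: (fz_fn(zz, rr), fr_fn(zz, rr)),
        )
        state = solver.run_to_steady(dt=dt_coarsest * (nz0 / nz) ** 2)
        r = solver.ops.radii(state.wa.hc)
        zz = np.broadcast_to(ax.zc[:, None], r.shape)
        ue, ve = u_fn(zz, r), v_fn(zz, r)
        scale = max(np.abs(ue).max(), np.abs(ve).max())
        err = max(np.abs(state.u - ue).max(), np.abs(state.v - ve).max()) / scale
        errors.append(float(err))
        hs.append(length / nz)
    orders = [
        math.log(errors[i] / errors[i + 1]) / math.log(hs[i] / hs[i + 1])
        for i in range(len(errors) - 1)
    ]
    out = {"errors": errors, "orders": orders}
    if len(errors) >= 3:
        # Richardson-triplet observed order (the standard grid-convergence
        # estimator): uses error *differences*, cancelling any common
        # converged-solution offset shared by all levels
        r = hs[0] / hs[1]
        out["observed_order"] = math.log(
            (errors[0] - errors[1]) / (errors[1] - errors[2])
        ) / math.log(r)
    return out


# ---------------------------------------------------------------------------
# Diffusion fixture


def diffusion_fixture(
    D: float = 1e-4, sigma0: float = 0.05, t_end: float = 30.0
) -> dict:
    """Free Gaussian spreading vs sigma_z^2(t) = sigma_0^2 + 2 D t."""
    from .transport import FluxBundle, TransportSolver, initialize_bolus, _volumes

    fluid = get_fluid("water_37C")
    sp_ = SpeciesModel(
        name="tracer",
        initial_concentration=1.0,
        base_diffusivity=lambda c: np.full_like(np.asarray(c, float), D),
    )
    ax = AxialGrid(nz=96, length=1.2)
    rad = RadialGrid(24, 1.2)
    hc = np.full(ax.nz, 0.45)
    V = _volumes(ax, rad, hc)
    bundle = FluxBundle(
        F=np.zeros((ax.nz + 1, rad.nr)),
        Gr=np.zeros((ax.nz, rad.nr + 1)),
        V0=V,
        V1=V,
        hc=hc,
        dhz_c=np.zeros(ax.nz),
        dt=0.05,
    )
    ts = TransportSolver(ax, rad, [sp_], fluid, end_bc="closed")
    hist = initialize_bolus(ax, rad, hc, [sp_], z0=0.6, sigma=sigma0)
    m0 = hist.total_moles(V)["tracer"]
    n = int(round(t_end / bundle.dt))
    for _ in range(n):
        ts.step(hist, bundle)
    c = hist.c["tracer"]
    m = (c * V).sum()
    zb = (c * V * ax.zc[:, None]).sum() / m
    s2 = float((c * V * (ax.zc[:, None] - zb) ** 2).sum() / m)
    expect = sigma0**2 + 2.0 * D * t_end
    return {
        "sigma2": s2,
        "expected": expect,
        "rel_err": abs(s2 - expect) / expect,
        "mass_drift": abs(float(m) - m0) / m0,
        "min_c": float(c.min()),
    }


# ---------------------------------------------------------------------------
# Synthetic sweep tables with planted effects


def synthetic_sweep(
    seed: int = 0,
    *,
    dominant: str = "pocket_volume",
    effect: float = 0.35,
    minor_effect: float = 0.08,
    noise: float = 0.03,
    include_peristalsis: bool = True,
) -> pd.DataFrame:
    """Factorial sweep table with a planted dominant factor effect on CS.

    The dominant factor moves CS by ``effect`` between its extreme levels;
    every other factor contributes at most ``minor_effect``; i.i.d. Gaussian
    noise of scale ``noise`` is added and the result clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    motilities = ["segmentation", "peristalsis"] if include_peristalsis else ["segmentation"]
    rows = list(
        itertools.product(
            motilities,
            ["light", "moderate", "vigorous"],
            ["water_37C", "nutridrink_default"],
            [2.0, 10.0],
            [0.3, 0.5, 0.7],
            ["most_occluded", "least_occluded"],
        )
    )
    df = pd.DataFrame(
        rows,
        columns=["motility", "intensity", "fluid", "pocket_volume", "occlusion_ratio", "release"],
    )
    centred = {
        "motility": (df["motility"] == "segmentation").astype(float) - 0.5,
        "intensity": df["intensity"].map({"light": 0.5, "moderate": 0.0, "vigorous": -0.5}),
        "fluid": (df["fluid"] == "nutridrink_default").astype(float) - 0.5,
        "pocket_volume": 0.5 - (df["pocket_volume"] - 2.0) / 8.0,
        "occlusion_ratio": (0.5 - df["occlusion_ratio"]) / 0.4,
        "release": (df["release"] == "most_occluded").astype(float) - 0.5,
    }
    cs = 0.45 + effect * centred[dominant]
    for f, vals in centred.items():
        if f != dominant:
            cs = cs + minor_effect * rng.uniform(0.3, 1.0) * vals
    cs = cs + noise * rng.standard_normal(len(df))
    df["cs"] = np.clip(cs, 0.0, 1.0)
    return df


def kmeans_1d_optimal(values: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Exact optimal 1-D k-clustering by dynamic programming.

    Returns (labels aligned with the sorted order mapped back to the input
    order, total within-cluster sum of squares).  O(k n^2); intended for
    small oracle problems.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    order = np.argsort(x)
    xs = x[order]
    pref = np.concatenate([[0.0], np.cumsum(xs)])
    pref2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def sse(i, j):  # cost of cluster xs[i:j]
        m = j - i
        s = pref[j] - pref[i]
        return (pref2[j] - pref2[i]) - s * s / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                cand = dp[kk - 1, i] + sse(i, j)
                if cand < dp[kk, j] - 1e-15:
                    dp[kk, j] = cand
                    back[kk, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for kk in range(k, 0, -1):
        i = back[kk, j]
        labels_sorted[i:j] = kk - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, float(dp[k, n])
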