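"""Boundary-fitted axisymmetric grid and finite-volume operators.

The deforming lumen ``0 <= r <= h(z, t)`` is mapped onto a fixed rectangle
with coordinates ``xi = z`` (axial, periodic for the flow solver) and
``eta = r/h(z, t)`` in [0, 1].  Scalars and velocity components live at cell
centres; fluxes at the four cell faces.  With ``h'`` denoting dh/dz, the
exact flux of a diffusive field ``a * grad(phi)`` through the mapped faces is

* xi-face (plane z = const):
    2*pi*a*eta*deta * [ h_f^2 * phi_xi - eta*h'*h_f * phi_eta ]
* eta-face (surface r = eta_f * h(z)):
    2*pi*a*eta_f   * [ (1 + eta_f^2 h'^2) * phi_eta - eta_f*h'*h * phi_xi ] * dz

The first (compact, "orthogonal") parts are assembled into sparse matrices
for implicit solves; the second (cross-derivative) parts are evaluated
explicitly and either added as deferred corrections (viscous terms) or
iterated to convergence (pressure projection).

Anisotropic diagonal diffusion (different axial/radial coefficients, needed
for the exact viscous-stress splitting in :mod:`lumenflow.flow`) is supported
by passing separate axial and radial coefficient fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["RadialGrid", "AxialGrid", "FVOperators", "WallArrays"]


def _tanh_faces(nr: int, beta: float) -> np.ndarray:
    """eta faces in [0, 1] clustered toward eta = 1 (the wall)."""
    x = np.linspace(0.0, 1.0, nr + 1)
    if beta <= 0:
        return x
    # d(eta)/dx = beta*sech^2(beta*x)/tanh(beta): widest at the axis,
    # finest at the wall (boundary-layer resolution)
    return np.tanh(beta * x) / np.tanh(beta)


@dataclass(frozen=True)
class RadialGrid:
    """Stretched radial (eta) discretisation shared by all solvers."""

    nr: int
    beta: float = 1.8  # tanh clustering strength toward the wall

    def __post_init__(self):
        ef = _tanh_faces(self.nr, self.beta)
        ec = 0.5 * (ef[1:] + ef[:-1])
        object.__setattr__(self, "ef", ef)
        object.__setattr__(self, "ec", ec)
        object.__setattr__(self, "deta", ef[1:] - ef[:-1])
        object.__setattr__(self, "dec", ec[1:] - ec[:-1])  # centre spacing
        object.__setattr__(self, "d_wall", 1.0 - ec[-1])
        object.__setattr__(self, "d_axis", ec[0])


@dataclass(frozen=True)
class AxialGrid:
    nz: int
    length: float  # cm

    def __post_init__(self):
        dz = self.length / self.nz
        object.__setattr__(self, "dz", dz)
        object.__setattr__(self, "zf", np.arange(self.nz + 1) * dz)
        object.__setattr__(self, "zc", (np.arange(self.nz) + 0.5) * dz)


@dataclass
class WallArrays:
    """Wall geometry sampled on an axial grid at one instant."""

    hc: np.ndarray  # h at cell centres
    hf: np.ndarray  # h at faces (face i is the left face of cell i)
    dhz_c: np.ndarray
    dhz_f: np.ndarray
    ht_c: np.ndarray  # dh/dt at centres

    @classmethod
    def sample(cls, wall, ax: AxialGrid, t: float) -> "WallArrays":
        return cls(
            hc=np.asarray(wall.radius(ax.zc, t), dtype=float),
            hf=np.asarray(wall.radius(ax.zf[:-1], t), dtype=float),
            dhz_c=np.asarray(wall.dradius_dz(ax.zc, t), dtype=float),
            dhz_f=np.asarray(wall.dradius_dz(ax.zf[:-1], t), dtype=float),
            ht_c=np.asarray(wall.velocity_c(ax.zc, t), dtype=float),
        )


class FVOperators:
    """Finite-volume operator factory on a periodic mapped grid.

    All matrices act on fields flattened as ``phi[i, j] -> n = i*nr + j``
    (i axial, j radial).  The factory caches the sparsity pattern; only the
    coefficient data changes between time steps.
    """

    def __init__(self, ax: AxialGrid, rad: RadialGrid):
        self.ax = ax
        self.rad = rad
        nz, nr = ax.nz, rad.nr
        self.nz, self.nr = nz, nr
        n = nz * nr
        idx = np.arange(n).reshape(nz, nr)
        self._i_diag = idx
        self._i_west = np.roll(idx, 1, axis=0)  # neighbour i-1
        self._i_east = np.roll(idx, -1, axis=0)
        self._i_south = idx[:, :-1]  # neighbour j-1 of cells j=1..nr-1
        self._i_north = idx[:, 1:]
        # 2D meshes of radial metric (broadcast helpers)
        self.ec2 = np.broadcast_to(rad.ec, (nz, nr))
        self.deta2 = np.broadcast_to(rad.deta, (nz, nr))

    # -- geometry helpers --------------------------------------------------

    def volumes(self, hc: np.ndarray) -> np.ndarray:
        """Exact cell volumes: pi * dz * h^2 * (ef_n^2 - ef_s^2)."""
        ef = self.rad.ef
        band = ef[1:] ** 2 - ef[:-1] ** 2
        return np.pi * self.ax.dz * hc[:, None] ** 2 * band[None, :]

    def radii(self, hc: np.ndarray) -> np.ndarray:
        return self.rad.ec[None, :] * hc[:, None]

    # -- orthogonal face coefficients -------------------------------------

    def face_coeff_xi(self, hf: np.ndarray, a_zf: np.ndarray) -> np.ndarray:
        """C_f[i, j]: compact coupling through xi-face i (between cells i-1, i)."""
        return (
            2.0
            * np.pi
            * self.ec2
            * self.deta2
            * hf[:, None] ** 2
            * a_zf
            / self.ax.dz
        )

    def face_coeff_eta(
        self, dhz_c: np.ndarray, a_rg: np.ndarray, a_zg: np.ndarray
    ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Compact coupling through interior eta-faces and the wall face.

        Returns ``(C_g, (W_w, W_1, W_2))``: ``C_g[i, j]`` couples faces
        j = 1..nr-1 (between cells j-1 and j) with coefficient
        ``a_r + a_z * eta_f^2 h'^2`` over the centre spacing; the wall-face
        flux uses a one-sided *quadratic* derivative through the wall value
        and the two wall-nearest centres (second-order Dirichlet flux):
        ``flux_out = W_w*phi_wall - W_1*phi_{nr-1} + W_2*phi_{nr-2}``.
        ``a_rg``/``a_zg`` must be sampled at eta-faces, shape (nz, nr+1).
        """
        rad = self.rad
        ef_in = rad.ef[1:-1]
        coef = a_rg[:, 1:-1] + a_zg[:, 1:-1] * (ef_in**2 * dhz_c[:, None] ** 2)
        C_g = 2.0 * np.pi * ef_in[None, :] * coef * self.ax.dz / rad.dec[None, :]
        coef_w = a_rg[:, -1] + a_zg[:, -1] * dhz_c**2
        K = 2.0 * np.pi * coef_w * self.ax.dz
        d1 = rad.d_wall
        d2 = 1.0 - rad.ec[-2]
        den = d1 * d2 * (d2 - d1)
        W_w = K * (d2**2 - d1**2) / den
        W_1 = K * d2**2 / den
        W_2 = K * d1**2 / den
        return C_g, (W_w, W_1, W_2)

    # -- matrix assembly ----------------------------------------------------

    def helmholtz(
        self,
        vol_over_dt: np.ndarray,
        C_f: np.ndarray,
        C_g: np.ndarray,
        wall: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
        diag_extra: np.ndarray | None = None,
    ):
        """Assemble ``A = diag(V/dt + extra) - L`` (csr).

        ``L phi = sum_faces C * (phi_nb - phi_self)``; a Dirichlet wall is
        handled through the quadratic wall-flux triple ``wall = (W_w, W_1,
        W_2)`` from :meth:`face_coeff_eta` (callers add ``W_w * phi_wall``
        to the RHS of wall-adjacent cells).  Pass ``wall=None`` for a
        zero-flux wall.
        """
        nz, nr = self.nz, self.nr
        diag = vol_over_dt.copy()
        if diag_extra is not None:
            diag += diag_extra
        # xi faces: face i couples cells i-1 (west) and i (self)
        diag += C_f  # left face of each cell
        diag += np.roll(C_f, -1, axis=0)  # right face
        # eta faces
        diag[:, 1:] += C_g
        diag[:, :-1] += C_g
        if wall is not None:
            W_w, W_1, W_2 = wall
            diag[:, -1] += W_1

        rows = [self._i_diag.ravel()]
        cols = [self._i_diag.ravel()]
        data = [diag.ravel()]
        # west/east couplings
        rows.append(self._i_diag.ravel())
        cols.append(self._i_west.ravel())
        data.append(-C_f.ravel())
        rows.append(self._i_west.ravel())
        cols.append(self._i_diag.ravel())
        data.append(-C_f.ravel())
        # south/north couplings
        rows.append(self._i_north.ravel())
        cols.append(self._i_south.ravel())
        data.append(-C_g.ravel())
        rows.append(self._i_south.ravel())
        cols.append(self._i_north.ravel())
        data.append(-C_g.ravel())
        if wall is not None:
            # quadratic wall flux couples the wall-adjacent cell to the next
            rows.append(self._i_diag[:, -1])
            cols.append(self._i_diag[:, -2])
            data.append(-W_2)
        A = sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nz * nr, nz * nr),
        )
        return A

    def poisson(self, C_f: np.ndarray, C_g: np.ndarray):
        """Assemble ``-L`` with zero-flux walls, pinning cell 0 to fix the
        pressure nullspace.  Returns a csr matrix."""
        nz, nr = self.nz, self.nr
        zero = np.zeros((nz, nr))
        A = self.helmholtz(zero, C_f, C_g, None)
        A = A.tolil()
        A.rows[0] = [0]
        A.data[0] = [1.0]
        return A.tocsr()

    # -- cross-derivative (explicit) fluxes --------------------------------

    def dphi_dxi(self, phi: np.ndarray) -> np.ndarray:
        return (np.roll(phi, -1, axis=0) - np.roll(phi, 1, axis=0)) / (2 * self.ax.dz)

    def dphi_deta(self, phi: np.ndarray) -> np.ndarray:
        """Nonuniform central d(phi)/d(eta) at centres (one-sided at ends)."""
        return np.gradient(phi, self.rad.ec, axis=1, edge_order=2)

    def cross_fluxes(
        self,
        hf: np.ndarray,
        hc: np.ndarray,
        dhz_c: np.ndarray,
        dhz_f: np.ndarray,
        az_f: np.ndarray,
        az_g: np.ndarray,
        phi: np.ndarray,
        wall_value: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Cross-term parts of the oriented diffusive fluxes.

        Returns ``(Xf, Xg)``: Xf at xi-faces (nz, nr), Xg at eta-faces
        (nz, nr+1).  ``az_*`` are the *axial* coefficient fields sampled at
        the respective faces (the cross terms carry the axial coefficient).
        ``wall_value`` (values of phi on the wall vs z) sharpens the wall-face
        xi-derivative for Dirichlet fields; otherwise the top-cell derivative
        is used.
        """
        rad, ax = self.rad, self.ax
        de = self.dphi_deta(phi)
        de_f = 0.5 * (de + np.roll(de, 1, axis=0))  # at xi-faces
        Xf = (
            -2.0
            * np.pi
            * self.ec2**2
            * self.deta2
            * hf[:, None]
            * dhz_f[:, None]
            * az_f
            * de_f
        )
        dx = self.dphi_dxi(phi)
        Xg = np.zeros((self.nz, self.nr + 1))
        ef_in = rad.ef[1:-1]
        dx_g = 0.5 * (dx[:, 1:] + dx[:, :-1])
        Xg[:, 1:-1] = (
            -2.0
            * np.pi
            * ef_in[None, :] ** 2
            * dhz_c[:, None]
            * hc[:, None]
            * az_g[:, 1:-1]
            * dx_g
            * ax.dz
        )
        if wall_value is not None:
            dxw = (np.roll(wall_value, -1) - np.roll(wall_value, 1)) / (2 * ax.dz)
        else:
            dxw = dx[:, -1]
        Xg[:, -1] = -2.0 * np.pi * dhz_c * hc * az_g[:, -1] * dxw * ax.dz
        # axis face has zero area
        return Xf, Xg

    @staticmethod
    def flux_divergence(Xf: np.ndarray, Xg: np.ndarray) -> np.ndarray:
        """Net outflow per cell of oriented face fluxes."""
        return (np.roll(Xf, -1, axis=0) - Xf) + (Xg[:, 1:] - Xg[:, :-1])

    # -- mapped derivatives of cell fields ---------------------------------

    def physical_gradients(
        self, phi: np.ndarray, hc: np.ndarray, dhz_c: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(d(phi)/dz, d(phi)/dr) at cell centres via the mapping."""
        dxi = self.dphi_dxi(phi)
        deta = self.dphi_deta(phi)
        dpdz = dxi - (self.ec2 * dhz_c[:, None] / hc[:, None]) * deta
        dpdr = deta / hc[:, None]
        return dpdz, dpdr
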