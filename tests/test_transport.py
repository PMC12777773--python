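"""Scalar-transport contracts: conservation, positivity, diffusion law,
species symmetry, bolus initialisation."""

import numpy as np
import pytest

from lumenflow.fluids import FluidModel, SpeciesModel, get_fluid, get_species
from lumenflow.grid import AxialGrid, RadialGrid
from lumenflow.oracles import diffusion_fixture
from lumenflow.transport import (
    FluxBundle,
    ReleaseSpec,
    TransportSolver,
    _volumes,
    initialize_bolus,
)


def _static_bundle(ax, rad, R=0.45, dt=0.05):
    hc = np.full(ax.nz, R)
    V = _volumes(ax, rad, hc)
    return FluxBundle(
        F=np.zeros((ax.nz + 1, rad.nr)),
        Gr=np.zeros((ax.nz, rad.nr + 1)),
        V0=V,
        V1=V,
        hc=hc,
        dhz_c=np.zeros(ax.nz),
        dt=dt,
    )


@pytest.fixture(scope="module")
def tube():
    ax = AxialGrid(nz=64, length=2.0)
    rad = RadialGrid(16, 1.8)
    return ax, rad


class TestBolus:
    def test_peak_concentrations_match_initial_doses(self):
        # on a grid that resolves the bolus, the discrete peak approaches ci
        ax = AxialGrid(nz=320, length=1.2)
        rad = RadialGrid(96, 0.0)
        species = [get_species("insulin"), get_species("C10")]
        hc = np.full(ax.nz, 0.45)
        hist = initialize_bolus(ax, rad, hc, species, z0=0.6, sigma=0.05)
        assert hist.c["insulin"].max() == pytest.approx(2.0, rel=1e-2)
        assert hist.c["C10"].max() == pytest.approx(100.0, rel=1e-2)

    def test_released_moles_match_gaussian_integral(self):
        # resolve the bolus well and compare with ci * (2 pi)^(3/2) sigma^3
        ax = AxialGrid(nz=320, length=1.2)
        rad = RadialGrid(96, 0.0)
        sp = get_species("insulin")
        sigma = 0.05
        hist = initialize_bolus(ax, rad, np.full(ax.nz, 0.45), [sp], 0.6, sigma)
        expect = 2.0 * (2 * np.pi) ** 1.5 * sigma**3
        assert hist.released_moles["insulin"] == pytest.approx(expect, rel=1e-3)

    def test_wall_overlapping_bolus_rejected(self, tube):
        ax, rad = tube
        with pytest.raises(ValueError, match="overlaps the wall"):
            initialize_bolus(
                ax, rad, np.full(ax.nz, 0.45), [get_species("insulin")], 1.0, 0.2
            )

    def test_release_positions(self):
        from lumenflow.kinematics import derive_geometry

        geom = derive_geometry(2.0, 2.4, 0.3, "segmentation", period=5.0)
        centre = ReleaseSpec(position="most_occluded").axial_position(geom)
        off = ReleaseSpec(position="least_occluded").axial_position(geom)
        assert centre == pytest.approx(1.5 * 2.4)
        assert centre - off == pytest.approx(2.4 / 4.0)


class TestConservationAndPositivity:
    def test_closed_box_mass_constant_and_positive(self, tube, rng):
        ax, rad = tube
        sp = SpeciesModel(
            name="s",
            initial_concentration=1.0,
            base_diffusivity=lambda c: np.full_like(np.asarray(c, float), 2e-5),
        )
        b = _static_bundle(ax, rad)
        # random solenoidal fluxes from a smooth random streamfunction with
        # zero borders: discretely divergence-free, no boundary flux; the
        # amplitude keeps face velocities CFL-safe for dt = 0.01
        x = np.linspace(0, np.pi, ax.nz + 1)[:, None]
        y = np.linspace(0, np.pi, rad.nr + 1)[None, :]
        psi = 0.0
        for k in range(1, 4):
            for m in range(1, 4):
                psi = psi + rng.normal() * np.sin(k * x) * np.sin(m * y)
        psi = 1e-4 * psi
        F = np.diff(psi, axis=1)  # (nz+1, nr)
        Gr = -np.diff(psi, axis=0)  # (nz, nr+1)
        b = FluxBundle(F=F, Gr=Gr, V0=b.V0, V1=b.V1, hc=b.hc, dhz_c=b.dhz_c, dt=0.01)
        ts = TransportSolver(ax, rad, [sp], get_fluid("water_37C"), end_bc="closed")
        hist = initialize_bolus(ax, rad, b.hc, [sp], 1.0, 0.06)
        m0 = hist.total_moles(b.V0)["s"]
        for _ in range(400):
            ts.step(hist, b)
        m1 = hist.total_moles(b.V1)["s"]
        assert abs(m1 - m0) / m0 < 1e-3
        assert hist.c["s"].min() >= -1e-12 * 1.0

    def test_uniform_field_stays_uniform(self, tube):
        ax, rad = tube
        sp = get_species("insulin")
        b = _static_bundle(ax, rad)
        ts = TransportSolver(ax, rad, [sp], get_fluid("water_37C"), end_bc="closed")
        hist = initialize_bolus(ax, rad, b.hc, [sp], 1.0, 0.06)
        hist.c["insulin"][:] = 1.0
        for _ in range(60):
            ts.step(hist, b)
        assert np.abs(hist.c["insulin"] - 1.0).max() < 1e-10

    def test_species_symmetry_under_identical_properties(self, tube, rng):
        ax, rad = tube
        mk = lambda n: SpeciesModel(
            name=n,
            initial_concentration=2.0,
            base_diffusivity=lambda c: np.full_like(np.asarray(c, float), 1.11e-6),
        )
        a, bsp = mk("a"), mk("b")
        b = _static_bundle(ax, rad)
        ts = TransportSolver(ax, rad, [a, bsp], get_fluid("water_37C"), end_bc="closed")
        hist = initialize_bolus(ax, rad, b.hc, [a, bsp], 1.0, 0.06)
        for _ in range(50):
            ts.step(hist, b)
        assert np.abs(hist.c["a"] - hist.c["b"]).max() < 1e-10


class TestDiffusionLaw:
    def test_gaussian_variance_growth(self):
        out = diffusion_fixture()
        assert out["rel_err"] < 0.01
        assert out["mass_drift"] < 1e-3
        assert out["min_c"] >= -1e-12

    def test_open_ends_only_lose_mass(self, tube):
        ax, rad = tube
        sp = SpeciesModel(
            name="s",
            initial_concentration=1.0,
            base_diffusivity=lambda c: np.full_like(np.asarray(c, float), 1e-6),
        )
        b = _static_bundle(ax, rad)
        # uniform rightward plug flow at 0.1 cm/s (flux = u * face area)
        Af = 2 * np.pi * rad.ec * rad.deta * 0.45**2
        F = np.tile(0.1 * Af, (ax.nz + 1, 1))
        b = FluxBundle(F=F, Gr=b.Gr, V0=b.V0, V1=b.V1, hc=b.hc, dhz_c=b.dhz_c, dt=0.05)
        ts = TransportSolver(ax, rad, [sp], get_fluid("water_37C"), end_bc="open")
        hist = initialize_bolus(ax, rad, b.hc, [sp], 1.7, 0.06)
        masses = []
        for _ in range(600):
            ts.step(hist, b)
            masses.append(hist.total_moles(b.V1)["s"])
        masses = np.array(masses)
        assert np.all(np.diff(masses) <= 1e-12)
        assert masses[-1] < 0.5 * masses[0]  # advected out through the end
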