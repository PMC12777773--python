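"""Delivery-metric and colocalisation-score contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumenflow.grid import AxialGrid, RadialGrid
from lumenflow.metrics import (
    PeakInfo,
    build_colocalisation_records,
    colocalisation_score,
    escape_fraction,
    near_wall_fraction,
)
from lumenflow.transport import _volumes


@pytest.fixture(scope="module")
def straight_grid():
    ax = AxialGrid(nz=48, length=4.0)
    rad = RadialGrid(24, 1.8)
    hc = np.full(ax.nz, 0.5)
    V = _volumes(ax, rad, hc)
    return ax, rad, hc, V


class TestNearWallFraction:
    def test_uniform_field_matches_annulus_ratio(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.ones((ax.nz, rad.nr))
        total = float(V.sum())
        for a in (0.05, 0.0667, 0.15):
            expect = 100.0 * (1.0 - (1.0 - a / 0.5) ** 2)
            got = near_wall_fraction(c, V, hc, rad, a, total)
            assert got == pytest.approx(expect, rel=1e-12)

    def test_axis_mass_contributes_nothing(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.zeros((ax.nz, rad.nr))
        c[:, 0] = 5.0
        total = float((c * V).sum())
        assert near_wall_fraction(c, V, hc, rad, 0.05, total) == 0.0

    def test_thin_layer_never_exceeds_thick_layer(self, straight_grid, rng):
        ax, rad, hc, V = straight_grid
        c = rng.random((ax.nz, rad.nr))
        total = float((c * V).sum())
        thin = near_wall_fraction(c, V, hc, rad, 0.5 / 15, total)
        thick = near_wall_fraction(c, V, hc, rad, 1.0 / 15, total)
        assert 0.0 <= thin <= thick <= 100.0

    def test_excessive_thickness_rejected(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.ones((ax.nz, rad.nr))
        with pytest.raises(ValueError, match="thickness"):
            near_wall_fraction(c, V, hc, rad, 0.6, float(V.sum()))


class TestEscapeFraction:
    def test_mass_inside_window_is_zero_escape(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.zeros((ax.nz, rad.nr))
        c[20:28] = 1.0  # cells well inside [1, 3]
        total = float((c * V).sum())
        assert escape_fraction(c, V, ax, 1.0, 3.0, total) == pytest.approx(0.0)

    def test_all_mass_outside_is_full_escape(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.zeros((ax.nz, rad.nr))
        c[:6] = 1.0
        total = float((c * V).sum())
        assert escape_fraction(c, V, ax, 1.0, 3.0, total) == pytest.approx(100.0)

    def test_partial_cell_overlap_is_fractional(self, straight_grid):
        ax, rad, hc, V = straight_grid
        c = np.zeros((ax.nz, rad.nr))
        i = 12  # cell [1.0, 1.0833]; window edge at its middle
        c[i] = 1.0
        total = float((c * V).sum())
        edge = ax.zf[i] + 0.5 * ax.dz
        got = escape_fraction(c, V, ax, edge, 3.0, total)
        assert got == pytest.approx(50.0, rel=1e-9)


class TestColocalisationScore:
    def test_perfect_colocalisation_is_one(self):
        assert colocalisation_score(1.0, 1.0, 0.0, 0.0, 0.0) == 1.0

    def test_temporal_separation_arithmetic(self):
        assert colocalisation_score(0.5, 0.8, 1.0, 0.0, 0.0) == pytest.approx(0.2)

    def test_unnormalised_inputs_rejected(self):
        with pytest.raises(ValueError, match="normalise"):
            colocalisation_score(1.4, 0.5, 0.0, 0.0, 0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        cmm=st.floats(0.0, 1.0),
        cpe=st.floats(0.0, 1.0),
        dt=st.floats(0.0, 10.0),
        dz=st.floats(0.0, 10.0),
        dr=st.floats(0.0, 10.0),
    )
    def test_score_bounded_between_zero_and_one(self, cmm, cpe, dt, dz, dr):
        cs = colocalisation_score(cmm, cpe, dt, dz, dr)
        assert 0.0 <= cs <= 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        cmm=st.floats(0.05, 1.0),
        cpe=st.floats(0.05, 1.0),
        d0=st.floats(0.0, 5.0),
        bump=st.floats(0.01, 5.0),
    )
    def test_monotonicity_in_each_term(self, cmm, cpe, d0, bump):
        base = colocalisation_score(cmm, cpe, d0, 0.0, 0.0)
        assert colocalisation_score(cmm, cpe, d0 + bump, 0.0, 0.0) < base
        assert colocalisation_score(cmm * 0.5, cpe, d0, 0.0, 0.0) < base


class TestEnsembleNormalisation:
    def _cases(self):
        mk = lambda vi, ti, zi, vc, tc, zc: {
            "peaks": {
                "insulin": PeakInfo(value=vi, t=ti, z=zi, r=0.5),
                "C10": PeakInfo(value=vc, t=tc, z=zc, r=0.5),
            },
            "duration": 150.0,
            "wavelength": 2.4,
            "r0": 0.5,
        }
        return {
            "a": mk(0.02, 50.0, 3.6, 0.05, 52.0, 3.6),
            "b": mk(0.01, 80.0, 3.0, 0.025, 95.0, 4.2),
        }

    def test_best_case_attains_unit_normalised_peaks(self):
        recs = build_colocalisation_records(self._cases())
        by = {r.case_label: r for r in recs}
        assert by["a"].c_mm == pytest.approx(1.0)
        assert by["a"].c_pe == pytest.approx(1.0)
        assert by["b"].c_mm == pytest.approx(0.5)

    def test_separation_terms_normalised_by_case_scales(self):
        recs = build_colocalisation_records(self._cases())
        by = {r.case_label: r for r in recs}
        assert by["a"].dt_bar == pytest.approx(2.0 / 150.0)
        assert by["b"].dz_bar == pytest.approx(1.2 / 2.4)
        assert 0.0 <= by["b"].cs <= by["a"].cs <= 1.0

    def test_empty_ensemble_rejected(self):
        assert build_colocalisation_records({}) == []
        bad = self._cases()
        for d in bad.values():
            d["peaks"]["insulin"].value = 0.0
        with pytest.raises(ValueError, match="nonzero"):
            build_colocalisation_records(bad)
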