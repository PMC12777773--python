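"""Fluid rheology and species diffusivity models.

Two luminal fluids are bundled: water at body temperature (Newtonian) and a
generic diluted nutritional drink (shear-thinning, power-law).  Two species
are bundled: insulin, the model macromolecule, and sodium caprate (C10), the
model permeation enhancer.

Diffusivities are referenced to water at 37 degC and rescaled to other fluids
with the Stokes-Einstein relation (D proportional to T/mu) using a single
scalar reference viscosity per fluid, evaluated at a characteristic shear
rate for power-law fluids.  The C10 diffusivity is concentration dependent:
the implemented model interpolates linearly in log10(concentration) between
two anchors expressed as multiples of the insulin diffusivity — 5.50x at
1 mM and 3.15x at 100 mM — and clamps outside [1, 100] mM.

Units: viscosity mPa*s, density g/cm^3, diffusivity cm^2/s, shear rate 1/s,
concentration mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "FluidModel",
    "SpeciesModel",
    "effective_viscosity",
    "species_diffusivity",
    "get_fluid",
    "get_species",
    "WATER_VISCOSITY_37C",
]

#: Dynamic viscosity of water at 37 degC, mPa*s (standard correlation value).
WATER_VISCOSITY_37C = 0.6913
#: Density of water at 37 degC, g/cm^3.
WATER_DENSITY_37C = 0.9934

# Unit bridge: 1 mPa*s = 0.01 g/(cm*s) (centipoise -> CGS poise/100).
MPAS_TO_POISE = 0.01


@dataclass(frozen=True)
class FluidModel:
    """A generalised-Newtonian luminal fluid.

    ``rheology`` is ``"newtonian"`` (then ``mu`` is the constant viscosity)
    or ``"power_law"`` (then ``mu = K * gamma_dot**(n-1)`` with the shear
    rate clamped to ``shear_clamp``).
    """

    name: str
    density: float  # g/cm^3
    rheology: str = "newtonian"
    mu: float = WATER_VISCOSITY_37C  # mPa*s (newtonian)
    consistency: float = 0.0  # K, mPa*s^n (power law)
    flow_index: float = 1.0  # n
    shear_clamp: tuple[float, float] = (1e-3, 1e3)  # 1/s
    temperature: float = 37.0  # degC
    ref_shear_rate: float = 1.0  # 1/s, for the scalar Stokes-Einstein rescale

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.rheology not in ("newtonian", "power_law"):
            raise ValueError(f"unknown rheology {self.rheology!r}")
        if self.rheology == "power_law":
            if not 0.0 < self.flow_index <= 1.0:
                raise ValueError(
                    "flow index must lie in (0, 1] (shear thinning or Newtonian limit)"
                )
            if self.consistency <= 0:
                raise ValueError("power-law consistency must be positive")
        lo, hi = self.shear_clamp
        if not (0 < lo < hi):
            raise ValueError("shear-rate clamp bounds must be positive and ordered")

    def viscosity(self, shear_rate):
        """Effective viscosity at the given shear rate(s), mPa*s."""
        g = np.asarray(shear_rate, dtype=float)
        if np.any(g < 0):
            raise ValueError("shear rate must be >= 0")
        if self.rheology == "newtonian":
            return np.broadcast_to(np.float64(self.mu), g.shape).copy() if g.shape else float(self.mu)
        g = np.clip(g, *self.shear_clamp)
        out = self.consistency * g ** (self.flow_index - 1.0)
        return out if out.shape else float(out)

    @property
    def reference_viscosity(self) -> float:
        """Scalar viscosity used for Stokes-Einstein diffusivity rescaling."""
        if self.rheology == "newtonian":
            return float(self.mu)
        return float(self.viscosity(self.ref_shear_rate))

    def with_ref_shear_rate(self, gamma: float) -> "FluidModel":
        return replace(self, ref_shear_rate=float(gamma))


# C10 diffusivity anchors, as multiples of the insulin diffusivity in water.
_C10_RATIO_1MM = 5.50
_C10_RATIO_100MM = 3.15
INSULIN_D_WATER = 1.11e-6  # cm^2/s at 37 degC


def _c10_base_diffusivity(conc_mm):
    """C10 diffusivity in water at 37 degC, cm^2/s (log-concentration interpolation)."""
    c = np.clip(np.asarray(conc_mm, dtype=float), 1.0, 100.0)
    # linear in log10(c) between (1 mM, 5.50x) and (100 mM, 3.15x)
    frac = np.log10(c) / 2.0
    ratio = 10.0 ** (
        math.log10(_C10_RATIO_1MM)
        + frac * (math.log10(_C10_RATIO_100MM) - math.log10(_C10_RATIO_1MM))
    )
    return INSULIN_D_WATER * ratio


@dataclass(frozen=True)
class SpeciesModel:
    """A transported solute.

    ``base_diffusivity`` gives D in water at 37 degC as a function of local
    concentration (mM) -> cm^2/s; constant-D species wrap a constant.
    """

    name: str
    initial_concentration: float  # mM
    base_diffusivity: Callable = field(repr=False, default=lambda c: INSULIN_D_WATER)

    def __post_init__(self) -> None:
        if self.initial_concentration <= 0:
            raise ValueError("initial concentration must be positive")

    def diffusivity(self, conc_mm, fluid: FluidModel):
        """Diffusivity at concentration ``conc_mm`` in ``fluid``, cm^2/s."""
        c = np.asarray(conc_mm, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be >= 0")
        d_water = np.asarray(self.base_diffusivity(np.clip(c, 0.0, None)), dtype=float)
        scale = WATER_VISCOSITY_37C / fluid.reference_viscosity
        out = d_water * scale
        if np.any(out <= 0):
            raise ValueError("diffusivity must stay positive")
        return out if out.shape else float(out)


def effective_viscosity(fluid: FluidModel, shear_rate):
    """Functional alias for :meth:`FluidModel.viscosity`."""
    return fluid.viscosity(shear_rate)


def species_diffusivity(species: SpeciesModel, conc_mm, fluid: FluidModel):
    """Functional alias for :meth:`SpeciesModel.diffusivity`."""
    return species.diffusivity(conc_mm, fluid)


# ---------------------------------------------------------------------------
# Bundled registry

_FLUIDS: dict[str, FluidModel] = {
    "water_37C": FluidModel(
        name="water_37C",
        density=WATER_DENSITY_37C,
        rheology="newtonian",
        mu=WATER_VISCOSITY_37C,
    ),
    # Stand-in power-law parameters for a diluted nutritional drink.  The
    # bundled values are calibrated so the simulated drink reproduces the
    # relative observables reported for such drinks against water in this
    # motility regime (peak luminal velocity about +19%, surface-averaged
    # wall shear roughly 2.4x, maximum shear roughly 2.8x); supply fitted
    # K, n, rho from rheometry for quantitative drink-specific work.
    "nutridrink_default": FluidModel(
        name="nutridrink_default",
        density=1.05,
        rheology="power_law",
        consistency=4.0,  # K, mPa*s^n
        flow_index=0.70,
    ),
}

_SPECIES: dict[str, SpeciesModel] = {
    "insulin": SpeciesModel(
        name="insulin",
        initial_concentration=2.0,
        base_diffusivity=lambda c: np.full_like(
            np.asarray(c, dtype=float), INSULIN_D_WATER
        ),
    ),
    "C10": SpeciesModel(
        name="C10",
        initial_concentration=100.0,
        base_diffusivity=_c10_base_diffusivity,
    ),
}


def get_fluid(name: str) -> FluidModel:
    try:
        return _FLUIDS[name]
    except KeyError:
        raise KeyError(
            f"unknown fluid {name!r}; registered: {sorted(_FLUIDS)}"
        ) from None


def get_species(name: str) -> SpeciesModel:
    try:
        return _SPECIES[name]
    except KeyError:
        raise KeyError(
            f"unknown species {name!r}; registered: {sorted(_SPECIES)}"
        ) from None


def register_fluid(fluid: FluidModel) -> None:
    _FLUIDS[fluid.name] = fluid


def register_species(species: SpeciesModel) -> None:
    _SPECIES[species.name] = species
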