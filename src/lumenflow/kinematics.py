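"""Wall kinematics of small-intestinal motility.

Two motility programmes are modelled as prescribed motion of the epithelial
boundary of an axisymmetric lumen segment:

* **segmentation** — non-propagating, rhythmic circumferential contractions.
  The radial wall velocity is a standing wave

      Ur(z, t) = (2*pi*delta/tp) * cos(2*pi*z/lambda) * cos(2*pi*t/tp) + f(t)

  where ``f(t)`` is a spatially uniform correction enforcing *exact*
  conservation of luminal volume per wavelength at every instant (a standing
  sinusoidal deformation alone would pump fluid in and out of the segment
  through second-order effects of the radius appearing squared in the
  cross-section).  Integrating in time, the wall radius is

      h(z, t) = r0 + delta*sin(2*pi*t/tp)*cos(2*pi*z/lambda) + B(t),
      B(t)    = sqrt(r0^2 - (delta^2/2)*sin^2(2*pi*t/tp)) - r0,

  with B'(t) = f(t).  One checks directly that
  integral_0^lambda h^2 dz = r0^2 * lambda for all t.

* **peristalsis** — a propagating contraction wave,

      h(z, t) = r0 + delta * sin(2*pi*(z - c*t)/lambda),

  which conserves volume per wavelength trivially and is stationary in the
  frame travelling at the wave speed ``c``.

Units throughout: lengths cm, times s, volumes mL (= cm^3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import quad

__all__ = [
    "WallGeometry",
    "MotilityCase",
    "INTENSITY_LEVELS",
    "POCKET_WAVELENGTHS",
    "derive_geometry",
    "wall_radius",
    "wall_velocity",
    "check_volume_conservation",
]

MotilityType = Literal["segmentation", "peristalsis"]

#: Motility intensity -> (period tp in s, wave speed c in cm/s).
INTENSITY_LEVELS: dict[str, tuple[float, float]] = {
    "light": (7.0, 0.5),
    "moderate": (5.0, 1.0),
    "vigorous": (3.0, 1.5),
}

#: Default pocket-volume (mL) -> wavelength (cm) pairing.
POCKET_WAVELENGTHS: dict[float, float] = {2.0: 2.4, 10.0: 4.1}


@dataclass(frozen=True)
class WallGeometry:
    """Geometry and waveform of one motility pattern.

    Parameters
    ----------
    motility:
        ``"segmentation"`` or ``"peristalsis"``.
    r0:
        Rest (undeformed) lumen radius, cm.
    delta:
        Occlusion amplitude of the waveform, cm.  Must satisfy
        ``0 <= delta < r0*sqrt(2)`` so the volume-conservation offset stays
        real for segmentation.
    wavelength:
        Contraction wavelength, cm (one pocket per wavelength).
    period:
        Contraction period tp, s.  For peristalsis this is ``wavelength/c``.
    wave_speed:
        Peristaltic wave speed c, cm/s (``None`` for segmentation).
    n_pockets:
        Number of pockets in the simulated segment (3 for segmentation,
        30 for peristalsis by default).
    volume_offset:
        If True (default), segmentation includes the conservation offset
        B(t) in the realised wall position; the occlusion-ratio inversion in
        :func:`derive_geometry` accounts for it.
    """

    motility: MotilityType
    r0: float
    delta: float
    wavelength: float
    period: float
    wave_speed: float | None = None
    n_pockets: int = 3
    volume_offset: bool = True

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError(f"rest radius must be positive, got r0={self.r0}")
        if self.wavelength <= 0 or self.period <= 0:
            raise ValueError("wavelength and period must be positive")
        if self.delta < 0:
            raise ValueError(f"occlusion amplitude must be >= 0, got {self.delta}")
        if self.motility == "segmentation" and self.delta >= self.r0 * math.sqrt(2.0):
            raise ValueError(
                f"delta={self.delta:.4g} >= r0*sqrt(2)={self.r0 * math.sqrt(2.0):.4g}: "
                "the volume-conservation offset would become imaginary "
                "(wall would have to pass through itself)"
            )
        if self.motility == "peristalsis":
            if self.wave_speed is None or self.wave_speed <= 0:
                raise ValueError("peristalsis requires a positive wave_speed")
            if self.delta >= self.r0:
                raise ValueError("peristaltic amplitude must be < r0 (no full occlusion)")

    # -- segmentation building blocks ------------------------------------

    def _radicand(self, t):
        s = np.sin(2.0 * np.pi * np.asarray(t, dtype=float) / self.period)
        return self.r0**2 - 0.5 * self.delta**2 * s**2

    def offset(self, t):
        """Volume-conservation radial offset B(t), cm (segmentation)."""
        if not self.volume_offset:
            return np.zeros_like(np.asarray(t, dtype=float))
        rad = self._radicand(t)
        if np.any(rad <= 0):
            raise ValueError("invalid amplitude: offset radicand <= 0")
        return np.sqrt(rad) - self.r0

    def correction_velocity(self, t):
        """Correction term f(t) = B'(t), cm/s (segmentation)."""
        t = np.asarray(t, dtype=float)
        rad = self.r0**2 + 0.25 * self.delta**2 * (
            np.cos(4.0 * np.pi * t / self.period) - 1.0
        )
        if np.any(rad <= 0):
            raise ValueError("invalid amplitude: correction radicand <= 0")
        out = (
            -(np.pi * self.delta**2 / self.period)
            * np.sin(4.0 * np.pi * t / self.period)
            / (2.0 * np.sqrt(rad))
        )
        if not self.volume_offset:
            return np.zeros_like(out)
        return out

    # -- wall position / velocity ----------------------------------------

    def radius(self, z, t):
        """Instantaneous wall radius h(z, t), cm."""
        z = np.asarray(z, dtype=float)
        t = np.asarray(t, dtype=float)
        if self.motility == "segmentation":
            return (
                self.r0
                + self.delta
                * np.sin(2.0 * np.pi * t / self.period)
                * np.cos(2.0 * np.pi * z / self.wavelength)
                + self.offset(t)
            )
        phase = 2.0 * np.pi * (z - self.wave_speed * t) / self.wavelength
        return self.r0 + self.delta * np.sin(phase)

    def velocity(self, z, t):
        """Radial wall velocity dh/dt at (z, t), cm/s."""
        z = np.asarray(z, dtype=float)
        t = np.asarray(t, dtype=float)
        if self.motility == "segmentation":
            return (
                (2.0 * np.pi * self.delta / self.period)
                * np.cos(2.0 * np.pi * z / self.wavelength)
                * np.cos(2.0 * np.pi * t / self.period)
                + self.correction_velocity(t)
            )
        phase = 2.0 * np.pi * (z - self.wave_speed * t) / self.wavelength
        return -(2.0 * np.pi * self.delta * self.wave_speed / self.wavelength) * np.cos(
            phase
        )

    def dradius_dz(self, z, t):
        """Axial wall slope dh/dz at (z, t)."""
        z = np.asarray(z, dtype=float)
        t = np.asarray(t, dtype=float)
        k = 2.0 * np.pi / self.wavelength
        if self.motility == "segmentation":
            return (
                -self.delta * k * np.sin(2.0 * np.pi * t / self.period) * np.sin(k * z)
            )
        return self.delta * k * np.cos(k * (z - self.wave_speed * t))

    # -- derived quantities -----------------------------------------------

    def min_radius(self) -> float:
        """Minimum wall radius over a full cycle (defines the occlusion ratio)."""
        if self.motility == "peristalsis":
            return self.r0 - self.delta
        if self.volume_offset:
            return math.sqrt(self.r0**2 - 0.5 * self.delta**2) - self.delta
        return self.r0 - self.delta

    @property
    def occlusion_ratio(self) -> float:
        return self.min_radius() / self.r0

    @property
    def domain_length(self) -> float:
        return self.n_pockets * self.wavelength

    def pocket_center(self, k: int) -> float:
        """Axial centre (most-occluded point) of pocket ``k`` (0-based).

        Pockets are the intervals [k*lambda, (k+1)*lambda).  For segmentation
        the most-occluded point of pocket k (during the contracted half-cycle
        sin(2*pi*t/tp) > 0) is where cos(2*pi*z/lambda) = -1, i.e.
        z = (k + 1/2)*lambda.  For peristalsis it is the wave trough at t=0,
        z = (k + 3/4)*lambda.
        """
        if self.motility == "segmentation":
            return (k + 0.5) * self.wavelength
        return (k + 0.75) * self.wavelength


def derive_geometry(
    pocket_volume: float,
    wavelength: float,
    occlusion_ratio: float,
    motility: MotilityType,
    *,
    period: float | None = None,
    wave_speed: float | None = None,
    n_pockets: int | None = None,
    volume_offset: bool = True,
) -> WallGeometry:
    """Build a :class:`WallGeometry` from physiological descriptors.

    The rest radius is set so a rest cylinder of one wavelength holds the
    pocket volume, ``r0 = sqrt(V/(pi*lambda))``.  The amplitude ``delta`` is
    inverted from the occlusion ratio OR = (minimum cycle radius)/r0:

    * segmentation with the volume offset: the minimum realised radius is
      ``sqrt(r0^2 - delta^2/2) - delta``, giving the quadratic solution
      ``delta = r0*(-2*OR + sqrt(6 - 2*OR^2))/3``;
    * peristalsis (or offset disabled): ``delta = (1 - OR)*r0``.
    """
    if pocket_volume <= 0 or wavelength <= 0:
        raise ValueError("pocket volume and wavelength must be positive")
    if not 0.0 < occlusion_ratio < 1.0:
        raise ValueError(
            f"occlusion ratio must lie in (0, 1); got {occlusion_ratio} "
            "(OR is the minimum-to-rest radius ratio of the contracting lumen)"
        )
    r0 = math.sqrt(pocket_volume / (math.pi * wavelength))
    if motility == "segmentation" and volume_offset:
        delta = r0 * (-2.0 * occlusion_ratio + math.sqrt(6.0 - 2.0 * occlusion_ratio**2)) / 3.0
    else:
        delta = (1.0 - occlusion_ratio) * r0
    if motility == "segmentation":
        if period is None:
            raise ValueError("segmentation requires a period")
        tp = period
        c = None
    else:
        if wave_speed is None:
            raise ValueError("peristalsis requires a wave_speed")
        c = wave_speed
        tp = wavelength / wave_speed
    if n_pockets is None:
        n_pockets = 3 if motility == "segmentation" else 30
    return WallGeometry(
        motility=motility,
        r0=r0,
        delta=delta,
        wavelength=wavelength,
        period=tp,
        wave_speed=c,
        n_pockets=n_pockets,
        volume_offset=volume_offset,
    )


def wall_radius(geom: WallGeometry, z, t):
    """Functional alias for :meth:`WallGeometry.radius`."""
    return geom.radius(z, t)


def wall_velocity(geom: WallGeometry, z, t):
    """Functional alias for :meth:`WallGeometry.velocity`."""
    if geom.motility != "segmentation":
        return geom.velocity(z, t)
    return geom.velocity(z, t)


def check_volume_conservation(geom: WallGeometry, t: float) -> float:
    """Relative error of the luminal volume per wavelength at time ``t``.

    Evaluates the luminal volume per wavelength by adaptive quadrature and
    compares it with its time-independent reference: ``pi*r0^2*lambda`` for
    segmentation (the conservation offset enforces this exactly) and
    ``pi*(r0^2 + delta^2/2)*lambda`` for a sinusoidal travelling wave (whose
    volume exceeds the rest cylinder by the mean-square wave amplitude).
    """
    val, _ = quad(lambda z: geom.radius(z, t) ** 2, 0.0, geom.wavelength, limit=200)
    ref = geom.r0**2 * geom.wavelength
    if geom.motility == "peristalsis":
        ref = (geom.r0**2 + 0.5 * geom.delta**2) * geom.wavelength
    return abs(val - ref) / ref


# ---------------------------------------------------------------------------
# Motility cases


@dataclass(frozen=True)
class MotilityCase:
    """One fully parameterised simulation scenario.

    ``fluid_id`` and ``species`` refer to entries of the fluid/species
    registry (:mod:`lumenflow.fluids`).  ``release_position`` selects release
    at the most-occluded pocket centre or a quarter wavelength off-centre
    (least occluded), both on the centreline.
    """

    motility: MotilityType
    intensity: str = "moderate"
    fluid_id: str = "nutridrink_default"
    pocket_volume: float = 2.0  # mL
    occlusion_ratio: float = 0.3
    release_position: Literal["most_occluded", "least_occluded"] = "most_occluded"
    species: Sequence[str] = ("insulin", "C10")
    n_periods: int = 30
    wavelength: float | None = None  # override of the volume pairing, cm
    n_pockets: int | None = None
    volume_offset: bool = True

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITY_LEVELS:
            raise ValueError(
                f"unknown intensity {self.intensity!r}; expected one of "
                f"{sorted(INTENSITY_LEVELS)}"
            )
        if not 0.0 < self.occlusion_ratio < 1.0:
            raise ValueError("occlusion ratio must lie in (0, 1)")
        if self.n_periods <= 0:
            raise ValueError("n_periods must be positive")

    @property
    def period(self) -> float:
        tp, c = INTENSITY_LEVELS[self.intensity]
        if self.motility == "peristalsis":
            return self.resolved_wavelength / c
        return tp

    @property
    def wave_speed(self) -> float | None:
        if self.motility == "peristalsis":
            return INTENSITY_LEVELS[self.intensity][1]
        return None

    @property
    def resolved_wavelength(self) -> float:
        if self.wavelength is not None:
            return self.wavelength
        try:
            return POCKET_WAVELENGTHS[float(self.pocket_volume)]
        except KeyError:
            raise ValueError(
                f"no default wavelength for pocket volume {self.pocket_volume} mL; "
                "pass wavelength= explicitly"
            ) from None

    def geometry(self) -> WallGeometry:
        tp, c = INTENSITY_LEVELS[self.intensity]
        return derive_geometry(
            self.pocket_volume,
            self.resolved_wavelength,
            self.occlusion_ratio,
            self.motility,
            period=tp,
            wave_speed=c,
            n_pockets=self.n_pockets,
            volume_offset=self.volume_offset,
        )

    def label(self) -> str:
        return (
            f"{self.motility}-{self.intensity}-{self.fluid_id}"
            f"-{self.pocket_volume:g}mL-OR{self.occlusion_ratio:g}"
            f"-{self.release_position}"
        )

    def with_(self, **kw) -> "MotilityCase":
        return replace(self, **kw)
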