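"""Stenosed-vessel geometry and quasi-static elastic wall response.

The vessel is an axisymmetric tube of rest radius ``R0`` carrying a cosine
stenosis of height ``delta`` over ``|x| <= x0``.  The stenotic segment
oscillates sinusoidally at angular frequency ``omega_wall`` with relative
amplitude ``alpha``, emulating wall motion imposed by surrounding tissue
(heartbeat, breathing):

    R(x, t) = R0 * [1 - (delta / 2 R0) (1 + alpha sin(omega t))
                        (1 + cos(pi x / x0))]        for |x| <= x0
    R(x, t) = R0                                      otherwise

On top of this prescribed motion the wall responds quasi-statically to the
local transmural pressure of the flow.  Dropping wall inertia and fluid shear
on the wall, the thin-shell radial displacement is

    xi = p R^2 (1 - sigma^2) / (E h)

with Young's modulus ``E``, Poisson ratio ``sigma`` and wall thickness ``h``.
All quantities are SI internally (metres, seconds, pascals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class VesselGeometry:
    """Axisymmetric stenosed tube with a sinusoidally oscillating stenosis.

    Parameters
    ----------
    R0 : float
        Rest lumen radius (m).
    delta : float
        Maximum stenosis height (m); ``delta/R0`` is the radius-reduction
        stenosis degree.
    alpha : float
        Dimensionless wall-oscillation amplitude coefficient.
    omega_wall : float
        Wall oscillation angular frequency (rad/s).
    x0 : float
        Stenosis half-length (m).
    h : float
        Wall thickness (m).
    axial_extent : tuple of float
        ``(x_min, x_max)`` of the computational domain (m).
    """

    R0: float
    delta: float
    alpha: float
    omega_wall: float
    x0: float
    h: float
    axial_extent: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.R0 <= 0:
            raise ConfigurationError(f"R0 must be positive, got {self.R0}")
        if not 0 <= self.delta < self.R0:
            raise ConfigurationError(
                f"delta must satisfy 0 <= delta < R0, got delta={self.delta}"
            )
        if self.delta * (1.0 + abs(self.alpha)) >= self.R0:
            raise ConfigurationError(
                "lumen closes: delta*(1+|alpha|) must stay below R0"
            )
        if self.x0 <= 0:
            raise ConfigurationError(f"x0 must be positive, got {self.x0}")
        if self.h <= 0:
            raise ConfigurationError(f"wall thickness h must be positive, got {self.h}")
        if self.axial_extent is None:
            object.__setattr__(self, "axial_extent", (-2.0 * self.x0, 2.0 * self.x0))
        x_min, x_max = self.axial_extent
        if not x_min < x_max:
            raise ConfigurationError("axial_extent must be an increasing pair")

    @property
    def stenosis_degree(self) -> float:
        """Fractional radius reduction delta/R0."""
        return self.delta / self.R0


@dataclass(frozen=True)
class WallProperties:
    """Elastic wall constants. ``B = E/(1-sigma^2)`` is always derived."""

    E: float
    sigma: float
    rho_w: float = 1100.0

    def __post_init__(self):
        if self.E <= 0:
            raise ConfigurationError(f"Young's modulus must be positive, got {self.E}")
        if not 0.0 <= self.sigma < 1.0:
            raise ConfigurationError(
                f"Poisson ratio must lie in [0, 1), got {self.sigma}"
            )

    @property
    def B(self) -> float:
        """Effective stiffness E/(1 - sigma^2) (Pa)."""
        return self.E / (1.0 - self.sigma**2)


@dataclass(frozen=True)
class FluidProperties:
    """Blood density (kg/m^3) and dynamic viscosity (Pa s)."""

    rho: float
    mu: float

    def __post_init__(self):
        if self.rho <= 0:
            raise ConfigurationError(f"density must be positive, got {self.rho}")
        if self.mu <= 0:
            raise ConfigurationError(f"viscosity must be positive, got {self.mu}")


def radius_at(geom: VesselGeometry, x, t):
    """Lumen radius R(x, t) of the oscillating stenosed tube (m).

    Vectorised over ``x`` and ``t`` (broadcasting).  Outside ``|x| > x0`` the
    tube is straight at ``R0`` for all times; the profile is continuous at
    ``|x| = x0`` because the cosine bump vanishes there.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(x / geom.x0, -1.0, 1.0)))
    bump = np.where(np.abs(x) <= geom.x0, bump, 0.0)
    wobble = 1.0 + geom.alpha * np.sin(geom.omega_wall * t)
    r = geom.R0 - geom.delta * wobble * bump
    return r if r.shape else float(r)


def radius_x_derivative(geom: VesselGeometry, x, t):
    """dR/dx (dimensionless), continuous and zero outside the stenosis."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    slope = (
        geom.delta
        * 0.5
        * (np.pi / geom.x0)
        * np.sin(np.pi * np.clip(x / geom.x0, -1.0, 1.0))
    )
    slope = np.where(np.abs(x) <= geom.x0, slope, 0.0)
    wobble = 1.0 + geom.alpha * np.sin(geom.omega_wall * t)
    d = slope * wobble
    return d if d.shape else float(d)


def compliance_displacement(wall: WallProperties, geom: VesselGeometry, p, R):
    """Quasi-static radial wall displacement xi = p R^2 (1-sigma^2)/(E h) (m).

    Linear in the transmural pressure ``p``; the sign of the displacement
    follows the sign of ``p``.  Vectorised over ``p`` and ``R``.
    """
    if geom.h <= 0 or wall.E <= 0:
        raise ConfigurationError("compliance requires h > 0 and E > 0")
    p = np.asarray(p, dtype=float)
    R = np.asarray(R, dtype=float)
    xi = p * R**2 * (1.0 - wall.sigma**2) / (wall.E * geom.h)
    return xi if xi.shape else float(xi)


def wall_trajectory(
    geom: VesselGeometry,
    wall: WallProperties,
    pressure_trace,
    times,
    x: float = 0.0,
):
    """Reference radial wall position R(x, t) + xi(t) at a fixed station.

    ``pressure_trace`` is the local pulsatile pressure p(t) sampled at
    ``times``; the trace combines the prescribed stenosis oscillation with the
    quasi-static compliance response and serves as the numerical ground truth
    against which ultrasound-derived wall displacement is scored.
    """
    times = np.asarray(times, dtype=float)
    p = np.broadcast_to(np.asarray(pressure_trace, dtype=float), times.shape)
    R = radius_at(geom, x, times)
    xi = compliance_displacement(wall, geom, p, R)
    from .tracking import DisplacementTrace

    return DisplacementTrace(times=times, position=R + xi, source="numerical")
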