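"""Magneto-acoustic (Lorentz-force) coupling of pressure to E-field and current.

In a conductive medium placed in a static magnetic field B0, the oscillatory
particle motion of an ultrasound wave drags charge carriers with velocity V,
and the Lorentz force separates them, producing an equivalent electric field

    E = V x B0,        J = sigma * E,

with, for a plane wave, V = P / (rho * cs) along the propagation direction.
The induced field is therefore perpendicular to both the beam axis and B0,
and its spatial distribution is an exact scalar multiple of the pressure
magnitude distribution: focusing the ultrasound focuses the E-field.

With the package geometry (beam along +y, B0 along +x) the vector product
y_hat x x_hat = -z_hat puts E along -z; all comparisons use magnitudes, and
the sign merely fixes the phase convention of the oscillation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .acoustic import ComplexPressureField, ConfigurationError, Medium, CartesianGrid

__all__ = [
    "StaticField",
    "EFieldMap",
    "particle_velocity",
    "induced_efield",
    "current_density",
    "efield_from_pressure_map",
]

BEAM_AXIS = np.array([0.0, 1.0, 0.0])


@dataclass(frozen=True)
class StaticField:
    """Static magnetic flux density B0, Tesla (3-vector)."""

    b0: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.b0, dtype=float)
        if v.shape != (3,) or not np.all(np.isfinite(v)):
            raise ValueError("B0 must be a finite 3-vector")
        object.__setattr__(self, "b0", tuple(float(c) for c in v))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.b0, dtype=float)

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.vector))


@dataclass
class EFieldMap:
    """Induced E-field vectors (V/m), optionally on the grid of the source field."""

    vectors: np.ndarray  # shape (..., 3)
    grid: CartesianGrid | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape[-1] != 3:
            raise ValueError("E-field vectors must have a trailing axis of size 3")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)


def particle_velocity(pressure, medium: Medium):
    """Plane-wave particle velocity V = P / (rho * cs), m/s.

    Accepts scalars or arrays; the sign of the velocity follows the sign of
    the instantaneous pressure.
    """
    if medium.impedance <= 0:
        raise ConfigurationError("acoustic impedance rho*cs must be > 0")
    return np.asarray(pressure, dtype=float) / medium.impedance


def induced_efield(velocity, b: StaticField) -> np.ndarray:
    """Lorentz E-field E = V x B0 for velocity 3-vector(s), V/m."""
    v = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("velocity must be finite")
    return np.cross(v, b.vector)


def current_density(e, medium: Medium) -> np.ndarray:
    """Ohmic current density J = sigma * E, A/m^2."""
    return medium.conductivity * np.asarray(e, dtype=float)


def efield_from_pressure_map(
    field: ComplexPressureField,
    b: StaticField,
    medium: Medium,
    propagation_axis=BEAM_AXIS,
) -> EFieldMap:
    """Map a pressure-magnitude field to the induced E-field, pointwise.

    Under the plane-wave approximation the local particle velocity is
    ``|p|/(rho*cs)`` along the nominal beam axis, so

        E = (|p| / (rho*cs)) * (axis x B0),

    identical to composing :func:`particle_velocity` with
    :func:`induced_efield` at each node.  The resulting magnitude
    distribution is the pressure distribution times the constant
    ``|B0_perp|/(rho*cs)``.

    A zero B0 degenerates to plain ultrasound stimulation: the map is all
    zero and a warning is issued.
    """
    axis = np.asarray(propagation_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isclose(norm, 1.0, atol=1e-6):
        raise ValueError("propagation_axis must be a unit vector")
    if b.magnitude == 0:
        warnings.warn(
            "B0 is zero: no Lorentz E-field is induced (TUS degenerate case)",
            stacklevel=2,
        )
    direction = np.cross(axis, b.vector)  # carries |B0| sin(angle)
    vel = field.magnitude() / medium.impedance
    vectors = vel[..., None] * direction
    return EFieldMap(vectors=vectors, grid=field.grid)
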