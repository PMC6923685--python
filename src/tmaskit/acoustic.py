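"""Steady-state pressure fields of a focused spherical-cap transducer.

A single-element concave (bowl) source driven at its carrier frequency for
many cycles per burst radiates what is effectively a continuous wave, so the
field is computed in the frequency domain: the complex pressure amplitude
``p(r)`` satisfies the Helmholtz equation and is obtained by discretising the
Rayleigh integral over the cap surface,

    p(r) = -(i k p0 / 2 pi) * integral over cap of  exp(i k R) / R  dS,

where ``p0 = rho * cs * u0`` is the characteristic surface drive of a
uniformly vibrating cap (normal velocity ``u0``), ``k = 2 pi f / cs`` and
``R`` the source-to-field distance.  The closed-form on-axis solution of the
uniformly vibrating bowl (O'Neil's solution) is provided as an independent
oracle for the numerical field.

Geometry convention: transducer apex at the origin, beam axis along +y, the
cap opening faces +y with its centre of curvature at ``(0, F, 0)``.  A static
magnetic field applied along +x induces a Lorentz E-field along ±z (see
:mod:`tmaskit.lorentz`).  Strict SI units internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .beam import ScanMap

__all__ = [
    "ConfigurationError",
    "GridError",
    "TransducerSpec",
    "Medium",
    "CartesianGrid",
    "ComplexPressureField",
    "oneil_axial_pressure",
    "rayleigh_field",
    "calibrate_drive",
    "extract_plane",
    "cap_source_points",
]

# Surface quadrature density for the Rayleigh integral: number of source
# elements per acoustic wavelength along each surface direction.
ELEMENTS_PER_WAVELENGTH = 6.0


class ConfigurationError(ValueError):
    """Invalid transducer, medium or protocol configuration."""


class GridError(ValueError):
    """Grid unusable for the requested field computation."""


@dataclass(frozen=True)
class TransducerSpec:
    """Geometry and drive of a focused spherical-cap source.

    Parameters
    ----------
    carrier_frequency : float
        Drive frequency in Hz.
    geometric_focus : float
        Radius of curvature of the cap in metres; equals the nominal focal
        length of the transducer.
    aperture_diameter : float
        Diameter of the cap rim in metres.  Must be smaller than
        ``2 * geometric_focus`` for the cap geometry to exist.
    surface_drive : float
        Characteristic surface pressure ``rho * cs * u0`` in Pa, with ``u0``
        the (uniform) normal surface velocity amplitude.
    """

    carrier_frequency: float
    geometric_focus: float
    aperture_diameter: float
    surface_drive: float = 1.0

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ConfigurationError("carrier_frequency must be > 0")
        if self.geometric_focus <= 0:
            raise ConfigurationError("geometric_focus must be > 0")
        if not 0 < self.aperture_diameter < 2 * self.geometric_focus:
            raise ConfigurationError(
                "aperture_diameter must lie in (0, 2*geometric_focus)"
            )
        if self.surface_drive <= 0:
            raise ConfigurationError("surface_drive must be > 0")

    @property
    def aperture_radius(self) -> float:
        return self.aperture_diameter / 2.0

    @property
    def cap_depth(self) -> float:
        """Depth h = F - sqrt(F^2 - a^2) of the cap along the beam axis."""
        f, a = self.geometric_focus, self.aperture_radius
        return f - np.sqrt(f * f - a * a)

    def wavenumber(self, medium: "Medium") -> float:
        return 2.0 * np.pi * self.carrier_frequency / medium.sound_speed


@dataclass(frozen=True)
class Medium:
    """Homogeneous, lossless propagation medium.

    density in kg/m^3, sound_speed in m/s, conductivity in S/m.  Defaults are
    the soft-tissue-like constants used throughout this package.
    """

    density: float = 1000.0
    sound_speed: float = 1450.0
    conductivity: float = 1.0

    def __post_init__(self) -> None:
        if min(self.density, self.sound_speed, self.conductivity) <= 0:
            raise ConfigurationError("medium constants must be strictly positive")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance rho*cs in Pa s/m."""
        return self.density * self.sound_speed

    def wavelength(self, frequency: float) -> float:
        if frequency <= 0:
            raise ConfigurationError("frequency must be > 0")
        return self.sound_speed / frequency


class CartesianGrid:
    """Cartesian sampling grid for field computation (coordinates in metres).

    Convention: apex at origin, beam axis +y, B0 along +x, induced E along
    ±z; the focal plane sits nominally at ``y = geometric_focus``.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> None:
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.z = np.asarray(z, dtype=float)
        for name, ax in (("x", self.x), ("y", self.y), ("z", self.z)):
            if ax.ndim != 1 or ax.size == 0:
                raise GridError(f"axis {name} must be a non-empty 1-D array")
            if ax.size > 1 and not np.all(np.diff(ax) > 0):
                raise GridError(f"axis {name} must be strictly increasing")

    @classmethod
    def regular(
        cls,
        x_range: tuple[float, float],
        y_range: tuple[float, float],
        z_range: tuple[float, float],
        step: float,
    ) -> "CartesianGrid":
        """Build a uniform grid with the given step (metres) on each axis."""
        if step <= 0:
            raise GridError("step must be > 0")

        def axis(lo: float, hi: float) -> np.ndarray:
            n = int(np.floor((hi - lo) / step + 1e-9)) + 1
            return lo + step * np.arange(n)

        return cls(axis(*x_range), axis(*y_range), axis(*z_range))

    @classmethod
    def centered(
        cls,
        x_halfwidth: float,
        y_range: tuple[float, float],
        z_halfwidth: float,
        step: float,
    ) -> "CartesianGrid":
        """Uniform grid whose x and z axes are symmetric about the beam axis.

        The x and z axes contain 0 exactly (odd point counts), so on-axis
        values are sampled without lateral offset; y spans ``y_range``.
        """
        if step <= 0:
            raise GridError("step must be > 0")

        def sym(half: float) -> np.ndarray:
            n = int(np.floor(half / step + 1e-9))
            return step * np.arange(-n, n + 1)

        ny = int(np.floor((y_range[1] - y_range[0]) / step + 1e-9)) + 1
        return cls(sym(x_halfwidth), y_range[0] + step * np.arange(ny), sym(z_halfwidth))

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.x.size, self.y.size, self.z.size)

    def max_spacing(self) -> float:
        steps = [np.diff(ax).max() for ax in (self.x, self.y, self.z) if ax.size > 1]
        return max(steps) if steps else 0.0


@dataclass
class ComplexPressureField:
    """Monochromatic complex pressure amplitude on a Cartesian grid.

    ``amplitude[i, j, k]`` is the complex pressure (Pa) at
    ``(x[i], y[j], z[k])``; its magnitude scales linearly with the surface
    drive of the source.
    """

    grid: CartesianGrid
    amplitude: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude)
        if self.amplitude.shape != self.grid.shape:
            raise GridError("amplitude shape does not match grid shape")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("pressure amplitude contains non-finite values")

    def magnitude(self) -> np.ndarray:
        return np.abs(self.amplitude)


def oneil_axial_pressure(
    spec: TransducerSpec, medium: Medium, axial_positions: np.ndarray
) -> np.ndarray:
    """Closed-form on-axis pressure magnitude of the uniformly driven bowl.

    For an axial point ``y`` (metres, measured from the apex) the magnitude is

        |p(y)| = 2 p0 |sin(k (d(y) - y) / 2)| / |1 - y/F|,

    with ``d(y) = sqrt((y - h)^2 + a^2)`` the distance from the cap rim and
    ``h`` the cap depth.  At the geometric focus both numerator and
    denominator vanish and the analytic limit ``|p(F)| = p0 * k * h`` is
    returned.

    Parameters
    ----------
    axial_positions : array-like
        Non-negative positions along the beam axis, metres.

    Returns
    -------
    ndarray of pressure magnitudes, Pa.
    """
    y = np.atleast_1d(np.asarray(axial_positions, dtype=float))
    if np.any(y < 0):
        raise ValueError("axial positions must be >= 0")
    f = spec.geometric_focus
    a = spec.aperture_radius
    h = spec.cap_depth
    k = spec.wavenumber(medium)
    p0 = spec.surface_drive

    d = np.sqrt((y - h) ** 2 + a * a)
    denom = 1.0 - y / f
    near_focus = np.abs(denom) < 1e-9
    safe = np.where(near_focus, 1.0, denom)
    mag = 2.0 * p0 * np.abs(np.sin(0.5 * k * (d - y))) / np.abs(safe)
    return np.where(near_focus, p0 * k * h, mag)


def cap_source_points(
    spec: TransducerSpec,
    medium: Medium,
    elements_per_wavelength: float = ELEMENTS_PER_WAVELENGTH,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quadrature points for the Rayleigh integral over the cap surface.

    The cap is sliced into latitude rings (midpoint rule in the polar angle)
    and each ring into azimuthal elements so that element extent is at most
    ``wavelength / elements_per_wavelength`` in both surface directions.

    Returns
    -------
    (ring_radius, ring_height, weight, azimuth) : ndarrays of length N
        Cylindrical source coordinates (radius from the beam axis, height
        above the apex along +y), element areas (m^2) and azimuthal angles.
    """
    lam = medium.wavelength(spec.carrier_frequency) / elements_per_wavelength
    f, a = spec.geometric_focus, spec.aperture_radius
    theta_max = np.arcsin(a / f)
    n_theta = max(4, int(np.ceil(f * theta_max / lam)))
    dtheta = theta_max / n_theta
    theta = (np.arange(n_theta) + 0.5) * dtheta

    radii, heights, weights, azimuths = [], [], [], []
    for t in theta:
        ring_r = f * np.sin(t)
        n_phi = max(6, int(np.ceil(2 * np.pi * ring_r / lam)))
        phi = 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
        area = f * f * np.sin(t) * dtheta * (2 * np.pi / n_phi)
        radii.append(np.full(n_phi, ring_r))
        heights.append(np.full(n_phi, f * (1.0 - np.cos(t))))
        weights.append(np.full(n_phi, area))
        azimuths.append(phi)
    return (
        np.concatenate(radii),
        np.concatenate(heights),
        np.concatenate(weights),
        np.concatenate(azimuths),
    )


def _min_distance_to_cap(spec: TransducerSpec, rad: np.ndarray, y: np.ndarray) -> float:
    """Minimum distance from field nodes (cylindrical rad, axial y) to the cap."""
    f, a = spec.geometric_focus, spec.aperture_radius
    h = spec.cap_depth
    # distance to the spherical shell (centre of curvature at y = F)
    dc = np.sqrt(rad * rad + (y - f) ** 2)
    # polar angle of the node seen from the centre, measured from -y
    on_cap = np.arctan2(rad, f - y) <= np.arcsin(a / f)
    shell = np.abs(dc - f)
    rim = np.sqrt((rad - a) ** 2 + (y - h) ** 2)
    d = np.where(on_cap, shell, rim)
    return float(d.min())


def rayleigh_field(
    spec: TransducerSpec,
    medium: Medium,
    grid: CartesianGrid,
    *,
    elements_per_wavelength: float = ELEMENTS_PER_WAVELENGTH,
    coarse_grid: str = "error",
    chunk_size: int = 256,
) -> ComplexPressureField:
    """Complex pressure field of the cap source by Rayleigh surface integration.

    The source is axisymmetric about the beam (+y) axis, so the field depends
    on a node only through its axial position and its distance from the axis.
    Nodes sharing an axis distance are evaluated once (exact reduction, no
    interpolation), which makes millimetre-resolution 3-D domains tractable.

    Parameters
    ----------
    coarse_grid : {"error", "warn"}
        Behaviour when the grid spacing exceeds a quarter wavelength.

    Raises
    ------
    GridError
        If the grid is too coarse (when ``coarse_grid="error"``) or a node
        (nearly) touches the transducer surface.
    """
    lam = medium.wavelength(spec.carrier_frequency)
    if grid.max_spacing() > lam / 4 * (1 + 1e-9):
        msg = (
            f"grid spacing {grid.max_spacing():.3e} m exceeds lambda/4 = "
            f"{lam / 4:.3e} m"
        )
        if coarse_grid == "warn":
            warnings.warn(msg, stacklevel=2)
        else:
            raise GridError(msg)

    k = spec.wavenumber(medium)
    src_r, src_h, src_w, src_phi = cap_source_points(
        spec, medium, elements_per_wavelength
    )
    # cartesian source coordinates in the (x, z) plane
    sx = src_r * np.cos(src_phi)
    sz = src_r * np.sin(src_phi)

    # unique axis distances over the x-z cross grid
    r2 = grid.x[:, None] ** 2 + grid.z[None, :] ** 2
    r2_round = np.round(r2, 18)
    uniq_r2, inverse = np.unique(r2_round, return_inverse=True)
    inverse = inverse.reshape(r2.shape)
    uniq_r = np.sqrt(uniq_r2)

    ry, yy = np.meshgrid(uniq_r, grid.y, indexing="ij")
    if _min_distance_to_cap(spec, ry.ravel(), yy.ravel()) < lam / 8:
        raise GridError("field grid intersects or touches the transducer surface")

    # field points on the half-plane z=0: (x=r, y)
    pts_r = ry.ravel()
    pts_y = yy.ravel()
    out = np.empty(pts_r.size, dtype=complex)
    prefactor = -1j * k * spec.surface_drive / (2 * np.pi)
    for start in range(0, pts_r.size, chunk_size):
        sl = slice(start, start + chunk_size)
        dx = pts_r[sl, None] - sx[None, :]
        dy = pts_y[sl, None] - src_h[None, :]
        rdist = np.sqrt(dx * dx + dy * dy + (sz * sz)[None, :])
        out[sl] = (np.exp(1j * k * rdist) / rdist) @ src_w
    out *= prefactor
    field_ry = out.reshape(uniq_r.size, grid.y.size)
    amplitude = field_ry[inverse, :].transpose(0, 2, 1)
    return ComplexPressureField(grid=grid, amplitude=amplitude, frequency=spec.carrier_frequency)


def calibrate_drive(
    spec: TransducerSpec, medium: Medium, target_focal_pressure: float
) -> TransducerSpec:
    """Rescale the surface drive so the axial peak pressure equals a target.

    Uses the closed-form on-axis solution (exact by linearity of the wave
    equation) over a fine axial scan around the geometric focus.
    """
    if target_focal_pressure <= 0:
        raise ConfigurationError("target focal pressure must be > 0")
    f = spec.geometric_focus
    y = np.linspace(0.5 * f, 1.5 * f, 4001)
    peak = oneil_axial_pressure(spec, medium, y).max()
    return replace(spec, surface_drive=spec.surface_drive * target_focal_pressure / peak)


def extract_plane(
    field: ComplexPressureField, plane: str, offset: float
) -> ScanMap:
    """Extract a 2-D magnitude map from a 3-D field.

    Parameters
    ----------
    plane : {"xy", "xz"}
        ``"xy"`` slices at fixed z = offset; ``"xz"`` at fixed y = offset
        (the focal-plane convention, e.g. ``extract_plane(f, "xz", 0.023)``).
    offset : float
        Slice coordinate in metres; must lie within the grid bounds.  The
        nearest grid node is used; ties break toward the lower index.
    """
    g = field.grid
    if plane == "xy":
        axis_coords, take = g.z, 2
        c0, c1, labels = g.x, g.y, ("x_mm", "y_mm")
    elif plane == "xz":
        axis_coords, take = g.y, 1
        c0, c1, labels = g.x, g.z, ("x_mm", "z_mm")
    else:
        raise ValueError(f"plane must be 'xy' or 'xz', got {plane!r}")
    if not (axis_coords[0] <= offset <= axis_coords[-1]):
        raise ValueError(
            f"offset {offset} m outside grid bounds "
            f"[{axis_coords[0]}, {axis_coords[-1]}]"
        )
    idx = int(np.argmin(np.abs(axis_coords - offset)))  # first (lower) on ties
    mag = np.take(field.magnitude(), idx, axis=take)
    label = f"{plane}@{axis_coords[idx] * 1e3:.3f}mm"
    return ScanMap(
        plane=label,
        coords=(c0 * 1e3, c1 * 1e3),
        coord_labels=labels,
        amplitude=mag,
    )
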