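"""Quantification of 2-D beam scan maps and 1-D beam profiles.

Works identically on simulated fields, hydrophone-style measurements and
synthetic emulations: normalization to the map maximum, half-amplitude
(-6 dB) focal width, focal length from the axial peak, distribution
agreement between maps, and linearity of a response against drive pressure.

"Focus size" is quantified as the -6 dB full width of the pressure-magnitude
profile — the full width of the interval around the peak where the amplitude
stays at or above half its maximum — which is the standard hydrophone
beam-plot criterion.  Half-maximum crossings are located by linear
interpolation between samples, which matters when the scan step (2 mm in the
emulated measurements) is comparable to the focal width itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "ScanMap",
    "BeamReport",
    "LinearFit",
    "ProfileError",
    "normalize_map",
    "minus6db_width",
    "focal_length",
    "map_correlation",
    "linearity_fit",
    "profile_through_peak",
    "beam_report",
]


class ProfileError(ValueError):
    """Profile unsuitable for the requested metric (truncated, flat, ...)."""


@dataclass
class ScanMap:
    """A 2-D amplitude map sampled on a uniform coordinate grid.

    coords are in millimetres; amplitude units are arbitrary (Pa, V/m, V —
    metrics that compare maps always normalize first).
    """

    plane: str
    coords: tuple[np.ndarray, np.ndarray]
    amplitude: np.ndarray
    coord_labels: tuple[str, str] = ("x_mm", "y_mm")
    normalized: bool = False

    def __post_init__(self) -> None:
        c0 = np.asarray(self.coords[0], dtype=float)
        c1 = np.asarray(self.coords[1], dtype=float)
        self.coords = (c0, c1)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (c0.size, c1.size):
            raise ValueError("amplitude shape does not match coordinate arrays")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude contains non-finite values")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative (magnitudes)")

    @property
    def peak_amplitude(self) -> float:
        return float(self.amplitude.max())

    def peak_index(self) -> tuple[int, int]:
        return np.unravel_index(int(np.argmax(self.amplitude)), self.amplitude.shape)


class LinearFit(NamedTuple):
    slope: float
    intercept: float
    r_squared: float


@dataclass
class BeamReport:
    """Summary metrics of one scan map."""

    focal_length_mm: float
    focus_size_minus6db_mm: float
    peak_amplitude: float
    distribution_correlation: float | None = None


def normalize_map(m: ScanMap) -> ScanMap:
    """Divide by the map maximum so the peak is exactly 1 (idempotent)."""
    peak = m.peak_amplitude
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero map")
    return replace(m, amplitude=m.amplitude / peak, normalized=True)


def minus6db_width(positions_mm: np.ndarray, amplitude: np.ndarray) -> float:
    """-6 dB (half-amplitude) full width of a 1-D beam profile, in mm.

    The width is that of the contiguous interval containing the peak where
    the amplitude is >= half the maximum; the two crossings are located by
    linear interpolation between neighbouring samples.

    Raises
    ------
    ProfileError
        If the profile never falls below half-maximum on one side (profile
        truncated) so a crossing cannot be bracketed.
    """
    pos = np.asarray(positions_mm, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    if pos.ndim != 1 or pos.shape != amp.shape or pos.size < 3:
        raise ValueError("profile needs matching 1-D arrays of length >= 3")
    half = amp.max() / 2.0
    ipk = int(np.argmax(amp))

    def cross(direction: int) -> float:
        i = ipk
        while 0 <= i + direction < pos.size and amp[i + direction] >= half:
            i += direction
        j = i + direction
        if j < 0 or j >= pos.size:
            raise ProfileError("profile truncated before reaching half-maximum")
        # linear interpolation between samples i (>= half) and j (< half)
        frac = (amp[i] - half) / (amp[i] - amp[j])
        return pos[i] + frac * (pos[j] - pos[i])

    return float(abs(cross(+1) - cross(-1)))


def focal_length(positions_mm: np.ndarray, amplitude: np.ndarray) -> float:
    """Axial position of the profile maximum (mm), parabolically refined.

    A three-point parabola through the peak sample and its neighbours
    relocates the vertex to sub-step accuracy.  A maximum on the profile
    boundary is an error: the scanned domain was too short to bracket it.
    """
    pos = np.asarray(positions_mm, dtype=float)
    amp = np.asarray(amplitude, dtype=float)
    if pos.ndim != 1 or pos.shape != amp.shape or pos.size < 3:
        raise ValueError("profile needs matching 1-D arrays of length >= 3")
    ipk = int(np.argmax(amp))
    if ipk in (0, pos.size - 1):
        raise ProfileError("profile maximum lies on the boundary; extend the scan")
    y0, y1, y2 = amp[ipk - 1], amp[ipk], amp[ipk + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # locally flat top: keep the sample position
        return float(pos[ipk])
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (pos[ipk + 1] - pos[ipk - 1])
    return float(pos[ipk] + delta * step)


def profile_through_peak(m: ScanMap, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D profile along grid axis ``axis`` (0 or 1) through the peak node."""
    i, j = m.peak_index()
    if axis == 0:
        return m.coords[0], m.amplitude[:, j]
    if axis == 1:
        return m.coords[1], m.amplitude[i, :]
    raise ValueError("axis must be 0 or 1")


def map_correlation(a: ScanMap, b: ScanMap) -> float:
    """Pearson correlation between two maps over matched grid nodes.

    Scale-free (invariant under affine rescaling of either map), so it can
    compare a simulated pressure map with a measured/derived map directly.
    """
    if a.amplitude.shape != b.amplitude.shape:
        raise ValueError("maps have different shapes")
    for ca, cb in zip(a.coords, b.coords):
        if ca.size != cb.size or not np.allclose(ca, cb):
            raise ValueError("maps are sampled on different grids")
    av, bv = a.amplitude.ravel(), b.amplitude.ravel()
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        raise ValueError("correlation undefined for a zero-variance map")
    return float(stats.pearsonr(av, bv).statistic)


def linearity_fit(pressures: np.ndarray, responses: np.ndarray) -> LinearFit:
    """Ordinary least-squares line of a response against drive pressure.

    Used for the induced-voltage / E-field versus pressure relation, which
    the Lorentz coupling predicts to be proportional (zero intercept).

    Returns slope, intercept and the coefficient of determination r^2.
    """
    p = np.asarray(pressures, dtype=float)
    r = np.asarray(responses, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError("pressures and responses must be matching 1-D arrays")
    if np.unique(p).size < 3:
        raise ValueError("need at least 3 distinct pressures")
    res = stats.linregress(p, r)
    return LinearFit(float(res.slope), float(res.intercept), float(res.rvalue**2))


def beam_report(
    m: ScanMap, *, axial_axis: int = 1, reference: ScanMap | None = None
) -> BeamReport:
    """Focal length, -6 dB width and peak of a map; optional agreement score.

    ``axial_axis`` identifies which grid axis of the map is the beam axis
    (1 for the x-y convention used by the simulation planes); the focal width
    is measured along the other (lateral) axis through the peak.
    """
    lateral_axis = 1 - axial_axis
    ax_pos, ax_amp = profile_through_peak(m, axial_axis)
    lat_pos, lat_amp = profile_through_peak(m, lateral_axis)
    corr = None if reference is None else map_correlation(m, reference)
    return BeamReport(
        focal_length_mm=focal_length(ax_pos, ax_amp),
        focus_size_minus6db_mm=minus6db_width(lat_pos, lat_amp),
        peak_amplitude=m.peak_amplitude,
        distribution_correlation=corr,
    )
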