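"""Seeded synthetic inputs emulating the study's measurements.

Three generators stand in for laboratory data so every analysis stage is
testable end-to-end:

* hydrophone/test-sample scan maps — a reference map resampled to a coarser
  scan step (2 mm in the emulated protocol) with multiplicative and additive
  Gaussian measurement noise;
* induced-voltage-versus-pressure series — a linear pickup (scalar
  sensitivity times the Lorentz E-field magnitude) plus Gaussian noise;
* fEPSP slope cohorts — per-animal series with a 30-min baseline, a
  post-TBS rise toward a group-specific LTP plateau (plateau plus a decaying
  overshoot), and a post-LFS exponential decay toward a depotentiated level,
  sampled once per minute, n = 6 animals per group by default.

Determinism contract: identical seed and parameters produce bit-identical
output.  A cohort seed fans out to per-animal substreams through
``numpy.random.SeedSequence(seed).spawn(n)``.

The default group plateaus (% of baseline) follow the published endpoint
levels of the three treatment arms — TMAS 343.9, TUS 154.8, control 74.4 —
so round-trip tests recover known targets.  Depotentiation levels are not
printed in the source study; the defaults preserve the reported group
ordering.  Noise is Gaussian and independent across samples (no
autocorrelation), so these series test parameter recovery, not realistic
trace statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .acoustic import Medium
from .beam import ScanMap
from .ephys import SlopeSeries
from .lorentz import BEAM_AXIS, StaticField

__all__ = [
    "ScanNoiseModel",
    "FepspGenParams",
    "GROUP_DEFAULTS",
    "gen_scan_map",
    "gen_voltage_series",
    "gen_fepsp_cohort",
    "default_cohort_params",
]

BASELINE_MIN = 30
PHASE_MIN = 90
TBS_TIME_MIN = 30.0
LFS_TIME_MIN = 120.0

#: Paper-style default endpoint plateaus (% of baseline) per treatment arm;
#: dp_level defaults keep the same ordering between arms.
GROUP_DEFAULTS: dict[str, dict[str, float]] = {
    "TMAS": {"plateau_ltp": 343.9, "dp_level": 180.0},
    "TUS": {"plateau_ltp": 154.8, "dp_level": 110.0},
    "Con": {"plateau_ltp": 74.4, "dp_level": 65.0},
}


@dataclass(frozen=True)
class ScanNoiseModel:
    """Measurement-noise model for emulated scan maps.

    relative_noise_sd is a fraction of the local amplitude; additive_noise_sd
    is in the map's amplitude units.
    """

    relative_noise_sd: float = 0.05
    additive_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_noise_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class FepspGenParams:
    """Generating parameters of one synthetic fEPSP cohort (one group).

    plateau_ltp, peak_overshoot, dp_level and noise_sd are in % of baseline;
    rise_time_constant in minutes (shared by the LTP rise and DP decay);
    baseline_level in raw slope units.
    """

    group: str
    plateau_ltp: float
    dp_level: float
    n_animals: int = 6
    baseline_level: float = 0.5
    peak_overshoot: float = 15.0
    rise_time_constant: float = 8.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.plateau_ltp <= 0 or self.dp_level <= 0:
            raise ValueError("plateau and DP levels must be > 0 (% of baseline)")
        if self.noise_sd < 0 or self.rise_time_constant <= 0:
            raise ValueError("noise_sd >= 0 and rise_time_constant > 0 required")


def gen_scan_map(reference: ScanMap, noise: ScanNoiseModel, step_mm: float) -> ScanMap:
    """Emulate a scanned measurement of a reference map.

    The reference is resampled to the coarser scan step by nearest-node
    selection, then each value is perturbed as
    ``v * (1 + N(0, rel)) + N(0, add)``; negative results clamp to zero
    (magnitudes).  Deterministic for a fixed seed.
    """
    c0, c1 = reference.coords
    ref_step = max(float(np.diff(c0).min()), float(np.diff(c1).min()))
    if step_mm < ref_step * (1 - 1e-9):
        raise ValueError(
            f"scan step {step_mm} mm finer than reference grid step {ref_step} mm"
        )

    def coarse(axis: np.ndarray) -> np.ndarray:
        n = int(np.floor((axis[-1] - axis[0]) / step_mm + 1e-9)) + 1
        return axis[0] + step_mm * np.arange(n)

    new0, new1 = coarse(c0), coarse(c1)
    i0 = np.abs(c0[None, :] - new0[:, None]).argmin(axis=1)
    i1 = np.abs(c1[None, :] - new1[:, None]).argmin(axis=1)
    sampled = reference.amplitude[np.ix_(i0, i1)]

    rng = np.random.default_rng(noise.seed)
    noisy = sampled * (
        1.0 + noise.relative_noise_sd * rng.standard_normal(sampled.shape)
    ) + noise.additive_noise_sd * rng.standard_normal(sampled.shape)
    return ScanMap(
        plane=reference.plane,
        coords=(new0, new1),
        coord_labels=reference.coord_labels,
        amplitude=np.clip(noisy, 0.0, None),
    )


def gen_voltage_series(
    pressures: np.ndarray,
    sensitivity: float,
    b: StaticField,
    medium: Medium,
    noise_sd: float,
    seed: int,
    propagation_axis=BEAM_AXIS,
) -> np.ndarray:
    """Synthetic test-sample voltages at a sweep of focal pressures.

    ``v_i = sensitivity * |E(P_i)| + N(0, noise_sd)`` with
    ``|E| = P * |axis x B0| / (rho cs)``; sensitivity in V per (V/m) models
    the short-wire pickup.  Deterministic per seed.
    """
    if sensitivity <= 0:
        raise ValueError("sensitivity must be > 0")
    p = np.asarray(pressures, dtype=float)
    e_per_pa = np.linalg.norm(np.cross(np.asarray(propagation_axis, float), b.vector))
    e_mag = p * e_per_pa / medium.impedance
    rng = np.random.default_rng(seed)
    return sensitivity * e_mag + rng.normal(0.0, noise_sd, size=p.shape) if noise_sd > 0 else sensitivity * e_mag


def _animal_series(params: FepspGenParams, animal_idx: int, rng: np.random.Generator) -> SlopeSeries:
    t = np.arange(1.0, BASELINE_MIN + 2 * PHASE_MIN + 1.0)  # 1..210 min
    target_pct = np.empty_like(t)

    base_mask = t <= TBS_TIME_MIN
    ltp_mask = (t > TBS_TIME_MIN) & (t <= LFS_TIME_MIN)
    dp_mask = t > LFS_TIME_MIN
    tau = params.rise_time_constant

    target_pct[base_mask] = 100.0
    tt = t[ltp_mask] - TBS_TIME_MIN
    target_pct[ltp_mask] = params.plateau_ltp + params.peak_overshoot * np.exp(-tt / tau)
    ltp_end = params.plateau_ltp + params.peak_overshoot * np.exp(-PHASE_MIN / tau)
    td = t[dp_mask] - LFS_TIME_MIN
    target_pct[dp_mask] = params.dp_level + (ltp_end - params.dp_level) * np.exp(-td / tau)

    noise = params.noise_sd * rng.standard_normal(t.shape)
    raw = params.baseline_level * (target_pct + noise) / 100.0
    return SlopeSeries(
        animal_id=f"{params.group}-{animal_idx + 1:02d}",
        group=params.group,
        time_min=t,
        slope=raw,
        tbs_time_min=TBS_TIME_MIN,
        lfs_time_min=LFS_TIME_MIN,
    )


def gen_fepsp_cohort(params: FepspGenParams | Sequence[FepspGenParams]) -> list[SlopeSeries]:
    """Generate per-animal fEPSP slope series for one or several groups.

    Each cohort seed is split into per-animal substreams with
    ``SeedSequence(seed).spawn(n_animals)``, so cohorts are reproducible and
    animals statistically independent.
    """
    if isinstance(params, FepspGenParams):
        params = [params]
    out: list[SlopeSeries] = []
    for p in params:
        streams = np.random.SeedSequence(p.seed).spawn(p.n_animals)
        for i, ss in enumerate(streams):
            out.append(_animal_series(p, i, np.random.default_rng(ss)))
    return out


def default_cohort_params(seed: int, noise_sd: float = 5.0) -> list[FepspGenParams]:
    """One :class:`FepspGenParams` per treatment arm with default plateaus.

    Per-group seeds are spawned from ``seed`` so arms are independent.
    """
    children = np.random.SeedSequence(seed).spawn(len(GROUP_DEFAULTS))
    return [
        FepspGenParams(
            group=g,
            plateau_ltp=d["plateau_ltp"],
            dp_level=d["dp_level"],
            noise_sd=noise_sd,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        for (g, d), child in zip(GROUP_DEFAULTS.items(), children)
    ]
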