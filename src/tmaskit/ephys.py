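"""Quantification of LTP and depotentiation from fEPSP slope time series.

The experimental timeline this pipeline assumes (times in minutes, one
sample every 60 s):

* 30 min of baseline recording,
* theta-burst stimulation (TBS) inducing long-term potentiation (LTP),
  followed by 90 min of recording,
* low-frequency stimulation (LFS) inducing depotentiation (DP), followed by
  another 90 min of recording.

Each animal's series is normalized to the mean of its own baseline window
(so the baseline mean is 100%), and each phase is quantified by (a) the
final sample of the 90-min window and (b) the mean of its last 10 samples
(10 min).  Group summaries are mean +/- SEM; group contrasts use Welch's
unequal-variance two-sample t-test, two-sided — appropriate for small
cohorts with no evidence of equal variances.  No multiplicity correction is
applied; pairwise p-values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StimProtocolDescriptor",
    "TBS_PROTOCOL",
    "LFS_PROTOCOL",
    "SlopeSeries",
    "PhaseQuantification",
    "GroupQuantification",
    "normalize_to_baseline",
    "quantify_phase",
    "group_summary",
    "compare_groups",
    "quantify_cohort",
    "read_slope_csv",
    "write_slope_csv",
]

PHASE_DURATION_MIN = 90.0
QUANT_WINDOW_SAMPLES = 10  # last 10 min at one sample per minute


@dataclass(frozen=True)
class StimProtocolDescriptor:
    """Metadata describing an induction protocol (no waveform synthesis)."""

    kind: str  # "TBS" | "LFS"
    trains: int
    pulses_per_train: int
    intra_train_rate_hz: float
    inter_train_interval_s: float
    duration_s: float

    @property
    def total_pulses(self) -> int:
        return self.trains * self.pulses_per_train

    def __post_init__(self) -> None:
        if self.kind not in ("TBS", "LFS"):
            raise ValueError("kind must be 'TBS' or 'LFS'")
        if min(self.trains, self.pulses_per_train) < 1:
            raise ValueError("trains and pulses_per_train must be >= 1")


# theta burst: 30 trains of 6 pulses at 100 Hz, 200 ms between trains
TBS_PROTOCOL = StimProtocolDescriptor("TBS", 30, 6, 100.0, 0.2, 6.0)
# low-frequency: 900 pulses at 1 Hz over 15 min
LFS_PROTOCOL = StimProtocolDescriptor("LFS", 1, 900, 1.0, 0.0, 900.0)


@dataclass
class SlopeSeries:
    """Per-animal fEPSP slope time series with protocol markers.

    ``time_min`` must be strictly increasing at 1-minute spacing; slopes are
    magnitudes (positive).  ``tbs_time_min`` and ``lfs_time_min`` mark the
    induction times; the baseline window is every sample at or before the
    TBS marker.
    """

    animal_id: str
    group: str
    time_min: np.ndarray
    slope: np.ndarray
    tbs_time_min: float = 30.0
    lfs_time_min: float = 120.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if self.time_min.shape != self.slope.shape or self.time_min.ndim != 1:
            raise ValueError("time and slope must be matching 1-D arrays")
        if self.time_min.size > 1 and not np.allclose(np.diff(self.time_min), 1.0):
            raise ValueError("samples must be 1 minute apart (once every 60 s)")
        if not self.tbs_time_min < self.lfs_time_min:
            raise ValueError("markers must be ordered: TBS before LFS")
        if not np.any(self.time_min <= self.tbs_time_min):
            raise ValueError("baseline window (time <= TBS) contains no samples")

    def baseline_mask(self) -> np.ndarray:
        return self.time_min <= self.tbs_time_min

    def phase_mask(self, phase: str) -> np.ndarray:
        start = {"LTP": self.tbs_time_min, "DP": self.lfs_time_min}.get(phase)
        if start is None:
            raise ValueError("phase must be 'LTP' or 'DP'")
        return (self.time_min > start) & (self.time_min <= start + PHASE_DURATION_MIN)


class PhaseQuantification(NamedTuple):
    endpoint_pct: float
    window_mean_pct: float


@dataclass(frozen=True)
class GroupQuantification:
    """Group-level summary: mean +/- SEM of a per-animal quantity (%)."""

    group: str
    n: int
    mean_pct: float
    sem_pct: float  # NaN when n == 1


def normalize_to_baseline(s: SlopeSeries) -> SlopeSeries:
    """Express slopes as percent of the baseline-window mean.

    The output's baseline mean is 100 by construction.
    """
    base = s.slope[s.baseline_mask()]
    m = base.mean()
    if m <= 0:
        raise ValueError("baseline mean must be positive to normalize")
    return replace(s, slope=s.slope * (100.0 / m), normalized=True)


def quantify_phase(s: SlopeSeries, phase: str) -> PhaseQuantification:
    """Endpoint and last-10-min mean of a normalized series' phase window.

    ``phase`` is "LTP" (window (TBS, TBS+90] min) or "DP" ((LFS, LFS+90]).
    The endpoint is the final sample of the window; the window mean averages
    its last 10 samples.
    """
    if not s.normalized:
        raise ValueError("series must be normalized to baseline first")
    vals = s.slope[s.phase_mask(phase)]
    if vals.size < QUANT_WINDOW_SAMPLES:
        raise ValueError(
            f"{phase} window has {vals.size} samples; need >= {QUANT_WINDOW_SAMPLES}"
        )
    return PhaseQuantification(
        endpoint_pct=float(vals[-1]),
        window_mean_pct=float(vals[-QUANT_WINDOW_SAMPLES:].mean()),
    )


def group_summary(values: Sequence[float], group: str) -> GroupQuantification:
    """Mean and SEM (sample sd / sqrt(n)) of per-animal values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty group")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return GroupQuantification(group=group, n=int(v.size), mean_pct=float(v.mean()), sem_pct=sem)


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Welch unequal-variance two-sample t-test, two-sided.

    Returns (statistic, p_value).  The degenerate case of two zero-variance
    groups is resolved analytically: p = 1 for equal means, p = 0 otherwise.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs n >= 2")
    if av.var(ddof=1) == 0 and bv.var(ddof=1) == 0:
        equal = av.mean() == bv.mean()
        return (0.0, 1.0) if equal else (float("inf"), 0.0)
    res = stats.ttest_ind(av, bv, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def quantify_cohort(
    series: Iterable[SlopeSeries], phase: str, *, use_window_mean: bool = False
) -> tuple[pd.DataFrame, dict[str, GroupQuantification]]:
    """Normalize and quantify a cohort; summarize per group.

    Returns a tidy per-animal table (animal_id, group, endpoint_pct,
    window_mean_pct) and a dict of group summaries of the endpoint (or of
    the last-10-min window mean when ``use_window_mean``).
    """
    rows = []
    for s in series:
        q = quantify_phase(s if s.normalized else normalize_to_baseline(s), phase)
        rows.append(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "endpoint_pct": q.endpoint_pct,
                "window_mean_pct": q.window_mean_pct,
            }
        )
    table = pd.DataFrame(rows)
    col = "window_mean_pct" if use_window_mean else "endpoint_pct"
    summaries = {
        g: group_summary(sub[col].to_numpy(), g) for g, sub in table.groupby("group")
    }
    return table, summaries


def read_slope_csv(
    path, *, tbs_time_min: float = 30.0, lfs_time_min: float = 120.0, flip_sign: bool = False
) -> list[SlopeSeries]:
    """Read per-animal series from a tidy CSV (animal_id, group, time_min, slope).

    ``flip_sign`` accommodates negative-going slope conventions by negating
    raw slopes on read.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "group", "time_min", "slope"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must contain columns {sorted(required)}")
    out = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("time_min")
        slope = sub["slope"].to_numpy(dtype=float)
        if flip_sign:
            slope = -slope
        out.append(
            SlopeSeries(
                animal_id=str(animal),
                group=str(group),
                time_min=sub["time_min"].to_numpy(dtype=float),
                slope=slope,
                tbs_time_min=tbs_time_min,
                lfs_time_min=lfs_time_min,
            )
        )
    return out


def write_slope_csv(series: Iterable[SlopeSeries], path) -> None:
    """Write series as a tidy CSV readable by :func:`read_slope_csv`."""
    frames = [
        pd.DataFrame(
            {
                "animal_id": s.animal_id,
                "group": s.group,
                "time_min": s.time_min,
                "slope": s.slope,
            }
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
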