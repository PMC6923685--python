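"""Acoustic-output dosimetry of a pulsed tone-burst stimulation protocol.

All metrics derive from four protocol numbers — carrier frequency, pulse
duration (PD), pulse repetition frequency (PRF) and the focal (intracranial)
peak pressure — under the plane-wave intensity relation I = P^2 / (2 rho cs):

* duty cycle        = PD * PRF
* I_sppa            = P^2 / (2 rho cs)              (spatial-peak pulse-average)
* I_spta            = I_sppa * duty cycle           (spatial-peak temporal-average)
* mechanical index  = P_neg[MPa] / sqrt(f[MHz])     (peak-negative == peak assumed)

The reference protocol of this package (1 MHz carrier, 200 us pulses at
1 Hz, 3 MPa intracranial peak) gives a duty cycle of 2e-4 and
I_spta ~ 62 mW/cm^2 — a deliberately low-duty, low-average-intensity
neurostimulation regime.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

from .acoustic import ConfigurationError, Medium

__all__ = [
    "PulseProtocol",
    "DosimetryReport",
    "ProtocolError",
    "duty_cycle",
    "i_sppa",
    "i_spta",
    "pulse_count",
    "mechanical_index",
    "dosimetry_report",
]

W_PER_M2_TO_W_PER_CM2 = 1e-4


class ProtocolError(ValueError):
    """Physically inconsistent pulse protocol."""


@dataclass(frozen=True)
class PulseProtocol:
    """Pulsed tone-burst stimulus descriptor (strict SI units).

    carrier_frequency Hz, pulse_duration s, pulse_repetition_frequency Hz,
    session_duration s, focal_pressure Pa (peak, at the target).
    """

    carrier_frequency: float
    pulse_duration: float
    pulse_repetition_frequency: float
    session_duration: float
    focal_pressure: float

    def __post_init__(self) -> None:
        if min(
            self.carrier_frequency,
            self.pulse_duration,
            self.pulse_repetition_frequency,
            self.session_duration,
            self.focal_pressure,
        ) <= 0:
            raise ProtocolError("all protocol fields must be > 0")
        if self.pulse_duration * self.pulse_repetition_frequency > 1 + 1e-12:
            raise ProtocolError("PD * PRF exceeds 1: pulses overlap")
        if self.carrier_frequency * self.pulse_duration < 1:
            raise ProtocolError("pulse shorter than one carrier cycle")

    @property
    def cycles_per_pulse(self) -> float:
        return self.carrier_frequency * self.pulse_duration


@dataclass(frozen=True)
class DosimetryReport:
    duty_cycle: float
    i_sppa_w_cm2: float
    i_spta_mw_cm2: float
    pulse_count: int
    cycles_per_pulse: float
    mechanical_index: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def duty_cycle(p: PulseProtocol) -> float:
    """Fraction of time the carrier is on: PD * PRF, in (0, 1]."""
    return p.pulse_duration * p.pulse_repetition_frequency


def i_sppa(p: PulseProtocol, medium: Medium) -> float:
    """Spatial-peak pulse-average intensity P^2/(2 rho cs), W/cm^2."""
    return p.focal_pressure**2 / (2.0 * medium.impedance) * W_PER_M2_TO_W_PER_CM2


def i_spta(p: PulseProtocol, medium: Medium) -> float:
    """Spatial-peak temporal-average intensity I_sppa * duty cycle, mW/cm^2."""
    return i_sppa(p, medium) * duty_cycle(p) * 1e3


def pulse_count(p: PulseProtocol) -> int:
    """Whole pulses delivered in a session: floor(duration * PRF)."""
    return math.floor(p.session_duration * p.pulse_repetition_frequency + 1e-9)


def mechanical_index(p: PulseProtocol) -> float:
    """MI = peak-negative pressure (MPa) / sqrt(frequency (MHz)).

    Assumes a linear, symmetric waveform so the peak-negative pressure
    equals the peak pressure.
    """
    p_mpa = p.focal_pressure * 1e-6
    f_mhz = p.carrier_frequency * 1e-6
    return p_mpa / math.sqrt(f_mhz)


def dosimetry_report(p: PulseProtocol, medium: Medium) -> DosimetryReport:
    """All output metrics of a protocol in one record."""
    return DosimetryReport(
        duty_cycle=duty_cycle(p),
        i_sppa_w_cm2=i_sppa(p, medium),
        i_spta_mw_cm2=i_spta(p, medium),
        pulse_count=pulse_count(p),
        cycles_per_pulse=p.cycles_per_pulse,
        mechanical_index=mechanical_index(p),
    )
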