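"""Dosimetry of the pulsed stimulation protocol.

200 us tone bursts of a 1 MHz carrier at 1 Hz repetition for 2 min, with a
3 MPa intracranial focal pressure: a very low duty-cycle regime.
"""

import tmaskit as tk

medium = tk.Medium()
protocol = tk.PulseProtocol(
    carrier_frequency=1e6,
    pulse_duration=200e-6,
    pulse_repetition_frequency=1.0,
    session_duration=120.0,
    focal_pressure=3e6,
)

report = tk.dosimetry_report(protocol, medium)
print(report.to_json())
# duty cycle 2e-4 means the carrier is on 0.02% of the time: the pulse-average
# intensity (~310 W/cm^2) collapses to a temporal average of ~62 mW/cm^2,
# and MI = 3.0 quantifies the cavitation safety margin of the 3 MPa peak.
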