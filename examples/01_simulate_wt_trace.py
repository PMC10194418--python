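"""Simulate wild-type hERG current under an AP clamp at two temperatures.

Builds the standard ventricular AP command (hold −80 mV, peak +40 mV,
APD90 ≈ 300 ms), simulates the whole-cell current at 37°C and at 27°C, and
prints the repolarization power (time integral of the current, pA·s) and the
time of the current peak.  Cooling slows the gating, so less current
develops within the same AP and the integral drops sharply.
"""

from hergpower import (
    APShapeParams,
    build_ap_waveform,
    default_wt_model,
    repolarization_power,
    scale_for_temperature,
    simulate_current,
    time_of_peak,
)

protocol = build_ap_waveform(APShapeParams())
model = default_wt_model()

for temp in (37.0, 27.0):
    trace = simulate_current(scale_for_temperature(model, temp), protocol)
    rp = repolarization_power(trace)
    print(
        f"{temp:g}°C: repolarization power = {rp.value:6.2f} pA·s, "
        f"peak {trace.current.max():6.1f} pA at t = {time_of_peak(trace):.0f} ms"
    )

print(
    "\nThe AP spans 100-400 ms of the sweep; the late peak is the hERG surge "
    "during repolarization.\nCooling by 10°C costs most of the integral — "
    "the deficit the time-dilation protocol compensates."
)
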