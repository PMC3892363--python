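"""From a raw chamber closure trace to a CO2 flux.

Synthesises one noisy 1 Hz closure trace encoding a known respiration flux,
fits the linear concentration rise after the opaque-chamber dead band (50 s,
then a 90 s window), and converts the slope to an areal flux with the
ideal-gas head-space equation F = slope * P V / (R T A).
"""

import numpy as np

from mesoflux import SimConfig, fit_record, synthesize_trace

config = SimConfig()
rng = np.random.default_rng(7)
true_flux = 1.25  # umol CO2 m-2 s-1, positive = release

trace = synthesize_trace(true_flux, config, "opaque", rng, temperature_c=6.0)
record = fit_record(trace)

print(f"true flux        : {true_flux:.3f} umol m-2 s-1")
print(f"fitted slope     : {record.slope:.5f} ppm s-1 "
      f"(r2 = {record.r2:.3f}, SE = {record.slope_se:.5f})")
print(f"recovered flux   : {record.flux:.3f} umol m-2 s-1")
print(f"dead band/window : {record.deadband_s:.0f} s / {record.window_s:.0f} s")

# The recovered flux sits within a few slope-standard-errors of the truth;
# with trace noise switched off the recovery is exact to machine precision.
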