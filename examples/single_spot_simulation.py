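"""Simulate one 35 mW / 2 s laser spot on a 500 um colon-wall slab.

Runs the default thin-slab configuration (Gaussian surface flux, insulated
boundaries, Pennes perfusion) and prints the space-time peak plus the four
standard surface probe points a-d at 0/100/150/200 um from the spot centre.
"""

from enafl import (LaserSource, SimGrid, ThermalProperties, TissueGeometry,
                   peak_summary, probe_traces, simulate, trace_metrics)

props = ThermalProperties()
geometry = TissueGeometry()          # 5 mm radius, 500 um thick
source = LaserSource()               # 35 mW, 200 um beam, 2 s on
history = simulate(props, geometry, source, SimGrid.build(geometry))

peak = peak_summary(history)
print(f"peak temperature : {peak.temperature:7.1f} C")
print(f"peak time        : {peak.time:7.2f} s (end of the 2 s irradiation)")
print(f"peak location    : r = {peak.location[0] * 1e6:.0f} um, "
      f"z = {peak.location[1] * 1e6:.0f} um (axis, surface)")
print()
print("surface probes (distance from spot centre):")
for trace in probe_traces(history):
    m = trace_metrics(trace)
    print(f"  point {trace.label}: peak rise {m.delta_peak:6.1f} C, "
          f"reached at t = {m.time_to_peak:.2f} s")
print()
print("The rise decreases monotonically away from the beam axis and decays")
print("after the laser switches off at t = 2 s.  Note the magnitude: a full")
print("35 mW absorbed at the surface of a 33 um-sigma spot drives the axis")
print("far above coagulation temperatures (see docs/methods.md on how this")
print("compares with reference values computed at coarser resolution).")
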