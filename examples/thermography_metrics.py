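"""Analyse a synthetic infrared thermography recording.

Generates a frame stack with a ~20 C Gaussian hot spot (2 s linear rise,
exponential cooling, sensor noise), recovers peak rise / time-to-peak /
return-to-baseline, and ranks four irradiation sites by their peak rise.
"""

from enafl import (ThermalFrameParams, gen_thermal_frames, peak_summary,
                   rank_peak_by_site, trace_metrics)

stack, truth = gen_thermal_frames(ThermalFrameParams(seed=0))
peak = peak_summary(stack)
trace = stack.pixel_trace(*peak.location, label="hot spot")
m = trace_metrics(trace)
print(f"single-site recording ({stack.frames.shape[0]} frames at "
      f"{1 / (stack.times[1] - stack.times[0]):.0f} Hz):")
print(f"  peak rise        : {m.delta_peak:5.1f} C  (truth: "
      f"{truth['sites']['spot']['amplitude']:.1f} C)")
print(f"  time to peak     : {m.time_to_peak:5.1f} s  (laser off at "
      f"{truth['peak_time']:.1f} s)")
print(f"  back to baseline : {m.return_time:5.1f} s "
      f"(within 1 C of {truth['baseline']:.0f} C)")
print()

sites = {"ear": 24.0, "dorsal_skin": 18.0, "external_colon": 12.0,
         "internal_colon": 6.0}
stack4, truth4 = gen_thermal_frames(
    ThermalFrameParams(shape=(96, 96), sites=sites, seed=1))
traces = [stack4.pixel_trace(int(t["centre"][0]), int(t["centre"][1]),
                             label=lab, baseline=truth4["baseline"])
          for lab, t in truth4["sites"].items()]
print("four sites ranked by peak rise:", " > ".join(rank_peak_by_site(traces)))
print("The ranking reflects how strongly each tissue absorbs the 1927 nm")
print("beam; the generator's decreasing amplitudes are recovered despite")
print("sensor noise.")
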