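"""Detect capture events on synthetic chromosome trajectories.

Generates labeled two-phase trajectories for a control cohort (slow
F-actin-driven approach, then fast dynein transport at 9.22 +/- 2.86
µm/min from a switch time drawn at 9.21 +/- 2.36 min), runs the
capture-event detector, and compares against the generator's ground
truth. The detector should localize events to within about one 3-s frame
and recover the transport speed.
"""

import numpy as np

from congression import SyntheticSpec, analyze_trajectories, make_geometry, make_trajectories

spec = SyntheticSpec.control(seed=42, n_oocytes=4)
trajectories, truth = make_trajectories(spec)
ap = make_geometry().ap_point

events = analyze_trajectories(trajectories, ap)
merged = events.merge(truth, on=["oocyte", "chromosome"])
detected = merged[merged.detected]

err_s = (detected.capture_time_min - detected.switch_time_min) * 60.0
print(f"tracks: {len(merged)}, events detected: {len(detected)}")
print(f"median |event-time error|: {err_s.abs().median():.1f} s (frame interval 3 s)")
print(f"mean post-event speed: {detected.post_speed_um_min.mean():.2f} um/min "
      f"(generator mean 9.22)")
print(f"mean pre-event speed:  {detected.pre_speed_um_min.mean():.2f} um/min "
      f"(slow F-actin-driven phase)")
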