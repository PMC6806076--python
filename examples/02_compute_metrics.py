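"""Compute skiing-specific metrics from a pose sequence.

The pipeline detects the turn-outside leg from COM-to-ankle proximity,
builds ski-relative coordinate frames, and derives knee/hip flexion, the
relative center of mass, d_vertical (ankle-COM distance), the fore/aft
sine, the lean angle and Barelle's drag area, frame by frame.
"""

import numpy as np

from skimocap import compute_metrics, generate_reference_run

seq, _, _ = generate_reference_run(seed=2)
series, cycles = compute_metrics(seq)

print(f"detected turn switches at frames {list(cycles.switch_frames)}")
mid = len(seq) // 2  # a frame near a turn apex
side = series["knee_outside"].side_labels[mid]
print(f"\nframe {mid} (outside leg: {side}):")
for name in ("knee_outside", "knee_inside", "hip_outside", "hip_inside",
             "d_vertical", "fore_aft", "lean_angle", "cda"):
    s = series[name]
    print(f"  {name:13s} {float(s.values[mid]):8.3f} {s.units}")

com = series["com_rel"].values[mid]
print(f"  com_rel       [{com[0]: .3f} {com[1]: .3f} {com[2]: .3f}] m (relative to mid-hip)")

print("\ninterpretation: 180 deg = fully extended joint; fore_aft > 0 means the")
print("COM rides ahead of the outside ankle toward the ski tip; the lean angle")
print("is the COM inclination from the local up axis in the frontal plane.")
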