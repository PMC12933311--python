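"""Simulate a paired IVUS/OCT pullback with known ground truth.

Builds a 40 mm phantom vessel, samples both acquisitions, and prints the
layout: frame counts, the anatomical events (side branches, calcium
deposits) and the OCT rotational drift.
"""

import numpy as np

from ivoctreg import PhantomConfig, simulate

cfg = PhantomConfig(seed=42)
ivus, oct_pb, gt = simulate(cfg)

print(f"vessel length          {cfg.length_mm:.1f} mm")
print(f"IVUS frames (ED)       {len(ivus)} at {cfg.ivus_frame_spacing_mm} mm")
print(f"OCT frames             {len(oct_pb)} at {cfg.oct_frame_spacing_mm} mm")
for ev in gt.branches:
    print(f"side branch            s = {ev.s_start:.1f}-{ev.s_end:.1f} mm "
          f"at {ev.angle_deg:.0f} deg, width {ev.width_deg:.0f} deg")
for ev in gt.calcium:
    print(f"calcium deposit        s = {ev.s_start:.1f}-{ev.s_end:.1f} mm, "
          f"arc {ev.arc_deg:.0f} deg")
print(f"OCT rotation           starts at {gt.oct_rotation_deg[0]:.1f} deg, "
      f"drifts over {np.ptp(gt.oct_rotation_deg):.1f} deg")

# Each IVUS frame's true partner on the 0.2 mm OCT grid:
from ivoctreg import true_correspondence

idx, rot = true_correspondence(gt)
print(f"IVUS frame 10 truly corresponds to OCT frame {idx[10]:.1f} "
      f"with rotation {rot[10]:.1f} deg")
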