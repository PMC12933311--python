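"""Co-register a simulated pullback pair and score it against ground truth.

Runs the full pipeline (feature signals -> DTW -> rotational DP) and prints
the longitudinal and angular errors; with the default moderate-noise
phantom both should sit well inside expert-level variability (a few OCT
frames / a few degrees).
"""

import numpy as np

from ivoctreg import PhantomConfig, RunConfig, coregister, simulate, true_correspondence
from ivoctreg.angles import circular_abs_diff_deg

ivus, oct_pb, gt = simulate(PhantomConfig(seed=7))
result = coregister(ivus, oct_pb, RunConfig())

true_idx, true_rot = true_correspondence(gt)
long_err = np.abs(result.oct_frame_continuous - true_idx[result.ivus_frames])
rot_err = circular_abs_diff_deg(result.rotation_deg, true_rot[result.ivus_frames])

print(f"analysis pairs          {len(result)}")
print(f"landmark pairs          {int(result.is_landmark.sum())}")
print(f"DTW path cost           {result.path.total_cost:.3f}")
print(f"median |frame error|    {np.median(long_err):.2f} OCT frames "
      f"({np.median(long_err) * 0.2:.2f} mm)")
print(f"median |angle error|    {np.median(rot_err):.1f} deg")
print(f"worst angle error       {rot_err.max():.1f} deg")
print("stage timings           " +
      ", ".join(f"{k} {v * 1e3:.0f} ms" for k, v in result.stage_seconds.items()))
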