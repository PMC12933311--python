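# ivoctreg

Automated longitudinal and circumferential co-registration of paired
intravascular ultrasound (IVUS) and optical coherence tomography (OCT)
coronary pullbacks, working from per-frame geometric annotations — lumen
contours, side-branch bounding boxes and per-angle calcium labels — rather
than raw images.

## The problem

Studies of coronary atherosclerosis increasingly image the same vessel with
both IVUS and OCT, whose strengths are complementary. Fusing the two
pullbacks requires knowing, for every IVUS cross-section, which OCT frame
shows the same vessel site (longitudinal registration) and by how many
degrees the OCT frame must be rotated to the IVUS orientation
(circumferential registration). Done by hand this takes an expert several
minutes per vessel; `ivoctreg` automates both steps for anyone analysing
multimodality pullback datasets.

## Method

**Longitudinal.** Four features are extracted per frame of each pullback:
lumen area and total side-branch area (both normalized by the vessel's
maximum lumen area), the fraction of the circumference labelled calcified,
and normalized frame position. The geometric channels are Gaussian-smoothed
along the pullback, the sequences are down-sampled (IVUS to its
end-diastolic frames, spaced about 0.5 mm; OCT to every second 0.2 mm frame,
i.e. a 0.4 mm analysis grid), and dynamic time warping over the
feature-weighted Euclidean distance matrix

&nbsp;&nbsp;&nbsp;&nbsp;*d(u, v) = sqrt( Σₖ wₖ (uₖ − vₖ)² )*

yields the optimal monotone frame correspondence, which is expanded to a
continuous OCT frame index per IVUS frame.

**Circumferential.** At landmark pairs — matched frames where both
modalities show a side branch or calcium — three circular signals are
sampled in 2° steps around the lumen centroid: centroid-to-border radius,
branch mass and calcium presence. Each candidate rotation *2k°* scores the
weighted mean of per-channel normalized cross-correlations; stacking
*cost = 1 − NCC* rows over landmark pairs gives a rotation cost matrix, and
a dynamic program with a quadratic shape-regularization penalty
*λ (Δθ/360)²* on the rotation change between consecutive landmarks (capped
at a maximum step) finds the lowest-cost rotation path. Rotations are
circularly interpolated to the remaining frames.

**Evaluation.** An agreement suite — median (IQR) frame/angle differences,
Lin's concordance correlation coefficient, Spearman r, Bland–Altman limits,
the Williams Index with jackknife 95% CI, Wilcoxon signed-rank tests — and
a phantom simulator that generates annotation pairs from an analytic vessel
with known true correspondence and known per-frame OCT rotational drift.

## Worked example

```sh
python examples/02_coregister_phantom.py
```

```
analysis pairs          81
landmark pairs          23
DTW path cost           1.050
median |frame error|    0.60 OCT frames (0.12 mm)
median |angle error|    1.3 deg
worst angle error       7.0 deg
```

A 40 mm phantom vessel with moderate annotation noise (0.05 mm contour
noise, 1°/frame rotational drift, 10% feature dropout) is simulated and
co-registered: 81 IVUS end-diastolic frames each receive a continuous OCT
frame index and a rotation. The median longitudinal error of 0.6 OCT frames
is 0.12 mm — below the 0.4 mm analysis grid — and the median rotation error
of 1.3° is below the 2° angular quantization, both well inside the
several-frame / ~10° spread typical of expert analysts. The other examples
simulate a phantom (`01`) and run the observer-agreement suite against two
synthetic experts (`03`).

The same pipeline is available as a CLI:

```sh
ivoctreg demo --out demo_out --seed 3
ivoctreg coregister ivus.json oct.json --out alignment.csv
ivoctreg evaluate alignment.csv ground_truth.csv
```

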