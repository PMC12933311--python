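# Methods

## Setting and inputs

`ivoctreg` registers two pullbacks of the same coronary segment acquired by
IVUS (slow pullback, ~0.5 mm/s, end-diastolic gating leaves analysis frames
about 0.5 mm apart) and OCT (fast pullback, 36 mm/s at 180 frames/s, hence
0.2 mm between frames; every second frame is analysed, a 0.4 mm grid). The
unit of input is an annotated frame: a closed lumen contour in
catheter-centered mm coordinates, zero or more side-branch bounding boxes,
and a 180-bin calcium arc (one binary flag per 2° of circumference around
the lumen centroid, bin *b* covering [2b°, 2b°+2°) counter-clockwise from
+x). Image segmentation itself is out of scope: annotations may come from
human readers or any upstream feature extractor.

## Geometric primitives

Contour area and centroid use the shoelace formulas. The radial profile
casts a ray from the centroid along each 2° bin-center direction *(2b+1)°*
and takes the first polygon-edge intersection; lumens are near-convex, so
the ray cast is exact, and a nearest-vertex fallback (with a warning)
covers contours that are not star-shaped about their centroid. Eccentricity
is defined as (max − min)/max of the radial profile: 0 for a circle,
scale-invariant, and monotone in how elliptical the section is. Degree of
calcification is the fraction of set bins; branch area is the summed box
area (overlaps not de-duplicated — in practice boxes mark distinct ostia).

## Longitudinal matching

Per frame, four features: lumen area and branch area normalized by the
vessel's maximum lumen area, calcium fraction, and normalized position
i/(N−1). The three geometric channels are smoothed with a Gaussian kernel
(default σ = 2 frames, truncated at ±4σ and renormalized, reflect padding)
so that a feature missed on one frame still leaves signal nearby; the
position channel is never smoothed, as it must stay strictly monotone.
Smoothing precedes down-sampling (IVUS keeps ED frames; OCT keeps indices
0, 2, 4, …), and the position channel is recomputed over the retained
frames so both modalities express relative progress through the segment.

DTW uses the classic three-direction unit-weight step pattern with both
endpoints constrained, accumulating the feature-weighted Euclidean
distances (default weights 1,1,1,1; an optional Sakoe–Chiba band is
exposed but off by default — sequences of ~100 frames need no pruning).
Backtracking prefers the diagonal predecessor, then (i−1, j), making the
path deterministic. The raw path may assign several OCT frames to one IVUS
frame; the functional map averages each IVUS frame's matched OCT original
indices, giving one continuous OCT index per IVUS analysis frame —
mirroring how interpolation between manually matched sections assigns an
OCT frame to every IVUS cross-section.

## Circumferential registration

Rotation is estimated only where it is identifiable: landmark pairs in
which the IVUS frame **and** its matched OCT frame each show a branch or
calcium (requiring the feature in both modalities avoids estimating from
one-sided evidence; the "either" rule is available in config). If no pair
qualifies, the single most eccentric pair is used — an elliptical lumen
still pins rotation up to the cos 2θ ambiguity, which branch/calcium
channels normally resolve.

For each landmark pair, the three circular channels of the OCT frame are
circularly shifted through all 180 candidate rotations; each shift scores
the weighted mean (default weights 1,1,1) of per-channel Pearson NCC, with
constant channels contributing 0 (uninformative), and cost 1 − score ∈
[0, 2]. The DP over the resulting T×180 matrix adds a quadratic penalty
λ·(Δθ/360)² per consecutive-landmark rotation change, with steps capped at
`max_step_deg`; ties prefer the smaller step, then the smaller rotation
index. Defaults λ = 25 and max step 30°: the penalty at the cap
(25·(30/360)² ≈ 0.17) is comparable to a meaningful NCC difference, so
smoothness competes with, but cannot overrule, strong landmark evidence.
Rotations at non-landmark pairs are linearly interpolated along the
shorter arc, constant-extended at the ends, yielding values in [0, 360);
rotation means "rotate the OCT frame CCW by this angle to match IVUS".

The two stages are deliberately sequential, not joint: a longitudinal
mis-pairing can propagate into the rotation stage. The smoothed feature
signals and the both-modality landmark rule bound this in practice.

## Phantom simulator

The generator emulates the annotation tables, not images. The ground-truth
vessel is r(s, θ) = R₀ (1 − taper·s/L)(1 + e(s) cos 2θ) with a smooth
eccentricity modulation e(s) ∈ [0.35, 1]·e_max (lumens are never perfectly
circular; the floor keeps the radial channel informative). Branches
(0.8 mm ostia) and calcium deposits (2–5 mm, 30–90° arcs) are placed
uniformly at random without arc-length overlap. IVUS samples ED frames
every 0.5 mm with optional residual cardiac jitter (sorted to stay
monotone); OCT samples every 0.2 mm with a Gaussian random-walk rotational
drift φ_j from a uniform start, all angular annotations rotated
accordingly. Contour vertices (96 per frame, on a per-frame randomly
dithered angular grid, as delineated contours share no grid) get additive
radial noise; each branch/calcium annotation can drop out per frame,
emulating extraction misses; a small random catheter offset decenters each
contour.

Defaults are the moderate-noise study condition: 40 mm vessel, 4 branches,
3 calcium deposits, 0.05 mm contour noise, 1°/frame drift, 10% dropout,
0.05 mm jitter. What the phantom does **not** model: image artifacts and
segmentation failure modes that correlate across frames, non-monotone raw
catheter motion (jitter is applied post-gating), culprit-lesion morphology
(ruptures, thrombus), and any real inter-modality lumen-size bias — so
passing recovery tests demonstrates the registration machinery, not
robustness to everything clinical data can contain.

## Agreement suite

Frame differences are plain absolute differences (×0.2 mm/frame); angular
differences are circular, in [0, 180°]. Lin's CCC uses population (1/n)
moments, the original definition; Bland–Altman limits use the sample SD
convention (±1.96·s). Spearman and Wilcoxon wrap scipy (exact signed-rank
enumeration for n ≤ 25, normal approximation with continuity correction
beyond). The Williams Index uses mean absolute difference as the
disagreement kernel — WI = ½(1/D(M,E1) + 1/D(M,E2))·D(E1,E2) — with a
delete-one jackknife 95% CI whose resampling unit is the vessel (frames
within a vessel are strongly dependent); with no grouping, each frame is
its own unit.

## Numerical choices and edge cases

- Ray casting tolerates hits exactly at polygon vertices (1e-9 slack on the
  edge parameter); a zero-area contour is rejected as invalid.
- NCC returns 0 for constant signals; since a constant channel scores 0 at
  every shift, it never biases the argmin.
- DP and DTW tie-breaks are fixed (documented above) so identical inputs
  give byte-identical outputs.
- Circular interpolation always follows the shorter arc; a 350°→10° pair
  passes through 0°, never through 180°.
- The DP step window always contains the zero step, so any
  `max_step_deg ≥ 0` is feasible.
- All randomness flows through seeded `numpy` generators; a config seed
  fully determines simulator output and therefore the whole pipeline.

## Test problem sizes

Oracle tests check DTW against exhaustive monotone-path enumeration (200
matrices up to 7×8) and the rotation DP against full K^T path enumeration
(100 matrices up to 4×8). Recovery tests use 10 noiseless and 20
moderate-noise 40 mm phantoms (~80 analysis pairs each), sizes at which a
single vessel registers in well under a second; pooled noisy-phantom CCC
against ground truth exceeds 0.99 with median errors of ~0.6 frames and
~1.4–2°, computed fresh by `scripts/acceptance.py`.

## Known limitations

Rotation is quantized to 2°; no sub-bin refinement. Landmark-free segments
inherit rotation from constant extension of the nearest landmark. The
Williams Index CI assumes independent vessels. Hyperparameters (feature
weights, σ, λ) default to neutral values rather than values tuned on
clinical data; all are exposed in `RunConfig`.
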