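# Methods

This note documents the modelling assumptions, parameter choices and
numerical decisions behind `videobp`, in the package's own words.

## Signal model and pipeline

The pipeline assumes the facial video has been decoded to RGB frames with
per-frame 68-point landmarks available (landmark detection itself is out of
scope: any detector can feed the JSON sidecar interface).  Four skin patches
rich in superficial vasculature — forehead, both cheeks, and a chin band —
are cut out per frame and spatially averaged.  Averaging hundreds of pixels
suppresses independent sensor noise by `1/sqrt(A)` while the blood-volume
pulse, common to all pixels of a patch, survives; the result is the
`N × T × 3` *initial spatiotemporal map* `f(n, t)`.

**ROI recipe.** The ROI polygons are derived from seven anchor landmarks
(brow mids 19/24, eye outer corners 36/45, nose bottom 33, mouth corners
48/54, iBUG-68 indexing) by fixed rectangle arithmetic documented in
`roi_maps._default_roi_polygons`.  Which seven points delimit the regions,
and the exact shapes, are a design choice of this package; the recipe keeps
all four regions on skin and clear of eyes, nose and mouth.  Frames with
missing landmarks are dropped, not interpolated — interpolation would
fabricate physiological signal.  Masks use 0-based, origin-top-left pixel
coordinates; a polygon covers a pixel iff it contains the pixel center, so
integer-coordinate rectangles cover exactly the half-open index ranges.

**Augmentation.** Training-time masking blanks one contiguous time block
(≤ 10 % of frames) on ≤ 25 % of ROI rows (with N = 4 rows: one row),
emulating transient occlusion and detector dropout.  Block count, shape and
fill value (0) are package choices; all are configurable.  Masking runs
before the color transform, and never at inference.

**Color space.** The modified-YUV matrix is applied exactly as specified
(rows `(0.299, 0.587, 0.114)`, `(−0.169, −0.331, 0.5)`,
`(0.5, −0.419, −0.081)`); numerically it coincides with the BT.601
luminance/chrominance analog matrix.  A classical-YUV variant
(U = 0.492 (B−Y), V = 0.877 (R−Y)) and an RGB pass-through are provided so
the color-space ablation axis is a one-flag change.  What exactly
distinguishes the "modified" from the plain transform beyond the chroma
scaling is not recoverable from the source method description; the printed
matrix is treated as authoritative.

**Subset expansion and slicing.** All 15 non-empty subsets of the 4 ROI rows
are aggregated by *unweighted* row means (pixel-count weighting would
require carrying areas through augmentation; with similarly sized patches
the difference is second-order).  Canonical subset order is increasing
binary encoding.  Windows are non-overlapping (`step = cl`), matching the
index arithmetic of the slicing definition; overlap is exposed as a knob.
Normalization is min–max to [0, 1] per slice and per channel, so every
network input is scale-standardized regardless of illumination level; a
constant channel maps to zeros.  The no-slicing ablation mode is a single
window of length T.

## The estimation network

Input orientation: rows = 15 subset signals (height), columns = time
(width), 3 channels.  The encoder is a compact residual CNN — 3×3 stride-1
convolutions each followed by batch normalization, average pooling, a
1×1-projected skip where widths change — ending in global average pooling
and a learned projection to the 64-d per-slice embedding.  Batch
normalization uses batch statistics during training and running averages at
inference (so evaluation is deterministic); it is what lets the randomly
initialized trunk converge inside the 30-epoch budget.  The default width (12 channels in the first stage,
24 in the trunk) is deliberately small: the synthetic study runs on one CPU
core, and the waveform features (upstroke steepness, dicrotic bump, pulse
amplitude relative to drift) need few channels.  A bidirectional LSTM
(hidden 32 per direction) consumes the per-slice embedding sequence; the
clip feature `F` is the concatenation of the two final hidden states.  A
unidirectional variant is a flag.

The classifier is a single 64→4 linear layer; the calculator a single 68→1
linear layer on `[F, F_cla]`.  The calculator output is produced on a
standardized scale and mapped to mmHg through the *fixed* affine transform
`R_reg = μ + σ·z`, with μ, σ frozen from the training labels and stored in
the snapshot.  This is a numerical choice, not a model change: predictions
start at the training mean, so ADAM at the default rate only has to learn
the residual variation within the epoch budget.  Output fusion uses
interval midpoints as STA reference values with α = β = 0.5 by default
(α = 0 reduces to pure regression, the "no classifier" ablation).  Argmax
ties break toward the lower interval.

**Grouping.** Four half-open intervals per target: SBP edges
90/110/120/130/160 mmHg, DBP edges 50/60/70/80/100 mmHg, covering the
clinical spans with finer resolution around the population mode.  Labels
outside the span clamp to the edge groups with a warning.

**Losses.** Categorical cross-entropy with one-hot interval targets (the
only consistent reading for a 4-way softmax head) plus the regression loss,
summed unweighted.  Both L1 and L2 regression losses are mean-normalized so
the ablation compares like with like.  Cross-entropy clamps probabilities at
1e−12.

**Optimization.** ADAM, initial learning rate 0.001, at most 30 epochs,
batch size 8.  The learning rate follows a cosine decay from the initial
value by default (`lr_schedule="constant"` restores a flat rate); the decay
stabilizes the late-epoch validation error of a small-batch run.  With the
balanced sampler an *epoch* is defined as enough 1:1:1:1 batches to cycle
the largest group once — minority groups are then revisited several times
per epoch, which is exactly the oversampling intent.  Within a batch no
subject appears twice; if a group has fewer distinct subjects than its
per-batch quota the batch under-fills that group with a warning rather than
duplicate a subject.  The subject-level 4/5–1/5 split is stratified by group
(single-subject groups stay in training), and the best-validation-MAE
snapshot is kept.  Everything is driven by explicit seeds; identical seeds
give identical histories on one machine.

## Synthetic data generator

No public generative model links BP to facial blood-volume-pulse
morphology, so the generator's BP → waveform map is an invented, documented
stand-in chosen to make parameter recovery well-posed:

| quantity | map | default constants |
|---|---|---|
| pulse amplitude | affine in pulse pressure | `1.5 + 0.06 (SBP − DBP)` intensity units |
| systolic upstroke fraction | linear, decreasing in SBP | `0.42 − 0.0022 (SBP − 90)` cycles |
| dicrotic relative amplitude | linear, increasing in DBP | `0.08 + 0.004 (DBP − 50)` |
| post-peak decay | exponential | τ = 0.20 cycles |
| dicrotic bump position/width | fixed | 0.22 / 0.07 cycles past peak |

Heart rate is uniform in 60–100 bpm independent of BP (nuisance).  Labels
are drawn per 4-group weights, default SBP (0.15, 0.45, 0.30, 0.10) and DBP
(0.15, 0.40, 0.35, 0.10) — an imbalanced central peak like real cohorts —
uniformly within the group, resampling the pair until SBP > DBP + 10 mmHg.
Pixel model per ROI: skin-tone baseline + perfusion × channel gain (green
strongest, as in rPPG) × pulse + global illumination drift (1 intensity
unit, 0.05–0.15 Hz sinusoid) + Gaussian sensor noise (σ = 1 intensity
unit per pixel).  Fast mode emits the per-ROI mean traces directly with
noise scaled by `1/sqrt(A)`; render mode draws every pixel, keeps frames as
float arrays in [0, 255] (so the zero-noise ROI-average identity holds to
float rounding), and recomputes the stored traces from the rendered pixels.

What the generator does *not* emulate: facial appearance, head pose and
expression changes, detector jitter correlated with motion, specular
highlights, video compression, and — most importantly — the true,
population-variable BVP–BP relationship.  Passing end-to-end tests on this
data therefore shows the pipeline can recover a *planted* monotone BP
encoding from pulsatile skin signals under noise, drift and label imbalance;
it says nothing about accuracy on real faces.

## Scaled-down end-to-end study

The acceptance study uses 200 fast-mode subjects (15 s at 30 fps,
cl = 150), the default imbalanced label weights, the reduced-width backbone,
and ≤ 30 epochs on one CPU — sizes chosen so the full study runs in minutes.
Reported quantities: validation MAE of the fused SBP estimate, the
training-mean baseline MAE, their relative improvement, 4-way interval
accuracy, and the fraction of errors within 10 mmHg.

## Known limitations

- The NumPy network trains on a single core; it is a faithful, compact
  implementation of the architecture, not a performance-oriented framework.
- SD ≈ RMSE only when the mean error is small; the metrics module reports
  the population SD of errors (`RMSE² = SD² + mean(e)²` exactly).
- The w/o-slicing mode changes the CNN input width to T; the global average
  pool keeps the trunk length-agnostic, but embeddings are not comparable
  across cl values.
- Group boundaries, STA values, fusion weights and the ROI recipe are
  documented package choices wherever the source method leaves them open;
  all are configurable.
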