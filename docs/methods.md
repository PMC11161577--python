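# Methods

## The measurement model

A fly heart filmed side-on is modeled as a tube whose lumen diameter
d(t) is observable as the gap between two segmented wall bands. All
cardiac physiology derives from d(t): each beat is a systolic interval
(SI, contraction onset to relaxation end) followed by a diastolic
interval (DI, quiescent at maximal diameter). Diastolic diameter (DD)
is the largest d over a beat's DI and systolic diameter (SD) the
smallest over its SI. Derived quantities:

- FS = 100 (DD − SD)/DD (%) — fractional shortening, the primary
  contractility index.
- EF = 100 (DD² − SD²)/DD² (%) — ejection fraction under a
  cross-sectional-area (circular lumen) model.
- HP = contraction onset to next onset (s); HR = 1/mean(HP) (Hz).
- AI = sd(HP)/median(HP) (dimensionless), sample (n−1) standard
  deviation. FS/EF/AI conventions vary across the fly-heart
  literature; the formulas above are this package's documented choice
  and are configurable nowhere else in the code, so results are
  comparable across runs.
- SV = π L ((DD/2)² − (SD/2)²) µm³ with 1 pL = 10³ µm³, for a
  cylindrical segment of length L = ROI width × pixel size. CO =
  Σ SV / Σ HP over complete beats. The length normalization follows
  the cylinder convention; absolute SV/CO therefore scale with the
  chosen ROI, while comparisons at fixed ROI are unaffected.
- Contractile latencies: per beat, time from onset to the most
  negative wall velocity, and from that sample to the most positive
  velocity later in the same beat. Velocity is the numeric derivative
  (central differences, one-sided endpoints) of the optionally
  smoothed trace, scaled by fps.
- Tachycardic events are beats with SI strictly over 0.5 s; bradycardic
  events have DI strictly over 1.0 s. Thresholds are configurable;
  defaults follow the established fly-heart screening convention.

## Beat detection

The interval decomposition is not prescribed by the statistics above,
so the detector is defined here: smooth d(t) with a centered moving
average (default 5 frames), differentiate, and set a velocity threshold
v_thr = 20% of the 95th percentile of |velocity|. A contraction onset
fires when velocity < −v_thr from an armed (diastolic) state; after the
subsequent positive excursion (> +v_thr), the relaxation end fires when
velocity re-enters [−v_thr, +v_thr]. DI runs from relaxation end to the
next onset, so HP = SI + DI exactly.

Edge policy: a contraction already in progress at the first analyzed
frame is counted from that frame; the final SI-complete beat whose DI
is cut off by the end of the trace is kept in the beat table flagged
`truncated` but excluded from every aggregate statistic (its HP is not
observable). Traces whose peak-to-peak excursion is below 2 µm are
treated as having no oscillation above the noise floor and yield an
empty table.

On noise-free piecewise-linear traces the detector lands within one
frame of the constructed boundaries when run with smoothing window 1;
the default 5-frame smoothing exists for quantized/noisy traces and
biases boundaries by at most ~2 frames, which cancels in HP
differences.

## Trace extraction

Masks label wall tissue, so the lumen is measured inner-edge to
inner-edge: per column, the diameter is the count of non-wall rows
strictly between the uppermost run's last row and the lowermost run's
first row; columns with fewer than two wall runs are invalid, columns
with more than two (speckle) use the outermost runs with interior
speckle rows subtracted. A frame needs ≥ 25% valid ROI columns. Interior
invalid gaps of ≤ 5 frames are linearly interpolated and marked valid;
longer gaps are filled (to keep the series finite) but stay invalid,
and leading/trailing invalid frames are never extrapolated. Coordinates
are 0-based, row 0 at top, ROI columns half-open [c0, c1). The M-mode
image uses the ROI center column by default.

## Segmentation

The segmenter is an attention U-Net: symmetric encoder/decoder with
per-level filters (8, 16, 32, 64, 128 by default), two convolutions
per level, 2×2 max pooling, and nearest-neighbour upsampling. Kernels
are rectangular, default 3×7 — wider along the horizontal heart-tube
axis, matching the anisotropy of the structure. Skip connections carry
additive attention gates: the upsampled decoder features (reduced to
the skip width by a 1×1 convolution) gate the encoder skip via
ψ = σ(w·relu(θx + φg)) with the intermediate width set to half the
skip channels; the skip is multiplied by the single-channel ψ map
before concatenation. The head is a 1×1 convolution to one sigmoid
channel (wall vs background). Temporal context enters through the
(t−4, t, t+4) stack, clamped at clip edges so T frames yield T outputs.

Training: Dice loss on the sigmoid output, Adam at 1e-3 (unstated in
the protocol; standard default), batch size 16, 85/15 train/validation
split, random horizontal/vertical flips and ±10% intensity jitter, and
checkpoint selection at the minimum validation loss. He-normal
initialization, all randomness from a single seed. Inputs whose spatial
dims are not divisible by 2^(levels−1) are edge-padded and cropped back.

Both networks run on a small reverse-mode autodiff engine
(`flyheart.nn`) written for this package: same-padded convolution via
sliding windows + tensordot, 2×2 argmax pooling, nearest upsampling,
and a numerically stable BCE-with-logits head. Its gradients are
verified against finite differences and its convolution against scipy
in the test suite.

## Synthetic data generator

The simulator emulates the geometry the analysis assumes: two
horizontal wall bands of fixed thickness whose inner-edge gap equals
round(d(t)/pixel size), centred vertically, plus i.i.d. Gaussian
intensity noise. The waveform is a smoothed trapezoid per beat —
cosine ramps of 10% of HP for contraction and relaxation around a
systolic plateau, followed by a diastolic plateau — so DI plateaus and
SI dips are unambiguous and DD/SD are exactly the configured values.
Per-beat heart periods are truncated-normal (HP > 2 frame intervals)
with configurable mean and CV; each beat spans onset→onset so the
drawn HP is exactly the ground-truth HP. Ground truth (per-frame
waveform, per-frame masks, per-beat table) accompanies every sample.

Default study conditions: recordings at 200 fps; recovery studies use
DD 60 µm / SD 40 µm, HP 0.5 s, CV 0.05, 10 s. Cohort "aging" defaults
follow the directional phenotypes of fly cardiac senescence — the old
cohort has a smaller DD−SD gap (FS 33% → 21%), a longer mean HP
(0.4 → 0.7 s), and more period variability (CV 0.05 → 0.12); per-heart
parameters are perturbed multiplicatively with 5% CV so within-cohort
variance is nonzero. Effect sizes are configuration, not hard-coded.

What the simulator does **not** model: photorealistic microscopy
texture, pericardial cells and occlusions, heart-region drift, curved
tube geometry, or realistic camera noise statistics (the Gaussian model
is a stand-in). Passing tests therefore demonstrate correctness of the
measurement chain under the stated geometric model, not segmentation
robustness on real microscopy.

## Age classification

The logistic pipeline standardizes the seven features (DD, SD, FS, DI,
SI, HP, AI) per training fold and fits L2-regularized logistic
regression (C = 1); evaluation is stratified 5-fold CV with per-fold
accuracy, AUROC, and a pooled confusion matrix. A probability of
exactly 0.5 resolves to the old class. Shapley attributions are exact
for the linear model on the link scale: φ_j = w_j (z_j − E_bg[z_j]);
the test suite and the acceptance script verify them against the full
2⁷-coalition enumeration with a mean-imputation value function.

The video pipeline computes SSD(t) = Σ_pixels (frame_t − frame_0)²
(t₀ = first frame, configurable), min-max normalizes, binarizes at 0.5,
and takes the center frame floor((start+end)/2) of every maximal run
(both 0-runs and 1-runs) until 96 keyframes are collected; clips with
fewer runs are repeat-padded with duration 0 under a warning. Durations
are in frames (fps recorded alongside). The classifier passes the
96-frame stack (frames as channels) through 3 convolution blocks (two
3×3 convolutions + 2×2 max pooling; 8/16/32 filters by default),
flattens, concatenates the standardized durations, and applies three
dense layers (64, 32, 1) with a sigmoid output, trained with
BCE-with-logits and Adam. Whether SSD uses raw or downsampled frames
is an open choice; this implementation uses raw frames and optionally
resizes keyframes before the CNN (`frame_shape`; native size when
None).

## Problem sizes and numerical choices

Scaled-down study sizes (chosen so the whole verification runs on one
CPU in minutes): segmentation trains a (4, 8, 16, 32, 64)-filter net
for 5 epochs on ~210 stacks of 48×64 frames and evaluates Dice on a
held-out heart; the logistic cohort has 100 hearts per class analyzed
from waveforms; the video cohort has 40 hearts per class at 32×24 px,
60 fps, 30 s, trained 30 epochs per fold. Dice loss uses smoothing
ε = 1e-6; sigmoid/BCE clip logits at ±60 to avoid overflow; beat
detection ties (velocity exactly at ±v_thr) resolve to the
in-band/neutral interpretation. Cross-validation folds, network
initialization, cohort perturbations, and rendering noise all derive
from explicit integer seeds, and identical seeds reproduce results
bit-for-bit.

## Known limitations

- The simulator's rendering is deliberately schematic; segmentation
  performance on real optical microscopy will be dominated by effects
  it omits (occlusion, drift, texture).
- Velocity-threshold beat detection assumes a quiescent DI; hearts
  with continuous slow drift between beats may need a different
  v_thr fraction or smoothing window.
- SV/CO depend linearly on the chosen ROI length; only within-study
  comparisons at a fixed ROI are meaningful.
- AVI ingestion requires an external conversion to multi-page TIFF;
  no codec stack is bundled.
- The video classifier's keyframe padding makes very short recordings
  degenerate (mostly repeated frames); recordings should span enough
  beats to produce ≥ 96 motion runs.
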