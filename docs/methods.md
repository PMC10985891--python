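# Methods

This note records the models, parameter choices and numerical decisions
behind `vessel3`, and what the synthetic experiments do and do not show.

## Problem setting

The target is multi-class segmentation of the three great-vessel
cross-sections in the fetal three-vessel view (3VV): pulmonary artery
(PA, label 1), aorta (Ao, label 2) and superior vena cava (SVC, label 3)
on 2-D grayscale ultrasound.  The two structural difficulties are the
size disparity (the SVC lumen is an order of magnitude smaller in area
than the PA) and background clutter.  The pipeline is two-stage and the
stages are trained independently: a detector localizes the region
containing all three vessels, and a dedicated network segments the
cropped region.  Joint end-to-end training is explicitly out of scope.

## Synthetic phantoms

Clinical 3VV data cannot be redistributed, so all experiments run on a
parametric phantom (`vessel3.phantom`):

* three filled near-circular ellipses (eccentricity ≤ 1.3, random
  orientation) with dark lumens (mean 0.15), brighter walls (0.75) on a
  mid-gray background (0.45) — the appearance of vessel cross-sections;
* centers approximately collinear (PA–Ao–SVC along a random direction,
  perpendicular offsets within a 12° tolerance), pairwise disjoint with
  a ≥ 2 px margin inside the image; placement is retried up to 200 times
  before an explicit infeasible-spec error;
* default radii at 256×256: PA 14–20 px, Ao 11–16 px, SVC 3–5 px.  No
  pixel-size statistics are available for the clinical vessels; these
  ranges only enforce the documented hierarchy (PA ≥ Ao ≫ SVC, SVC ≤ 40%
  of PA) and were fixed once before any training experiments;
* multiplicative unit-mean gamma speckle (shape 4 by default; the shape
  parameter is the single granularity knob; `None` disables noise), the
  standard first-order ultrasound speckle surrogate;
* background clutter: ellipse outlines/arcs at random intensity,
  labeled background, to exercise false-positive suppression.

Per-sample seeds are spawned from the master seed via
`numpy.random.SeedSequence`, so datasets are reproducible element-wise.

What the phantoms do **not** model: attenuation, shadowing, anisotropic
point-spread, probe-dependent geometry, anatomical context (atria,
spine, ribs) and pathological anatomy.  Passing phantom benchmarks
therefore demonstrates that the pipeline's machinery (geometry, losses,
optimization, evaluation) is correct and that the design behaves
sensibly under size disparity and clutter — not clinical performance.

## ROI localization

Coordinates are 0-based half-open `[min, max)`; `x` indexes columns.
From detector output the highest-confidence box per class is kept (ties:
larger area, then first occurrence, for determinism).  The minimum
axis-aligned rectangle enclosing the selected boxes is expanded by a
5-pixel margin on every side and clamped at the image border.  The
mask-based strategy (tight foreground bounding box of a coarse binary
mask, same margin) is provided with identical downstream handling; the
margin for this strategy is not independently documented anywhere, so it
defaults to the same 5 px.  Fewer than three detected classes: merge
whatever exists; zero detections: fall back to full-size segmentation.
Crops are resized bilinearly to the network input; predicted masks
return to full resolution by nearest-neighbor resize and pasting at the
ROI position.  The oracle detector (ground-truth boxes, independent
per-box drop probability, uniform ±jitter on each corner, confidence in
[0.5, 1]) stands in for a trained detector in all tests; real detectors
plug in as any callable `image -> list[LabeledBox]`.

## Network

Encoder: 7×7 stride-2 convolution (padding 3) with batch normalization
and ReLU, then four cascaded groups of 512-channel residual basic blocks
— four 3×3 convolutions per group, read as two basic blocks; the first
convolution of groups 1 and 2 has stride 2 (1×1 stride-2 projection on
the skip), groups 3 and 4 are stride 1.  Overall stride 8: 256×256 →
512×32×32.  Grayscale input is replicated to three channels.

AMFF head: four branches of 3×3 convolutions with dilations
(1, 6, 12, 18), padding equal to dilation, BN + ReLU.  Branch *i* > 0
consumes the encoder feature plus branch *i−1*'s pre-attention output
(additive, which preserves channel count without extra projections).
Each branch ends in a spatial-attention gate — channel-wise average and
max pooling, a 7×7 convolution, sigmoid — whose (0, 1) map multiplies
the feature, so attention never amplifies.  Outputs concatenate to
2048×32×32.  The branch count and width are forced by the published
2048-channel fused feature over a 512-channel encoder; the dilation
rates follow the standard ASPP choice.  The ASPP baseline is the same
branches without hierarchy or attention, concatenated.

Decoder: 3×3 convolution to 256 channels (BN + ReLU), 1×1 convolution
to 3 channels, 8× bilinear upsampling.  The three output channels are
per-vessel sigmoids (no background channel); a softmax-with-background
formulation would be the main alternative and is deliberately not used,
matching the one-channel-per-vessel output convention.  Masks are
decoded as argmax over channels where the maximum probability passes
0.5, ties to the lower class index.  The final 1×1 bias is initialized
to −2 so the untrained network predicts mostly background — foreground
is sparse and this avoids a large initial false-positive plateau.

The layer substrate (conv via im2col + BLAS, batch norm, bilinear
upsampling expressed as separable interpolation matrices, Adam) is
implemented on numpy with hand-written backward passes; every layer and
the composed network are verified against central finite differences at
float64 in `tests/test_nn.py`.

## Loss

`L = 0.5·L_dice + 0.5·L_ce`.  The cross-entropy term is literal:
positive pixels only, weighted by `W_k = N_total/N_k` computed once over
the training split (a per-batch option exists but dataset counts are the
default, since the weight definition carries no per-batch qualifier).
A class absent from the whole split is a hard error.  Probabilities are
clamped at 1e−7 inside the log; the Dice term adds 1e−6 to numerator and
denominator.  The Dice term uses the channel mean (1/M) rather than a
1/(MN) prefactor: the per-channel summand is already normalized by pixel
sums, and an additional 1/N would send the term to zero as images grow —
the printed prefactor is treated as a typo and recorded as such.  A
consequence of the positive-only CE is a transient over-segmentation
phase early in training (only the Dice term penalizes false positives);
with the background-prior bias initialization the phase resolves within
the training budget.

## Metrics

One-vs-rest per class: IoU = TP/(TP+FN+FP), Dice = 2TP/(2TP+FN+FP),
both reported in percent (Dice = 2·IoU/(1+IoU) is asserted as an
identity in the tests).  Hausdorff distance is the pure symmetric
maximum of directed max–min Euclidean distances between boundary point
sets, in pixels at full image resolution — no 95th-percentile variant.
Boundaries are foreground pixels with at least one background
4-neighbor; the image border counts as background.  Per-image per-class
values are macro-averaged over the evaluation set and then over the
three classes.  A class absent from both masks is skipped (not scored
100, which would inflate means); a class absent from exactly one mask
scores Dice = IoU = 0 and has no defined HD; skipped counts are reported
alongside the averages.

## Training protocol

Reference schedule: 35 epochs of Adam, learning rate 1e−3 stepping to
1e−4 for the final 10 epochs.  The published schedule couples the step
with "a decay rate of 1e−8", which is internally ambiguous; it is read
here as Adam's numerical-stability epsilon (exposed as `adam_eps`), and
the learning-rate change is a clean step at epoch 25.  Batch size
defaults to 8 (never documented in the protocol).  Augmentation
(paired horizontal flip, rotation within ±15°, isotropic scale
0.9–1.1; masks warped nearest-neighbor) is available and on by default
at full scale.  Stage-2 training crops come from ground-truth boxes
(teacher forcing), optionally from oracle-jittered boxes.

**Desk-scale presets** (`vessel3.presets`) define the study conditions
used by the tests, examples and `scripts/acceptance.py`, chosen once:
96×96 phantoms (PA 7–10 px, Ao 5.5–8 px, SVC 2.5–3.5 px), 64×64 network
input, width-32 encoder with 32-channel decode (the same topology at
1/16 the channels), learning rate 3e−3 → 3e−4 (a width-32 model trains
stably at a larger rate than the full 512-channel network), and
augmentation disabled — the generator already randomizes geometry per
sample, so flip/rotate/scale adds nothing at a 35-epoch budget.  The
end-to-end study trains on 120 phantoms and validates on 20; the
ablation uses 40 phantoms with a 7:1:2 split over three seeds; the
memorization sanity check runs 200 epochs on two phantoms at learning
rate 5e−3.

The data split is shuffle-then-partition at ratios 7:1:2 with
largest-remainder rounding (ties resolved train → val → test).  All
randomness (weights, batch order, augmentation, phantom geometry,
detector jitter) derives from explicit seeds, and training is
bit-reproducible on CPU.

## Known limitations

* Phantom realism as listed above; absolute scores on phantoms do not
  transfer to clinical images.
* The stage-1 detector is exercised only through the oracle stand-in;
  adapters for trained object detectors are out of scope.
* At desk scale the AMFF-vs-ASPP Dice delta is noisy (a few percentage
  points of spread across seeds over 8-image test splits); the harness
  reports the per-seed deltas and their spread rather than asserting a
  direction.
* The positive-only weighted CE makes early training over-segment; very
  short schedules can leave small-class false positives.
* Hausdorff units are pixels at whatever resolution the masks are
  compared; millimetre calibration is not modeled.
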