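# Methods

This note records the models and procedures saffpick implements, the
assumptions behind the synthetic scenes, and the design choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Problem setting

A safflower harvesting robot must cut the filament bundle at the *necking*,
the junction between the filament tuft and the fruit ball it opens on. The
pipeline is: segment an RGB frame into background (0), filament (1), fruit
ball (2) and branch (3); then localize the picking point geometrically from
the label map. Coordinates are x = column, y = row, origin top-left,
0-based, in pixels.

## Segmentation network (SDC-DeepLabv3+)

**Backbone.** ShuffleNetV2: a 3×3 stride-2 stem to 24 channels, a 3×3
stride-2 max-pool, then three stages of shuffle units. Stride-1 units split
the channels in half, transform one half (1×1 → depthwise 3×3 → 1×1),
concatenate and channel-shuffle with two groups; stride-2 units have no
split — both branches transform the input and concatenation doubles the
channel count while halving the spatial size. Stage widths are (48, 96,
192) at 0.5× and (116, 232, 464) at 1×; repeats default to (4, 8, 4).

Two structural choices were open:

- *Output stride.* Three downsampling stages after the stride-4 stem+pool
  would put the deep feature at stride 32. The decoder contract wants
  stride 16, so the last stage's downsampling unit runs at stride 1 with
  dilation 2 in its depthwise convolutions — the standard DeepLab
  adaptation.
- *Shallow tap.* The decoder fuses a stride-4 low-level feature. With every
  stage downsampling, the only stride-4 tensor is the post-pool stem output
  (24 channels); that is the tap point.

**DDSC-ASPP.** The pyramid head has eight parallel branches on the deep
feature: one 1×1 convolution, six dilated branches at rates 3, 6, 9, 12,
15, 18, and one global-average-pooling branch projected by 1×1 convolution
and broadcast back. Each dilated branch is a bottleneck: 1×1 to 64
channels, two cascaded 3×3 *dilated depthwise-separable* convolutions, and
1×1 back to 256. A depthwise-separable convolution factors a k×k dense
convolution into a per-channel k×k convolution plus a 1×1 cross-channel
mix, costing k²·C_in + C_in·C_out parameters instead of k²·C_in·C_out. A
single dilated 3×3 layer sees a receptive field R = (r−1)(k−1)+k; two
cascaded layers see R₁+R₂−1, so the rate-18 branch covers 73 pixels of the
stride-16 feature map. All eight branch outputs are concatenated and fused
by a 1×1 convolution to 256 channels. The bottleneck-and-cascade treatment
is applied to all six dilated branches.

**CBAM.** Convolutional block attention — channel attention (global average
and max pooling through a shared two-layer 1×1 bottleneck, sigmoid gate)
followed by spatial attention (channel-wise mean and max maps through a 7×7
convolution, sigmoid gate) — is applied at two points: on the ASPP output
(the encoder output) and on the shallow feature before decoder fusion.

**Decoder.** 1×1 reduction of the 256-channel encoder output to 128,
4× bilinear upsampling (align-corners false), concatenation with the
CBAM-gated shallow feature, a 3×3 fusion convolution, a 1×1 classifier to
4 logits and a final 4× bilinear upsampling to input resolution. Inputs
must have height and width divisible by 16.

**Numerics.** The network runs on a purpose-built numpy reverse-mode
autodiff core (im2col convolutions, hand-derived backward passes), in
float64. Every backward pass is verified against central finite differences
in the tests (tolerance 1e-4; observed agreement ~1e-10). Batch
normalization keeps *cumulative* running statistics (the plain average of
all batch statistics seen), which makes short runs deterministic and keeps
eval-mode behavior close to train-mode on small fixed datasets. The
classifier convolution is initialized with std 0.01 so early logits stay
near the class prior; other convolutions use He-normal initialization.
Argmax ties in `segment` resolve to the lowest class index.

**Training.** SGD at initial learning rate 0.01, batch size 8, unweighted
per-pixel cross-entropy. Momentum 0.9 is used; the optimizer is otherwise
plain SGD. If validation mean pixel accuracy does not improve for 15
epochs, the learning rate is multiplied by 0.01. Checkpoints are written
every 10 epochs plus `best`/`last`; weights serialize as `.npz` with a JSON
sidecar carrying the model config. The default run length is 20 epochs —
sized for synthetic desk-scale datasets; the schedule itself matches the
long-run recipe (which used 1,000 epochs on field data). One integer seed
drives initialization, shuffling and augmentation (default 42).

## Picking-point localization

From a label map containing all three organ classes:

1. **Components.** Largest 8-connected component of filament and of fruit
   ball (ties by lowest component label); barycenter = arithmetic mean of
   member pixel coordinates.
2. **ROI.** The branch is searched in the rectangle below the fruit ball:
   columns spanning the ball widened by 10% of its left-right pole distance
   per side (configurable), rows from the ball's lowest contour pixel to
   the image bottom. A strip under two rows tall is degenerate and an
   error.
3. **Edges.** Grayscale conversion, central-difference gradient magnitude
   √(f_w² + f_h²) with f_w(x,y) = ½[f(x+1,y) − f(x−1,y)] (replicated-edge
   padding at borders), then thresholding — Otsu by default, fixed value
   configurable. A flat gradient yields an empty edge map, not an error.
4. **Lines.** Probabilistic Hough transform (defaults: vote threshold 30,
   min length 20 px, max gap 5 px, 1° angular resolution — all
   configurable). The library's Hough implementation does not expose
   accumulator votes, so segments are scored by their edge-pixel support
   (pixels within 1 px) and returned strongest-first.
5. **Selection.** The segment minimizing the *sum* of perpendicular
   distances from the two barycenters to its supporting line. The distance
   uses the cross-product form |(q₂−q₁) × (p−q₁)|/|q₂−q₁|, which equals the
   slope-intercept form for non-vertical lines and remains defined for
   vertical ones — the common case, since branches grow near-vertically.
   Ties (within 1e-9 px) go to the longer segment, then input order.
6. **Picking point.** Both barycenters are projected orthogonally onto the
   *infinite* supporting line (not clamped to the segment — projections may
   fall beyond the detected endpoints); the picking point is the midpoint
   of the two projections, which therefore lies on the line by
   construction.

The residual error on clean scenes is dominated by the branch's finite
width: the Hough line follows one branch *edge*, offset half a width from
the axis, so with the default 6 px branch the picking point lands ~2–3 px
from the true necking. `locate` handles one flower per call (the largest
filament component); multiple flowers are handled by cropping upstream.

## Evaluation

- **Segmentation**: from a (K+1)² confusion matrix with entry [i][j] =
  pixels of true class i predicted j, per-class accuracy p_ii/Σ_j p_ij,
  IoU p_ii/(row+col−p_ii), precision p_ii/Σ_j p_ji, macro-averaged over
  classes present in prediction or truth (classes absent from both are
  excluded to avoid 0/0) and reported in percent. Macro recall equals mPA
  algebraically; both names are exposed because both are standard report
  columns. The printed forms of the precision/recall formulas in the source
  material are typographically corrupted; the standard definitions are
  implemented.
- **Pixel error**: e_x and e_y are the minimum axis distances from the
  predicted point to the best-picking region's column/row spans (zero
  inside), combined as e = √(e_x²+e_y²). The region is typically a 30×10 px
  rectangle on the branch axis; a point ground truth is the degenerate
  case.
- **Camera space**: pinhole back-projection X=(u−c_x)Z/f_x,
  Y=(v−c_y)Z/f_y; rigid transform to a calibration-plate frame with an
  orthonormality check; E_Z = mean|Z(CP)−Z(GT)|, E_X = mean|X(CP)−X(OP)−L|.
  Absolute deviations are used so opposite-signed errors cannot cancel.

## Synthetic scenes

Each scene renders, against a near-color green background with
low-frequency texture: a branch (thick segment from the ball center
downward, angle U[−10,10]° off vertical, width 6 px, length 180 px at the
default 480×640 resolution), a fruit ball (ellipse, semi-axes 28×26 px) at
the branch top, and a filament tuft (disk of radius 26 px with radial petal
strokes, tangent to the ball along the axis). The filament radius is set
comparable to the ball's vertical semi-axis, matching the proportions of an
opened flower; with similar sizes the projection midpoint coincides with
the necking, so localization error isolates the line-detection geometry.
The necking ground truth is the intersection of the branch axis with the
filament/ball boundary. Weather regimes are global brightness/contrast
shifts plus, for backlight, an additive halo gradient — a stand-in for
illumination, not a radiometric model. Optional occlusion covers part of
the structures with a leaf-colored ellipse (labels revert to background);
an optional planar depth map supports camera-space examples. Default pixel
noise is σ=3; verification scenes use σ=0.

What the generator does **not** emulate: real filament thread structure,
cross-occlusion between plants, specular highlights, depth variation, and
segmentation failure modes of real imagery. Passing tests therefore
demonstrate the correctness of the algorithms and the trainability of the
network, not field-grade accuracy.

`generate_dataset` splits 8:2 by seeded shuffle (first ⌊0.8n⌋ indices are
training — 1,050 scenes give exactly 840/210); `expand_dataset` doubles a
set by giving each scene one augmented variant with a randomly drawn op
(translation, rotation, contrast, brightness). Geometric ops move image,
labels (nearest-neighbor) and ground-truth points together; color ops leave
labels bit-identical; out-of-frame regions become background.

## Problem sizes used

Tests and the acceptance script size their runs for a single CPU:
localization recovery uses 100 full-resolution (480×640) clean scenes;
dataset bookkeeping renders 1,050 + 525 scenes at 48×64; network training
checks use 0.5×-width models on 96×128 scenes (8 scenes, 10 epochs for the
overfit check). These are the package's chosen desk-scale study conditions.

## Known limitations

- The network is numpy-only; throughput is desk-scale (no GPU path), so
  headline field accuracies from large private datasets are out of scope.
- `locate` assumes the flower grows upward (branch below the ball); scenes
  violating that geometry put the branch outside the ROI.
- Hough defaults assume a branch at roughly full-resolution scale; small
  crops need the thresholds scaled down via `LocateConfig`.
- The four-class palette is fixed; a trunk/other-organ class is not
  modeled.
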