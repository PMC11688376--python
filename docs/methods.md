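# Methods

## Problem and scope

Early-pregnancy ultrasound assessment of the gestational sac (GS) rests on
two measurements taken from the sac's outline: the maximum length `DM` and
the short diameter `Dm`, whose mean (the mean sac diameter, MSD) maps to a
gestational-age estimate.  `sacmetry` implements the automated version of
that workflow: candidate segmentation networks produce a binary sac mask,
and a geometric pipeline turns the mask plus the scan's pixel spacing into
`DM`, `Dm` and gestational weeks (GW).

## Biometry pipeline

Given a binary mask and a pixel spacing (cm/px per axis):

1. **Largest component.** The mask is reduced to its largest 8-connected
   foreground component (`scipy.ndimage.label`).  Segmentation artifacts
   (satellite blobs) are thereby discarded; interior holes are ignored
   because only the outer boundary is traced.
2. **Boundary tracing.** Moore-neighbor tracing with Jacob's stopping
   criterion walks the outer boundary: starting at the first foreground
   pixel in row-major order (whose west neighbor is guaranteed background),
   the 8-neighborhood of the current pixel is scanned clockwise from the
   backtrack pixel, and the walk ends when the start pixel is re-entered
   from the starting direction.  The mask is padded by one background pixel
   so objects touching the frame have a well-defined outer boundary;
   coordinates are reported in the original frame.  One augmentation is
   applied to the plain walk: on a diagonal step the walk would bypass a
   staircase-corner pixel whose only background contact is diagonal, so
   that pixel (the foreground 4-common neighbor of the step, `p + next -
   backtrack`) is emitted in passing.  With it, the contour's pixel set
   equals exactly `{foreground pixels with >= 1 background 8-neighbor}` for
   simply connected shapes, while staying an ordered, closed, 8-connected
   path.  A single isolated pixel traces to itself.
3. **Minimum-area rectangle.** The convex hull of the contour
   (`scipy.spatial.ConvexHull`, with explicit handling of 1-2 point and
   collinear inputs) feeds a rotating-calipers search: the optimal
   enclosing rectangle shares an edge direction with the hull, so only hull
   edge orientations are evaluated.  Ties below 1e-12 in area keep the
   first edge.  Collinear input degenerates to a zero-width rectangle, a
   single point to a zero-size one; both still yield a (degenerate)
   measurement rather than an error.
4. **Corner labeling.** Corners are labeled `c1` (reference: the
   lexicographically smallest corner), `c2` (adjacent along the longer
   side), `c3` (adjacent along the shorter side), `c4` (opposite).  Side
   lengths are compared *after* spacing is applied, so `DM >= Dm` holds
   even under anisotropic spacing, where the pixel-space ordering can
   invert.
5. **Diameters.** Each coordinate difference is scaled by its axis spacing
   before the Euclidean distance:
   `d = sqrt((dcol * PScol)^2 + (drow * PSrow)^2)`.  The rectangle is fitted
   in pixel space and spacing applied afterwards; for anisotropic spacing
   the physical-space figure is strictly a parallelogram, and fidelity to
   the measurement convention is preferred over geometric purity.
6. **Gestational age** (Hellman relation, diameters in cm):

   `GW = (0.5 * (DM + Dm) + 2.543) / 0.7`

   GW depends on the diameters only through their sum, is strictly
   increasing in each, and is floored at `2.543 / 0.7 = 3.6329` weeks for an
   empty measurement.

Pixels are treated as points at integer `(row, col)` centers, 0-based;
rectangle corners are real-valued.  Because the rasterized sac contains
only pixels whose centers fall inside the ideal curve, measured diameters
sit roughly half a pixel below the continuous truth per side -- visible as
the ~0.25% shortfall in the worked example below and well inside the
tolerances used throughout.

### Spacing conventions

Internal spacing is cm/px (`DM`/`Dm` are reported in cm); DICOM
PixelSpacing (mm) is divided by 10 at ingestion.  DICOM defines the tag as
(row spacing, column spacing); the reference algorithm's literal assignment
reads the first entry as the *column* spacing.  The default follows the
DICOM standard; `spacing_order="paper"` reproduces the literal assignment.
Both agree on isotropic scans.

## Segmentation stack

Four encoder-swapped architectures are provided on a ResNet50 backbone:
UNet, UNet++ (nested dense skips), DeepLabV3 (ASPP with 256 channels,
atrous rates 12/24/36, output stride 16, bilinear x16 head upsampling), and
ResUNet.  Decoder channel widths are (256, 128, 64, 32, 16); skip
connections come from the five encoder stages.  UNet and ResUNet differ in
decoder block style: plain blocks use two 3x3 conv-BN-ReLU units; residual
blocks add a biased 1x1-conv shortcut around the pair, summed before the
final ReLU, and end in a 1x1 (rather than 3x3) classification convolution.
Heads emit two logits (background/foreground); the public network output is
the softmax foreground channel, computed as `sigmoid(z_fg - z_bg)`, so every
model maps `(batch, 3, H, W)` to a single-channel probability map of the
input's spatial size (H, W divisible by 32).  These configurations were
chosen so the trainable-parameter totals reproduce the reference counts
exactly (UNet 32,521,250; UNet++ 48,985,890; DeepLabV3 39,633,986; ResUNet
33,435,410); the parameter-count tests pin them.

No deep-learning framework is used: the networks run on a small tape-based
reverse-mode autograd engine written on numpy (`sacmetry._nn`).
Convolutions are im2col gathers feeding BLAS matmuls; input gradients are
scatter-adds.  Every primitive's analytic gradient is verified against
central finite differences in the test suite.  Weights are He-normal
initialized (no pretrained encoder is loaded); batch norm uses batch
statistics in training and running averages (momentum 0.1) at inference.
Grayscale inputs are replicated to three channels to fit the RGB encoder
stem.

### Training protocol

Adam with learning rate 1e-4 and batch size 2; Dice, Jaccard, or
binary-cross-entropy loss.  The soft losses use `sum(p * y)` intersections
with an additive smoothing constant 1.0 (exact-identity tests use 0 on
non-empty masks); BCE clips probabilities to `[1e-7, 1 - 1e-7]`.  Offline
augmentation quadruples the training set: each image yields itself, one
45-degree rotation (bilinear for images, nearest-neighbor for masks, fill
0, size preserved), a horizontal flip and a vertical flip.  Cross-validation
uses stratified 5 folds (per-fold class fractions within one item of the
global fraction, reproducible under a seed).  Early stopping watches
validation Dice with patience 5 and restores the best checkpoint; "within
an epoch" training Dice is accumulated over the already-updated batches, so
it mixes pre- and post-update behavior in epoch 1.  Prediction binarizes
the probability map at 0.5, with ties assigned to foreground.

## Synthetic data

The generator emulates the post-crop 512x512 view of an early-gestation
scan.  A sac is a rotated ellipse with semi-axes `a >= b` (pixels),
optionally perturbed by a low-frequency radial profile
`rho(phi) = 1 + A * sum_k w_k cos(h_k phi + psi_k)` with amplitude
`A <= 0.3` and harmonics 2-4 (abnormal cases draw `A` in [0.05, 0.25];
normal cases are regular).  A pixel is foreground iff its center lies
inside the curve -- no anti-aliasing, masks are strictly binary.  Truth is
analytic and always refers to the unperturbed ellipse: `DM = 2 a s`,
`Dm = 2 b s` for isotropic spacing `s`, and GW via the Hellman relation.
Dataset sampling inverts that relation: GW is drawn uniformly over 4-10
weeks, `MSD = 0.7 GW - 2.543` fixes `a + b` given the spacing, the aspect
ratio `b/a` is uniform in [0.6, 1], and the spacing targets a sac diameter
near half the frame (as an operator would zoom) clipped to the 0.1-0.5
mm/px acquisition range.  The cohort mix defaults to 274/500 normal and
305/500 transabdominal, mirroring the emulated study's composition.

Pseudo-ultrasound renderings paint an anechoic lumen (0.12), a bright
3-px decidual rim (0.85) and an echogenic background (0.55), multiplied by
gamma-distributed speckle with unit mean and standard deviation 0.25.
These fixtures capture geometry, intensity ordering and multiplicative
noise, but none of the physics of real sonography (beam anisotropy,
shadowing, refraction) nor anatomical confounders (yolk sac, embryo,
uterine wall).  Tests passing on them therefore validate the geometry/
bookkeeping pipeline and trainability, not clinical segmentation accuracy.

## Problem sizes used in the checks

The oracle-equivalence checks run the rotating calipers against a dense
0.01-degree angle sweep on 100 random point sets, and the boundary tracer
against the background-adjacency oracle on 50 random star-shaped blobs.
End-to-end recovery uses 50 regular sacs spanning GA 4-10 weeks and all
orientations; each case recovers GW within 0.1 weeks (observed maximum
about 0.02) with mean absolute deviation under 0.05.  The training smoke
run uses 20 rendered 128x128 cases and the reference optimizer settings
with random initialization; Dice passes 0.9 by the second epoch, so the run
is capped at 6 of the allowed 15 epochs.

## Known limitations

* The engine is CPU-only and desk-scale; clinical-scale training (hundreds
  of 512x512 images, dozens of epochs) is out of reach by design, so the
  study's clinical segmentation scores cannot be reproduced here.
* No pretrained ImageNet weights are loaded; transfer-learning behavior is
  not exercised.
* Anisotropic spacing combined with an oblique sac makes the "rectangle"
  measurement convention slightly underestimate the true physical extent;
  the package reproduces the convention rather than correcting it.
* Boundary tracing assumes one sac; multiple gestations would need per-
  component measurement.
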