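# Methods

## Problem and model

The aortic valve's three leaflets (right-coronary `rc`, left-coronary `lc`,
non-coronary `nc`) are thin, fast-moving structures that standard imaging
cannot resolve, yet their individual planar shape matters for personalized
prosthesis design and biomechanical simulation.  The surrounding aortic
root, by contrast, is clearly visible in 3D transesophageal ultrasound and
its geometry is physiologically coupled to the leaflets.  `valvesynth`
therefore treats leaflet synthesis as a *domain-mapping* problem between
two data spaces:

- `D_US ⊂ R^{32×128×128}` — root subvolumes anchored at the commissure
  plane, thresholded at gray level 80 and scaled to [0, 1];
- `D_Lf ⊂ R^{128×64}` — planar leaflet shape images at 0.34 mm/pixel,
  centered on their mass and rotated so the two commissure points share an
  image column.

Convolutional autoencoders learn latent spaces `Z_US ⊂ R^m` and
`Z_Lf ⊂ R^n` (one shared leaflet space for all three types).  Two paths
predict a leaflet code from a volume:

1. **Shape estimation** — a VGG-style 3D CNN regresses `z_Lf` directly
   from the volume (trained per leaflet type against the frozen leaflet
   encoder's codes, MSE in latent space).
2. **Domain mapping** — the volume is first encoded to `z_US`, then a
   per-type random forest or MLP maps `z_US → z_Lf`.

Either way the predicted code is decoded by the leaflet decoder `p_Lf`
into a 128×64 image.  Three predictors are always trained, one per leaflet
type, sharing architecture but not weights.

## Architectures

Autoencoder (both modalities): `conv_layers` blocks of
[3(×3) convolution, `filters` channels, ReLU, 2(×2×2) average pooling],
flatten, one fully connected ReLU layer with as many units as the last
pooling output, and a linear bottleneck of `latent_dim`.  The decoder
mirrors this: dense ReLU back to the pooled size, reshape, and per level
nearest-neighbour 2× upsampling followed by a convolution (linear at the
output).  The optimal configuration for both autoencoders is three blocks,
16 filters, latent 20.  Regression CNN: `blocks` blocks of
`convs_per_block` 3×3×3 convolutions (`filters` channels, ReLU) each
followed by 2×2×2 average pooling, then `dense_layers` ReLU layers of
`dense_units` and a linear 20-dimensional output; the optimal
configuration is 4 blocks × 3 convolutions, one dense layer of 100 units.
Where reports of the optimal filter count disagree (16 in the text, 32 in
the grid table), the default follows the text (16); both build.

Unstated details are fixed as package conventions: convolutions use
kernel 3, stride 1, zero "same" padding (pooling alone controls
resolution); weights are He/Glorot-normal initialized from a seeded
generator, biases zero; Adam runs at its default learning rate 1e-3 with
MSE loss, batch 32, 100 epochs (defaults of `TrainConfig`); no
augmentation, weight decay or early stopping.  Latent inputs to the
mappers are used unscaled (a standardization toggle exists, default off);
the RF uses unlimited depth and all features, the MLP ReLU hidden layers,
linear output, Adam, max 2000 iterations, tol 1e-6 (scikit-learn).

## Numerical backend

The 2D/3D convolution/pooling/dense stack, backpropagation and the Adam
optimizer are implemented in-package on NumPy float32 arrays
(channels-last), with convolutions as JIT-compiled direct loops that skip
zero inputs — the thresholded volumes and ReLU maps are mostly zero.
Gradients are verified against central finite differences in float64 (at
points off the ReLU kink; with zero-initialized biases and exactly-zero
input regions the loss is evaluated precisely at the kink, where the
conventional relu'(0)=0 subgradient and one-sided difference quotients
legitimately disagree).  Adam updates are slab-wise and in place so that
optimizer temporaries stay bounded (~64 MB) even for the largest dense
layer; gradient accumulation chunks large batches (default 2 volumes / 64
images per chunk) to bound activation memory.  Training is bit-reproducible
for a fixed seed: all randomness flows through seeded NumPy generators and
every kernel is single-threaded.

The optimal ultrasound autoencoder (three blocks) has a 16384→16384
encoder dense layer (268M parameters).  It builds and runs inference
within a few GB, but its Adam state alone needs ~4.3 GB, so the *training*
runs of the standard benchmark use the four-block grid configuration
(pooled output 2×8×8×16 → dense 2048², ~4M parameters) with the same
filter count and latent size.  Both are exposed; nothing in the API
prevents training the three-block model given the memory.

## Synthetic data generator

Real paired data (ex-vivo volumes plus leaflet photographs) cannot ship
with the package, so a parametric generator produces paired records with
known ground truth:

- **Root volume**: per slice a bright annular wall (Gaussian radial
  profile, FWHM = `wall_thickness`) whose radius grows with depth at a
  rate set by `root_height` and whose center drifts with `tilt`; additive
  clipped Gaussian speckle inside a circular imaging field; gray values
  are then thresholded at 80/255 and scaled exactly like real volumes.
  Priors: annulus radius ~ N(11.5, 1.2²) mm clipped to [9, 14], root
  height ~ N(23, 2.5²) mm clipped to [18, 28], wall ~ N(2.2, 0.25²) mm,
  speckle sd 0.05, tilt ~ N(0, 2°) — porcine-root-like magnitudes.
- **Leaflet image**: a closed region between a straight vertical
  commissure-to-commissure edge of length `height` and a belly boundary
  with maximal chord `width`; `belly_curvature` morphs the boundary from
  triangular (0) to half-elliptic (1) and `asymmetry` skews the apex
  toward one commissure.  Interior intensities are smooth in (0.65, 0.95],
  background exactly 0; rendering is 4× supersampled and the shape is
  centered by whole-pixel center-of-mass translation.  With the commissure
  axis vertical, a symmetric leaflet mirrors about the mid *row*.
- **Coupling**: leaflet (width, height) are noisy linear functions of
  (annulus radius, root height) with per-type offsets (`nc` smaller, as in
  real valves).  `strong` keeps noise at about a third of the signal
  spread (R² ≈ 0.9), `weak` triples it, `none` draws leaflet parameters
  from the same marginals independently of the valve's own root — the
  negative control.  With zero noise, linear regression recovers the
  coupling coefficients to < 1%, validating the generator before any
  neural component runs.

What the generator does *not* emulate: Rayleigh speckle statistics and
shadowing, biological shape families beyond the two-parameter belly
model, calcification or other pathology, and annotation noise (records
are emitted in final preprocessed geometry; a raw mode produces
un-centered rotated RGB photographs to exercise the preprocessing).  A
passing benchmark therefore shows that the pipeline recovers a planted
volume-to-shape association at realistic geometry and noise scales — not
that it reaches any particular accuracy on real ultrasound.

## Evaluation protocol

Splits are Monte-Carlo: independent random 80/20 train/test draws over
*valves* (a valve's volume and leaflets never straddle a split), test size
round-half-up of 0.2·n, folds independent rather than a partition.  The
auxiliary leaflet set (leaflet images without volumes) joins autoencoder
training only, never any test fold or predictor training.  Grid search
selects the minimal mean held-out score (reconstruction RMSE for
autoencoders, latent RMSE for predictors), ties broken toward the smaller
model.  Performance analysis scores each method with RMSE, Jaccard
(segmentation threshold 0.45 ↔ gray level 115), Hausdorff and the average
symmetric contour distance (ASCD), in pixels and mm (0.34 mm/pixel);
aggregates weight every predicted leaflet equally.  Two reference rows
accompany the predictions: `reconstruction` (decode(encode(truth)), the
autoencoder ceiling) and `mean_baseline` (decoded per-type median of the
training codes — the "average leaflet").  An empty predicted segmentation
is reported as a failure case, not a metric value; Jaccard of two empty
masks is 1 by convention.  Contour extraction uses 4-connectivity with
image borders as background; "spreading" features measure first-to-last
extent (holes included), with a strict-run alternative behind a flag.

## Standard benchmark sizes

The shipped benchmark (`valvesynth.benchmark`) freezes desk-scale study
conditions chosen so a full run (two coupling controls plus the variance
experiment) completes in minutes on one CPU core: 24 valves, 3 folds,
leaflet autoencoder 20 epochs at batch 8 (the small dataset gets ~140
optimizer steps this way), ultrasound autoencoder 2 epochs, regression CNN
1 epoch, ultrasound autoencoder at the four-block configuration (above).
The compared quantities are order relations that are robust at this scale:

- **Positive control** (strong coupling): fold-mean ASCD of MLP domain
  mapping below the mean-shape baseline's.
- **Negative control** (no coupling): the mapper's advantage stays within
  the fold-to-fold standard deviation of the difference — a leakage guard.
- **Variance collapse**: the per-type variance of predicted leaflet areas
  under the (undertrained, small-n) shape-estimation CNN is below that
  under MLP domain mapping, which preserves inter-patient spread.

The budget is split asymmetrically on purpose: a convolutional encoder
projects the ring geometry of a root volume into latent coordinates that
track the annulus parameters even after very little training, so the
ultrasound schedule mainly limits reconstruction quality rather than the
mapper's input signal, while the leaflet autoencoder's schedule controls
the sharpness of every decoded prediction — it gets the longer budget.

## Known limitations

- Contour metrics are 2D and in-plane only; no 95th-percentile Hausdorff.
- The preprocessing's intermediate working-frame size is derived from the
  stated raw (0.037 mm/px) and final (0.34 mm/px) resolutions; it is a
  2:1 rows:columns frame so the final image is isotropic.
- `preprocess_leaflet` expects manual inputs (landmarks, per-image
  background threshold in 158–168, default 163); no automatic commissure
  detection.
- NRRD volumes are not read (no reader dependency available); NIfTI and
  multi-page TIFF are.
- Statistical significance testing between methods is out of scope.
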