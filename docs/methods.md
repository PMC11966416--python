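# Methods

`vmatqa` implements a patient-specific-QA (PSQA) prediction pipeline for
volumetric modulated arc therapy (VMAT): per-field feature extraction from
DICOM-RT inputs and daily linac performance logs, and a family of neural
models that predict the gamma passing rate (GPR) at four criteria
(3%/3mm, 3%/2mm, 2%/2mm, 1%/1mm) together with pass/fail at the 90%
universal action limit.  Because clinical PSQA data cannot be shipped, a
first-class synthetic-data module generates complete cohorts with known
planted structure; everything below states what the synthetic studies can
and cannot show about clinical data.

## Geometry and I/O conventions

Volumes are stored (z, y, x), 0-based, with voxel-center coordinates;
DICOM patient coordinates appear only at the I/O boundary.  Dose is carried
in cGy throughout (the dosimetric bin width is specified in cGy).  A voxel
belongs to a structure iff its center lies inside the contour polygon;
nested contours on a slice combine by the even-odd rule, so holes are
carved out.  Dose grids are resampled to the CT grid by trilinear
interpolation (exact for affine dose fields; voxels outside the dose
extent are zero).  Only single-frame CT series, 60-pair Millennium-120 MLC
geometries and axis-aligned orientations are supported.

## Plan-complexity features (C, 31 per field)

MU attribution uses the forward-interval convention: control point k
carries the cumulative-meterset increment to k+1 and the final control
point carries zero, so the weights sum to one exactly.  Jaw clipping is
applied before any area/perimeter computation.

* **MCS** — McNiven modulation complexity score with the VMAT adaptation:
  leaf-sequence variability (LSV) and aperture-area variability (AAV) are
  averaged over adjacent control points and MU-weighted.  The AAV
  denominator is the per-pair maximal extent (max right tip − min left
  tip) across the beam.
* **EM** — Younge edge metric with C1 = 0, C2 = 1: MU-weighted mean of
  (leaf-tip edge length)/area.  For a rectangle this is 2·height/area,
  so it grows as gaps narrow.
* **BI** — aperture irregularity P²/(4πA), MU-weighted.  The snapshot
  carries two boundary lengths: the exact union-polygon (staircase)
  perimeter, verified against a 0.1 mm rasterized edge walk, and a
  diagonal-smoothed length in which each leaf side merges with its tip jog
  into a hypotenuse.  BI uses the smoothed length: it is exact for
  rectangles (square → 4/π) and converges to the circumference for round
  apertures (circle → 1), whereas a staircase circle would sit at
  16/π² ≈ 1.62 at any leaf width.
* **BM** — Du beam modulation 1 − Σ muᵢAᵢ / A_union, with the union taken
  per leaf pair over interval unions.
* **MAD, MSAS20/MSAS10, AAJA, MAXJ, MUCP** and 17 descriptor features
  (total MU, control-point count, energy/FFF flags, machine and MLC codes,
  MU-weighted jaw positions, gap statistics, leaf travel, aperture-area
  summaries, LSV/AAV means) complete a fixed, versioned registry of 31
  names.  The registry is the single source of column order.

## Radiomic (R, 107) and dosimetric (D, 93) features

Preprocessing: crop to the PTV bounding box with a 10-voxel buffer;
fixed-bin-width discretization, level = floor((x − min)/w) + 1, with
w = 25 HU on CT and 25 cGy on dose; for CT only, voxels below −200 HU
(air cavities) are removed from the mask.  No image filters and no
resegmentation range are applied.  Families: shape (14, CT only),
first-order (18), GLCM (24), GLDM (14), GLRLM (16), GLSZM (16), NGTDM (5)
— the standard 3-D formulations, with texture matrices accumulated over
the 13 unique distance-1 offsets (symmetrized where applicable) and
features averaged over directions.  GLDM uses α = 0 with the dependence
size counting the center voxel; zones use 26-connectivity.

Degenerate-input conventions (all chosen so vectors stay finite):
correlation-type GLCM features are 0 at zero variance, MCC is 1 when
undefined, NGTDM coarseness is capped at 10⁶, and single-voxel masks set
axis-based shape features to 0.

The family counts give 107 radiomic and 93 dosimetric features.  Published
pipelines sometimes state 123 per modality; the discrepancy cannot be
reconstructed from family counts (and a 14-feature GLRLM is sometimes
named where the standard family has 16), so vectors are emitted at their
true lengths with an optional zero-pad to 123 for shape compatibility.

The shape mesh is built by marching cubes on a Gaussian-smoothed occupancy
field (σ = 0.8 voxels, iso-level 0.5).  A binary-mask surface
overestimates curved areas by ~10% through staircase bevels, and PTVs are
predominantly round; the smoothing restores curved-surface fidelity
(digital ball sphericity ≈ 0.99) at the cost of eroding sharp corners
(a 10³ cube measures ~14% low on area).  Tiny masks fall back to the raw
occupancy so the mesh always exists.

## Daily linac performance (L, 141 per day)

The registry (shipped as JSON, user-remappable) holds 21 scalar metrics —
isocenter size/offsets, beam output/uniformity/center changes, jaw
offsets, gantry/collimator/couch deviations, per-bank MLC means — plus
120 per-leaf MLC offsets.  The enumeration of the 141 names is a
documented stand-in: daily-check exports vary by installation, and only
the count and the metric families are fixed.  Model windows take the last
W = 30 calendar days ending at the most recent record on/before the QA
date (monthly QA cadence; configurable); missing days are forward-filled
and flagged, because machine state persists between checks.  Windows
depend only on records up to the QA date — no future leakage.
Standardization is z-scoring with training-split statistics only; constant
columns map to zero and are flagged.

## Models

All four architectures consume {L window, C, R, D} and emit four GPR
values plus four pass probabilities (one per criterion, so per-criterion
ROC analysis is possible).  They are implemented on a small reverse-mode
autodiff core over NumPy written for this package (verified against
central finite differences at 1e-4 relative end to end).

* **Informer-CNN** (primary): the window is projected to d_model = 256
  with sinusoidal positional and calendar encodings, then passes two
  encoder layers of 4-head ProbSparse self-attention with 512-d ReLU FFNs,
  residual connections and layer norm, with a distilling step (kernel-3
  conv → ELU → stride-2 max pool) halving the sequence between layers.
  ProbSparse attention scores each query by M(q) = max_k(qk/√d) −
  mean_k(qk/√d) and gives the top u = ⌈5·ln L⌉ queries a full softmax row;
  the remainder output the mean of V (encoder) or the running mean
  (causal decoder).  At u = L it equals dense attention exactly, which is
  the tested contract; at these window lengths the implementation
  evaluates the dense scores and applies the selection, so the sparsity
  is semantic rather than a speed optimization.  The decoder runs masked
  self-attention over a start token (the last W/2 embedded inputs) plus
  one placeholder, cross-attends the encoder output densely, and its final
  position is the temporal summary.  The summary is concatenated with
  C/R/D (256+31+107+93 = 487) and passed through the convolutional fusion
  stack — conv 3×3 → 5×5 → 3×3, 64 channels each, with ReLU, 2×2 average
  pooling and dropout 0.2 after each layer — before the two heads
  (FC+ReLU → 4 GPR values; FC → sigmoid pass probabilities).  The fused
  vector enters the stack as the channel axis of a 4×4 spatial grid
  (zero-padded): with many channels and few spatial positions the first
  convolution can form feature-specific linear combinations.  The
  single-channel square-image layout (pad 487 → 23², one channel) is kept
  as a configurable alternative, but it is demonstrably lossy here:
  spatially shared kernels apply one filter bank to every region of an
  arbitrarily ordered feature image, and in planted-signal studies that
  layout never recovered the signal (validation AUC near chance, MAE at
  the label standard deviation), while the channel layout does.
* **Informer** baseline: identical, with the convolutional stack replaced
  by the identity (fused vector straight to the heads); the test suite
  checks this ablation equivalence with shared weights.
* **LSTM** baseline: two stacked 128-unit layers over the window; last
  hidden state joins C/R/D at the heads.
* **CNN** baseline: every feature flattened onto one square grid through
  the same convolutional stack.

Open design points resolved here: only L is treated as temporal (C/R/D
join at fusion); the fusion layout (concat → pad → square grid) is one of
several defensible encodings and is isolated behind `latent()`; the loss
is the unit-weighted sum of MSE (GPR head) and BCE (pass head), since both
heads are described as trained jointly; sparse factor c = 5 and the W/2
start token follow the original long-sequence-transformer conventions.

Training: Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), lr 0.001 decayed ×0.95
every 20 epochs, batch 32, dropout 0.5 on fully connected layers and 0.2
in conv/attention blocks, L2 coefficient 0.01.  Three optimization details
matter and are deliberate:

* the L2 penalty is **decoupled** (AdamW-style) and applies to weight
  matrices only.  Folding l2·w into the Adam gradient lets the adaptive
  normalization turn the penalty into a constant ~lr shrink per step for
  any weakly driven weight, which silently zeroes saturated heads — a
  rare-class pass classifier collapses to its bias.  Decaying output
  biases would likewise pin the regression head an O(l2/gradient) offset
  below the label mean;
* pass-head biases start at the training-split class-prior log-odds, so
  heavily imbalanced criteria (3% pass at 1%/1mm) do not spend most of
  training crossing the sigmoid saturation plateau;
* regression targets are z-scored with training-split statistics
  (predictions transformed back), giving each criterion inverse-variance
  weight and keeping the MSE term commensurate with the BCE term —
  unweighted MSE on [0,1] labels is ~40× smaller than BCE and the shared
  trunk otherwise optimizes classification only.

Up to 100 epochs with best-validation checkpointing and early stopping
(patience 25 — the validation loss is noisy at ~137 held-out fields and
still drifts down past epoch 40 at full width); validation data never
contributes gradients.  All
randomness flows from integer seeds; runs are bit-reproducible on CPU.
Arrays are float32 for throughput; the autodiff core switches to float64
for gradient verification.

## Evaluation

RMSE, MAE and MAPE (percent; zero actual values are an error, since a GPR
of 0 indicates corrupt labels) per criterion; AUC by the rank
(Mann-Whitney) formulation with ties counted one-half, which equals
trapezoidal integration of the emitted ROC curve.  Pass ⇔ GPR strictly
above 0.90.  Splits are random at plan level, 70/15/15, so no plan's
fields straddle splits; field-level splitting is available but off by
default.

## Synthetic cohorts

The generator draws 465 plans / 915 fields over a 4-year span on three
machines (energy mix 86.5% 6MV / 13.5% 6MV-FFF at plan level).  Daily
machine state follows per-metric AR(1) drift (φ = 0.98) around registry
baselines with occasional recalibration resets (rate 1/180 days).
Complexity features load on one latent modulation factor with
field-realistic baselines (e.g. MCS decreases while EM/BI/BM increase
with modulation); R/D blocks use a fixed low-rank (3-factor) correlation
model.  The real covariance among clinical C/R/D features is unknown;
the low-rank model is a documented default, not an estimate.

Labels: a latent severity g = β_c·z_complexity + β_l·z_drift + ε
(β_c = β_l = 1, ε ~ N(0, 0.5) by default) is standardized and mapped
through the quantile function of a per-criterion two-component clamped
normal mixture whose five parameters are moment-matched (deterministically,
by least squares on numerically exact moments of the sampled distribution)
to the configured (mean, sd, pass-fraction) triple.  A single clamped
normal cannot reproduce the calibration triples jointly — at 3%/3mm the
printed mean/sd imply far fewer failures than printed — which is why the
mixture exists.  The drift score passes through a normal-scores transform
so the latent is exactly Gaussian and the marginals are calibrated in
distribution for any link strength.  Labels are floored at 0.5% (an exact
zero would be a corrupt measurement and breaks percentage errors).  The
generator also reports a per-criterion irreducible noise floor: the mean
absolute deviation of labels around their conditional mean given what is
*observable* — the linear-Gaussian posterior of the complexity factor
given the C row (the factor is only partially identifiable from noisy
loadings; posterior sd ≈ 0.28 at the defaults) and the drift score, which
is a deterministic function of the window.  It is estimated with 64 fresh
residual replicates per field.  Conditioning on the unobservable latent
itself would understate what any model could achieve.

The noise default (ε sd 0.5 against a combined signal sd of √2) makes the
planted structure carry ~89% of latent variance: strong enough that a
correctly implemented model must recover it (held-out linear probes on
the true scores reach AUC ≥ 0.9), weak enough that regression error has a
meaningful floor.  What passing these tests shows: the pipeline wiring,
standardization, and optimization can extract a known monotone
complexity/drift signal at clinical scale.  What it does not show:
clinical effect sizes, real feature covariance, detector/measurement
physics, or temporal nonstationarity of real linacs — the published
clinical accuracy numbers are not reproducible from synthetic data and
are not targets of this package.

## Problem sizes and numerics

Default synthetic studies run at the cohort's native scale (915 fields,
W = 30) with the full model width (d_model = 256); the structural test
suite uses reduced widths (d_model = 32, W = 8) chosen to exercise every
code path quickly.  Texture-feature oracles enumerate volumes up to 6³
where dense loops are exact.  Mixture calibration residuals are required
below 0.05 percentage points on mean/sd and 0.5 points on the pass
fraction; quantile maps use a 4001-point grid on [0, 100].
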