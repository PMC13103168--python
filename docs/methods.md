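# Methods

## Problem and model

`ganscreen` screens grayscale medical images for out-of-distribution (OOD)
inputs — concretely, the chest-radiograph view problem: a model trained to
read frontal (posterior-anterior) films should refuse lateral films rather
than silently misread them.  The detector has three stages:

1. **Generative model of the in-distribution class.**  A compact
   convolutional GAN is trained on in-distribution images only.  The
   generator G maps a latent vector z ~ N(0, I_d) (d = 100) through
   transposed-convolution / batchnorm / ReLU blocks from a 4×4 seed up to
   the working resolution, ending in Tanh, so G(z) ∈ (−1, 1)^{H×W}.  The
   discriminator mirrors this with strided convolutions, batchnorm and
   LeakyReLU(0.2), ending in a sigmoid.  Both networks train with binary
   cross-entropy and Adam (lr 0.001, betas (0.5, 0.999)) for 999
   alternating steps; the generator uses the non-saturating objective.
   Weights are initialized N(0, 0.02) for convolutions and N(1, 0.02) /
   0 for batchnorm scale/shift.

2. **Latent inversion.**  A test image X is reconstructed by minimizing
   the mean squared pixel difference L(z) = ‖G(z) − X‖² / (H·W) over z
   alone (Adam, lr 0.001, generator frozen in evaluation mode so it is a
   fixed deterministic map).  Optimization stops when L first crosses a
   loss threshold τ, then runs a fixed number of extra refinement steps;
   if τ is never reached within the step budget the image is declared OOD
   outright — failure to reconstruct is itself OOD evidence, and the
   result records this route in `failure_mode`.

3. **Distributional test.**  When the threshold is reached, the pixel
   intensity distributions of G(z_final) and X are compared with a
   two-sample Kolmogorov–Smirnov test; the image is in-distribution iff
   p ≥ α (default 0.05).

The mean (not sum) squared loss keeps τ on an O(0.1) scale independent of
resolution, matching the natural operating range explored by the
evaluation harness (τ ∈ 0.05–0.4).

## The K–S stage and pixel correlation

The two-sample statistic D = sup_x |F̂₁(x) − F̂₂(x)| is computed from
first principles: both one-sided ECDF gaps are evaluated at every pooled
jump point, so heavily tied (quantized) samples never under-estimate D.
The p-value uses the asymptotic Kolmogorov series
Q(λ) = 2 Σ_{k≥1} (−1)^{k−1} e^{−2k²λ²} at λ = √(n₁n₂/(n₁+n₂))·D,
truncated below 1e−12 and clamped to [0, 1].  No small-sample continuity
correction is applied; intended sample sizes are in the hundreds.

Adjacent pixels of natural and generated images are strongly correlated,
so feeding all H·W pixels to the test as if i.i.d. grossly overstates the
effective sample size: at 64×64 the α = 0.05 critical distance is
D ≈ 0.03, and even visually excellent reconstructions (MSE ~ 5e−3) get
rejected wholesale.  The detector therefore evaluates the test on a
deterministic spatial subsample of stride 4 in each axis (256 pixels per
image at 64×64), spacing samples beyond the decoder's correlation length.
`InversionConfig.ks_stride = 1` restores the literal every-pixel reading.

## Extra-step semantics and caching

"Extra steps" counts refinement iterations executed *after* the loss
first crosses τ (the alternative reading — a total budget of 60–100
steps — is implausibly small for Adam at lr 0.001, which needs hundreds
of steps to converge).  Because τ only decides where the optimization
trajectory is cut, never how it evolves, a single run to `max_steps` can
be re-read under any (τ, extra-steps) pair; `invert_trajectories` exploits
this to sweep thresholds with one optimization per image, and a test
asserts the cached decisions equal direct inversion.  Evaluation-mode
batchnorm makes batch elements independent, so batched inversion is
step-for-step equivalent to one-at-a-time runs (up to float32 last-ulp
accumulation, checked at tight tolerance).

## Synthetic phantoms

Clinical radiographs are credential-gated, so the package ships a
procedural phantom family per view at matched resolution:

* **frontal**: exactly left-right symmetric template — two dark elliptical
  lung fields flanking a bright vertical mediastinal band, shoulder
  girdle, smooth radial intensity falloff;
* **lateral**: strongly asymmetric — one dominant dark lobe (the
  superimposed lungs), an off-center bright spine band, a diaphragm
  wedge, decentred falloff.

All primitives are analytic Gaussians / super-Gaussians on a [−1, 1]²
grid whose coordinates are exactly antisymmetric in floating point, so
the jitter-free frontal template mirrors bitwise.  Two noise knobs
emulate acquisition variability: `jitter` (default 0.10) perturbs feature
positions, widths and amplitudes per sample — the anatomical variation a
GAN must absorb — and `noise_sigma` (default 0.02, i.e. ~1% of the
dynamic range, radiograph-realistic) adds white Gaussian pixel noise.
Backgrounds fall off smoothly rather than sitting at a constant level:
real films have no exactly flat regions, and a flat field concentrates
the intensity histogram into a near point mass, which would make *any*
marginal distribution test pathologically sensitive (a 0.07-RMSE
reconstruction error can displace a third of the CDF mass).  The phantom
histograms instead spread over the full range (max 5%-window mass ≈ 0.14).

What the phantoms do **not** emulate: anatomical texture (bones, vessels,
devices), pathology, detector artifacts, or the long-tailed intensity
statistics of DICOM pipelines.  Passing tests therefore demonstrate the
*mechanics* of the method — training, inversion, calibrated testing,
threshold behaviour — on a clean separable problem; they do not certify
clinical performance, and thresholds tuned here do not transfer to real
data.

## Desk-scale study conditions

Test and acceptance runs use sizes chosen for a single CPU: 200 frontal
training phantoms at 64×64; generator/discriminator width
`base_feature_maps = 16` and batch 16 (library defaults stay at the
canonical 64/64); 999 training steps; inversion budget `max_steps = 400`
with 95 extra steps; threshold sweep {0.05, 0.10, 0.15, 0.20, 0.30};
held-out evaluation on 20 + 20 phantoms; a disjoint 20 + 20 calibration
split for baseline threshold search.  The inversion optimizer is Adam at
lr 0.001 with standard betas (0.9, 0.999).

## Baselines

* **Canny score**: fraction of pixels marked by the classical Canny
  operator (delegated to scikit-image) on the [0, 1]-rescaled image;
  σ = 1, hysteresis thresholds 0.1/0.2.
* **Histogram score**: intersection Σ min(h_img, h_ref) between the
  image's 32-bin normalized histogram on [−1, 1] and the mean histogram
  of in-distribution calibration images; low intersection is OOD-like.

Each score is thresholded by an F1-maximizing grid search over the
2nd–98th calibration-score percentiles (49 points); ties prefer higher
precision, then the smaller threshold.  Threshold selection uses a
labeled calibration split containing both classes (F1 cannot be computed
from one class alone).

## Numerical choices and degenerate inputs

* All network arithmetic is float32; convolutions run as single BLAS
  GEMMs over im2col patch matrices, and transposed convolution is the
  exact adjoint (col2im) of the matching convolution — backward passes
  agree with float64 central finite differences to 1e−4 relative.
* Binary cross-entropy is computed on logits (log1p formulation), so
  saturated discriminator outputs cannot produce non-finite losses; any
  non-finite loss raises a divergence error naming the step.
* Batchnorm: momentum 0.1, eps 1e−5; inversion always runs the generator
  in evaluation mode with frozen running statistics.
* ANOVA: F = (SS_between/df_b)/(SS_within/df_w) with p from the F upper
  tail; all-identical data gives F = 0, p = 1, and zero within-group
  variance with between-group variation gives F = +∞, p = 0 by
  convention.
* Metric conventions (OOD positive): precision/recall/F1 are 0 when their
  denominators vanish; rounding to 3 decimals happens only at reporting.
* Disk images are 8-bit PNG; the affine [−1,1] ↔ [0,255] map rounds half
  up, making both endpoints exact and the round trip accurate to 1/255.

## Known limitations

* The K–S stage tests the *marginal* intensity distribution only; an OOD
  image with coincidentally matching histogram passes the statistical
  stage and is caught only by the reconstruction-threshold route.
* The asymptotic p-value is conservative for samples under ~50 values;
  the detector never operates there, but `ks_two_sample` callers might.
* The phantom separation is easier than real frontal/lateral
  discrimination; measured accuracies here are mechanics checks, not
  clinical estimates.
* Inversion is non-convex; a single restart suffices on phantoms, and
  `restarts` is exposed for harder data.
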