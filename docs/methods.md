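# Methods

`lesionsr` implements a lesion-focused super-resolution (SR) framework for
CT together with the downstream methodology for judging whether SR helps or
hurts the stability of radiomic texture features. This note documents the
models, the conventions that had to be fixed where more than one reasonable
choice existed, and what the synthetic phantoms do and do not demonstrate.

## Degradation model (LR/HR pair construction)

High-resolution CT slices are windowed to [-100, 400] HU (a soft-tissue
diagnostic window) and mapped affinely onto [0, 1]. The low-resolution
counterpart of a patch is produced on the *same pixel grid* by, in order:

1. additive Gaussian white noise, sd 0.25 on the normalised scale, clipped
   back to [0, 1];
2. Gaussian blur with an 8x8 kernel, bandwidth sigma = 1.6;
3. 2x decimation (top-left pixel of every block; the blur acts as the
   anti-alias filter);
4. nearest-neighbour upsampling back to the original shape.

Conventions that the even-sized kernel and integer resampling force:

* an 8x8 kernel has no centre pixel; the anchor is the top-left element of
  the central 2x2 block, the kernel is normalised to sum one, and reflect
  padding is used — deterministic and shape-preserving;
* image sides not divisible by the scale are reflect-padded up before
  decimation and the upsampled result is cropped back;
* whether noise precedes blur is genuinely ambiguous in descriptions of
  such pipelines; this package fixes noise -> blur (the panel order of the
  pipeline it reproduces) and treats "nearest neighbour" and "proximal"
  interpolation as the same operation.

## Super-resolution model

The SR model is a cycle-consistent GAN with two same-architecture
generators (G: LR -> HR appearance, F: HR -> LR appearance) and two
same-architecture discriminators (D_HR, D_LR), i.e. the minimax problem

    min_{G,F} max_{D_HR,D_LR}  L_GAN(G, D_HR) + L_GAN(F, D_LR).

Because LR patches are pre-upsampled onto the HR grid, both generators are
same-grid mappings: twelve 3x3 conv + bias + LeakyReLU(0.1) + dropout
feature blocks whose outputs are all concatenated (dense skips), a
two-branch network-in-network reconstruction head, a stride-2 convolution
paired with a stride-2 transposed convolution (so the net output grid
equals the input grid; odd sides are padded to even and cropped back), and
a final merging convolution. Default filter counts taper 64 -> 16 across
the twelve blocks and are configurable.

The discriminators use four 4x4 conv blocks (strides 2,2,1,1) with
instance normalisation and LeakyReLU(0.1), a spatial-pyramid max-pooling
(SPP) layer with levels (4, 2, 1), and two dense layers. SPP tiles the
final C-channel feature map into l x l near-equal cells per level
(boundaries at floor(c*size/l)) and takes per-cell maxima, giving a
descriptor of fixed length C * sum(l^2) = 21C for any admissible input
size — this is what lets patches of different sizes train one network.
The minimum input side (24 with the default strides) is reported in the
rejection message for smaller inputs.

The training objective is the four-term composite

    L = L_Adv(D_HR, G) + L_Adv(D_LR, F)
        + lambda1 * L_Cyc(G, F) + lambda2 * L_IDT(G, F) + lambda3 * L_JST(G)

with lambda1 = 1, lambda2 = 0.5, lambda3 = 1e-5. Choices fixed here:

* **Adversarial form.** The least-squares (LSGAN) objective: D is driven
  toward 1 on real and 0 on fake, the generator term is mean (D(fake)-1)^2.
  It is stable on small batches without gradient penalties; the form is a
  config decision, not hard-coded.
* **Cycle / identity losses** are l1: |F(G(lr))-lr| + |G(F(hr))-hr| and
  |G(hr)-hr| + |F(lr)-lr| respectively.
* **Joint sparsifying term** is the anisotropic total variation of G's
  output (mean |horizontal difference| + mean |vertical difference|),
  the classic sparsifying transform for denoising.
* **Dropout rate 0.8** is implemented literally as the fraction dropped
  but configurable: 0.8 as a drop-fraction is unusually aggressive, and
  "initialised with the rate" is ambiguous between keep- and
  drop-probability. Both readings are supported via the config value.
* **Weight init.** Zero-mean Gaussian with sd sqrt(2/m), m = f^2 * n_f
  (filter size f, filter count n_f) — the He rule. The literal variant
  sd = 2/m is selectable (`init_rule="2_over_m"`); the printed "2/m"
  appears alongside a citation of the He rule, so the square-root form is
  the default.
* **Optimisation.** Adam with beta1 = 0.5, beta2 = 0.9, batch 16,
  discriminator learning rate gamma_D = 1e-5 and generator rate
  gamma_G = gamma_D / 2 (the two time-scale update rule); one
  discriminator update and one generator update per batch (TTUR here is
  the learning-rate ratio, not an update-count ratio). Training histories
  record every objective term per epoch; non-finite losses abort with the
  offending term named.

4x SR is obtained by composing the 2x generator with itself
(`super_resolve(..., passes=2)`).

The networks run on a small reverse-mode autodiff engine written on numpy
(`lesionsr.nn`): broadcast-aware arithmetic, im2col convolutions, a
transposed convolution expressed as zero-upsampling plus a flipped-kernel
convolution (so its gradient falls out of the graph), instance norm
composed from primitive ops, and SPP max pooling with argmax scatter in
the backward pass. Float32 throughout; checkpoints are a single zip
archive (JSON header + one .npy per weight) and round-trip bit-exactly.

## Image-quality evaluation

PSNR is 10 log10(range^2 / MSE), with identical images reported as
infinite (flagged, never capped). SSIM is the standard single-scale form
with an 11x11 Gaussian window (sigma 1.5) and constants k1 = 0.01,
k2 = 0.03 on the declared range; the window and constants are unstated in
many SR papers, so the canonical defaults are adopted and documented.
The interpolation baseline is separable Catmull-Rom bicubic (a = -0.5),
half-pixel-centred, with reflect boundaries — it reproduces linear ramps
exactly away from the border, which the tests exploit as an analytic
check. Method comparisons use two-sided Mann-Whitney U tests on per-image
scores (exact for tie-free samples up to n = 20, otherwise the normal
approximation with tie correction) with Benjamini-Hochberg adjustment at
alpha = 0.05.

## Radiomic texture features

Seventy-five 3D texture features are computed in five matrix families —
GLCM (24), GLDM (14), GLRLM (16), GLSZM (16), NGTDM (5) — following the
IBSI-aligned formulations used by the common reference extractor. Shape
and first-order features are excluded by design: they do not depend on
gray-level rebinning, which is the variable under study. No resampling
and no image filters are applied.

* **Quantization** is fixed-bin-count equal-width over the ROI's own
  min-max: width (max-min)/N_g, level floor((v-min)/width)+1, with the
  maximum closed into bin N_g. A constant ROI maps to level 1 and carries
  a degeneracy flag. Note this is invariant to increasing *affine*
  intensity transforms but not to general monotone ones.
* **Directions.** GLCM and GLRLM accumulate over the 13 unique direction
  vectors of the 26-neighbourhood symmetrically, compute each feature per
  direction, and report the unweighted mean. GLDM/NGTDM use the full
  26-neighbourhood at distance 1 (GLDM similarity tolerance alpha = 0);
  GLSZM zones are 26-connected components of constant level.
* **GLDM indexing.** The matrix column indexes the dependent-neighbour
  *count* (0 for an isolated voxel); emphasis formulas use dependence
  size = count + 1, matching the reference extractor's feature values
  while keeping the isolated-voxel row at zero.
* **Degenerate ROIs** yield documented sentinels instead of NaN:
  GLCM Correlation/MCC = 1, IMC1/IMC2 = 0, NGTDM Contrast/Busyness/
  Strength = 0, Coarseness capped at 1e6.

## Robustness methodology

For each feature, stability across k repeated measurement settings
(n subjects x k settings) is the two-way mixed-effects, consistency,
single-measurement intraclass correlation

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)

where MS_R is the between-subject mean square and MS_E the residual mean
square after removing row and column effects; systematic column shifts
(e.g. every feature rising with bin count) therefore do not count against
a feature. An all-constant table has no defined ICC and is reported as NA
with a reason. Features are banded Poor (<= 0.5), Moderate (<= 0.75),
Good (<= 0.9), Excellent (> 0.9).

The two uses never mix: ICC over rebinnings uses the k = 6 bin settings
{8, 16, 32, 64, 128, 256}; ICC over contour perturbation uses the k = 3
ROI versions (original, opened, closed) produced by morphological opening
and closing with the discrete radius-1 ball — the 7-voxel face-connected
cross, the only discrete sphere of exactly 1 voxel radius. The closing is
computed on a 1-voxel-padded array so the extensivity law
opened <= original <= closed holds at the volume border. The optimal bin
count is the one whose perturbation-ICC yields the most Excellent
features, ties broken toward fewer bins, selected on original (never
super-resolved) images — the conservative choice. "Robust" in this
selection means Excellent, the band the comparative analyses use.

Feature importance is PCA-based and task-agnostic: eigendecomposition of
the feature correlation matrix (features implicitly z-scored), PCs sorted
by eigenvalue, and per-feature importance the quadrature sum over the
first three PCs. The source methodology says both "weighted average" and
"quadrature sum"; both readings are implemented —
sqrt(sum_i lambda_i v_ij^2) (eigenvalue-weighted, default) and
sqrt(sum_i v_ij^2) (unweighted) — with the weighted form as default since
it honours the weighting language while keeping the quadrature structure.
The variance fraction of the first three PCs is reported so the
"at least 85% of the trace" adequacy condition can be checked.
Zero-variance features are dropped with a log entry.

A packaged 13-feature x 3-group reference ICC matrix (Original / Bicubic /
GAN-SR, published values) drives the comparative report: per-group
Excellent counts, strict per-feature winners, and percent relative
differences 100 (ICC_test - ICC_ref) / ICC_ref. The fixture maps the
alias "IDN" == "ID" onto a single feature (`GLCM_Idn`).

## Synthetic phantoms and what they show

The phantom module generates HU-valued volumes with a spherical lesion
(background ~ -50 HU, lesion ~ 100 HU) whose interior carries a
stationary Gaussian random-field texture (smoothed white noise,
correlation length ~ 2 voxels, amplitude ~ 40 HU) — continuous gray
levels that respond to rebinning the way real tumour texture does, which
is exactly what the robustness analysis needs. Blob and checkerboard
texture models exist for constructing degenerate cases. Default HU levels
make the [-100, 400] window informative.

Cohorts add a per-subject lesion-intensity offset a_j ~ N(0, sigma_b^2)
and a per-replicate scalar offset eps_jk ~ N(0, sigma_w^2) (calibration-
drift style), so a mean-intensity statistic is exactly mu + a_j + eps_jk
and its consistency ICC has the closed form sigma_b^2 / (sigma_b^2 +
sigma_w^2). A 3:1 variance ratio therefore predicts ICC = 0.75, which the
parameter-recovery tests verify by simulation at n = 500 subjects, k = 6.

Phantoms are not anatomically realistic CT: no organs, no scanner or
reconstruction-kernel physics, no partial-volume effects, no HU
calibration drift across vendors. Passing tests demonstrate that the
*machinery* (degradation, training dynamics, feature mathematics, ICC,
selection, ranking) is correct and internally consistent — not that any
particular robustness conclusion transfers to clinical CT.

## Training benchmark sizing

The package's training benchmark (`lesionsr.benchmark`) asks a deliberately
modest question: after ten epochs on 200 synthetic 32x32 pairs (batch 16),
does the generator restore degraded patches better than leaving them
untouched, i.e. median held-out PSNR(G(lr), hr) > median PSNR(lr, hr)?
For minutes-scale single-core training the benchmark uses a narrow
variant of the same architecture family (four feature blocks tapering
16 -> 8, reconstruction branches 8/4, dropout 0.1, discriminators
8/16/16/16) and Adam rates gamma_D = 4e-3, gamma_G = gamma_D / 2 — at the
full-scale default of gamma_D = 1e-5, ten epochs of any architecture
moves the weights imperceptibly.

Two properties of the objective shape the benchmark protocol. First, the
four-term loss is *unpaired*: nothing in it directly minimises
|G(lr) - hr|, so PSNR gains come from the adversarial denoising pressure
on G, not from supervised regression. Second, per-epoch diagnostics show
the adversarial game does not converge monotonically — held-out quality
typically rises past the degraded-input baseline mid-run and then
oscillates. The benchmark therefore applies standard keep-best model
selection: after every epoch the generator is scored (median PSNR) on a
40-pair validation subset of the *training* pairs and the best epoch's
weights are the trained model; the 50 evaluation pairs are never used
for training or selection. The outcome remains stochastic, so the
acceptance check uses a three-seed majority. An optional linear
learning-rate decay (`TrainConfig.lr_decay="linear"`) is available for
longer runs. Full-scale training (12 blocks, 64 -> 16 filters, 100
epochs, 10,000 patches) is out of desk scope and its image-quality
numbers are not reproduced here.

## Known limitations

* The numpy autodiff engine is single-threaded and CPU-bound; it is meant
  for correctness and small benchmarks, not production training.
* GLCM/GLRLM features are direction-averaged only (no distance weighting
  options); quantization offers fixed bin *count* only, as that is the
  variable the robustness analysis sweeps.
* The exact filter schedule of the original cycle-consistent SR generator
  is inherited by name, not by weights; defaults here (64 -> 16 taper)
  are config-overridable.
* ICC assumes the two-way model without subject-by-setting interaction;
  with k = 3 contour versions the residual absorbs any interaction.
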