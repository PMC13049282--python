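# Methods

`renalmpr` implements an automated post-processing pipeline for
multiparametric renal MRI: contrastive-pretrained 2-D U-Net segmentation
of kidney / cortex / medulla, pairwise affine + non-rigid registration of
every contrast onto a Dixon reference, propagation of Dixon annotations
to low-contrast maps, and quantitative volume / region-mean extraction,
together with the full evaluation-metric suite.  This note records the
models, the assumptions, and the choices made where the design was
genuinely open.

## The phantom: what it emulates, and what it does not

No study data ship with the package.  The `phantom` module generates
synthetic multiparametric studies: two ellipsoidal kidneys per volume
with a cortical shell, sinusoidally lobed medulla and a medial pelvis
(excluded from the parenchyma labels); one volume per contrast (Dixon,
T1, T2, T2*, RBF, ADC) with contrast-specific mean intensities —
strongly separated cortex/medulla for Dixon/T1/T2/T2* and
near-isointense (gap < 1 noise SD) for RBF/ADC, emulating why
perfusion/diffusion maps cannot be sub-segmented directly; additive
Gaussian noise; and per-contrast misalignment composed of a random
in-plane affine (translation, rotation, isotropic scale, drawn uniformly
from configurable bounds) and a Gaussian-smoothed white-noise
deformation rescaled to a requested peak amplitude.  Default geometry is
32×256×256 at 3×1.5×1.5 mm (slice, row, col); a fast 8×64×64 preset
(`PhantomSpec.tiny`) serves the test and acceptance harnesses.

Anatomy is defined by closed-form ellipsoid membership, so a misaligned
contrast is rendered by evaluating the anatomy at transformed
coordinates `T(x) = A(x + u(x))`.  Its label mask is therefore exact,
and the stored ground-truth field `u_true = T − id` satisfies
`warp(reference_mask, u_true) ≈ contrast_mask` up to nearest-neighbor
discretization (volume Dice ≥ 0.99 at the default resolution, ≥ 0.96 at
the tiny preset, where boundary voxels are a larger fraction of the
kidney).  A registration network warps the *moving* image onto the
reference, i.e. it should recover the *inverse* of the stored field;
recovery harnesses compare predictions against the fixed-point inverse
of the truth (closed-form for pure translations).

What the phantom does **not** model: MR physics (no Bloch equations, no
ASL kinetics), through-plane motion (deformations are per-slice 2-D, as
is the network family), anatomy variability beyond the affine/deformable
perturbations, and realistic artifact structure.  Passing phantom
harnesses therefore demonstrates that the machinery — losses, field
algebra, training loops, propagation, quantification — is correct and
recovers known ground truth, not that the shipped defaults reach any
particular accuracy on acquired patient data.

## Networks

All stages share one configuration-driven 2-D U-Net family
(`backbone`): encoding depth 5 (4 downsamplings), two 3×3 convolutions
per level starting at 16 kernels and doubling after each 2×2 max-pool to
256 at the bottleneck, mirrored decoder with 2×2 nearest-neighbor
upsampling, leaky-ReLU (slope 0.01) and batch normalization after every
convolution (conv → norm → activation), and additive residual skips
between encoder and decoder blocks at equal resolution.  Two
convolutions per block and the conv→norm→activation order are package
choices where the block internals were unspecified.

The affine head consumes the bottleneck features through a 1×1
convolution (16 channels), 2×2 max-pool, flatten, dense(16) and
dense(6).  The 6 outputs are *deltas* about the identity
(`A = I + dA`, translation `b`), so the zero-initialized final layer
starts the network exactly at the identity transform, and the identity
encoding maps to the zero displacement field.  The non-rigid head
appends two 3×3 convolutions of 16 and 2 filters with a ReLU between;
its final layer is zero-initialized so training starts from zero
displacement.

Because the target environment is CPU-only scientific Python, the
networks and their training run on a compact reverse-mode automatic
differentiation engine inside the package (`renalmpr.nn`): float64
numpy kernels, im2col convolutions, and hand-written backward closures
for the fused operations (convolution, pooling, batch normalization,
bilinear grid sampling).  Every backward closure is finite-difference
checked in the test suite.  The engine favours exact seeded
reproducibility over throughput; the full-size configuration trains the
same way as the tiny one, only slower.

## Contrastive pre-training (constraint maps)

T2 and T2* slices are stacked per pixel, reduced by PCA (P = 20 retained
components; with only two source channels fewer survive) and clustered
by k-means (K = 4, k-means++ with 10 restarts, fixed seed) into a
constraint map.  Cluster indices are canonicalized by ascending mean
channel intensity so labelings are stable under channel permutation.
100 random 4×4 patches per slice are labeled by the dominant cluster in
their window (ties to the lowest index).  A two-layer 1×1-conv
projection head embeds the U-Net decoder output into N = 64 channels;
pixel embeddings are L2-normalized, patch embeddings are window means
re-normalized.  The loss is the supervised-contrastive form over patch
embeddings with temperature τ = 0.1: anchors attract same-label patches
against all others; anchors without positives are skipped.  The cited
description leaves the exact functional form to its reference, and
which channels enter the pixel-wise PCA is configurable
(`sources=`) because the source text does not pin it down.

After pre-training the projection head is dropped; encoder/decoder
weights initialize the segmentation networks (the fresh segmentation
head keeps its own initialization).

## Segmentation

Two schemes: 3-class (background, left/right kidney) trained on all
contrasts, and 5-class (background, left/right medulla and cortex)
trained on all but ADC, whose cortico-medullary contrast does not
support labels.  The loss is class-weighted Tversky with α = 0.3
(false-positive penalty) and β = 0.7 (false-negative penalty), smoothing
ε = 1e-6 in numerator and denominator (preventing empty-class NaNs);
with α = β = 0.5 it reduces exactly to the soft-Dice complement
(oracle-tested).  Class weights are inversely proportional to label
frequency, normalized to sum to the class count, with a floor frequency
of 1e-6 for absent classes.  Optimization is Adam at initial lr 0.01
with polynomial decay `lr·(1 − t/T)^0.9`; the source description pairs
this rate with a Nesterov momentum, which Adam does not have — the
package reads it as Adam + the stated schedule.  Full-scale defaults are
500 epochs × 250 iterations; the harnesses use reduced budgets (the
package's scaled-down study conditions, below).  On-the-fly augmentation
(rotation ±15°, scale 0.85–1.25, small elastic field, brightness ±0.2,
contrast 0.8–1.2) runs from a seeded stream; the transform families are
prescribed, the ranges are package defaults.  Foreground Dice on
held-out slices is the validation metric and the best-validation
checkpoint is returned.  Inference is per-coronal-slice softmax-argmax
(ties to the lower class index) with restoration to native geometry
through the recorded crop/pad/resample bookkeeping.

## Registration

Every contrast is registered pairwise to Dixon through a shared-weight
two-channel (fixed, moving) network — chosen over a joint N+1-channel
formulation for robustness to missing contrasts.  The affine stage is
trained on `−NMI + (1 − softDice)` over the left/right kidney masks; the
non-rigid stage (affine frozen, its output the network input) on

    L = L_NMI + λ1·L_DSC + λ2·L_smooth + λ3·L_consistency,
    λ1 = 1, λ2 = 0.1, λ3 = 100.

* **NMI.**  `2·MI/(H_fixed + H_warped)` per pair.  Evaluation uses a
  hard-binned plug-in estimator (32 bins, quantile edges; discrete data
  with ≤ 32 distinct values get one bin per value, making the estimator
  exact there and invariant under strictly monotone intensity remaps).
  Training uses a differentiable Parzen soft-binning (Gaussian kernel,
  σ = half a bin width, min–max scaled).  Degenerate constant images:
  NMI defined as 1 for two constants, 0 for one, with a warning.
* **Dice guidance** uses the ground-truth masks of both images during
  training (phantom labels here); no masks are needed at inference.
  It covers the two kidney classes only, matching the stated
  left/right-kidney overlap role.
* **Smoothness** is the mean absolute forward-difference gradient of
  the displacement, averaged over all difference entries, both channels
  and the field set.
* **Consistency** compares each affine-corrected moving image with its
  forward-then-inverse warp (mean squared error).  The inverse is the
  fixed-point iteration `v ← −u(x + v(x))` (bilinear, border-
  replicated), treated as a constant during backpropagation; if the
  iteration diverges mid-training (transient folding) the first-order
  inverse `−u` substitutes, and the large λ3 penalty pushes the field
  back toward invertibility.  The bi-warped image is compared against
  the affine-corrected moving image (the non-rigid stage's actual
  input) — the open alternative (raw moving) would mix affine error
  into a term meant to regularize the deformable stage.

Displacement convention everywhere, including NIfTI export: backward /
sampling, in pixels — `warped(x) = moving(x + u(x))`; fields are
per-slice 2-D with channel 0 the row displacement.  Composite fields
are `u_aff ∘ (id + u_def) + u_def`; their fixed-point inverses propagate
the Dixon 5-class mask into each contrast's frame by nearest-neighbor
warping.  The strict fixed-point iteration aborts with a folding
diagnosis if its update grows three iterations running; inference falls
back to a damped (relax = 0.5) iteration and, failing that, to the
first-order inverse with a logged warning.  The inverse-of-inverse
residual is limited by bilinear interpolation of the field (~2e-3 px on
smooth 48² fields), not by the iteration tolerance.

## Quantification

Volumes (mL) are voxel counts × voxel volume from the Dixon 5-class
mask, per side and combined; kidney = cortex + medulla holds exactly by
construction (the pelvis is excluded from the parenchyma).  Region
means are taken on native (unnormalized) intensities — z-scored data
are never quantified — with NaN voxels excluded and counted, and empty
regions reported as missing rather than zero.  High-contrast maps use
their direct 5-class segmentations; RBF and ADC use the propagated
Dixon masks, and every row records its mask provenance.

## Evaluation metrics

Dice (both-empty defined as 1 with a warning, single-empty 0),
symmetric boundary Hausdorff distance in physical mm (strict maximum by
default, 95th-percentile variant available), the hard-binned NMI above,
the percentage of non-positive `det(I + ∇u)` (central differences,
one-sided at borders), and a PCA deformation index over an aligned
series: eigendecompose the L×L correlation matrix of the vectorized
images and report the *residual* spectrum Σ_{j>K} λ_j (0 for a
perfectly coherent series, → L−K for independent images; lower is
better).  The printed description of this index as a top-K eigenvalue
*ratio* is bounded by 1 and increases with alignment, which contradicts
both the reported magnitudes (~2.6) and the lower-is-better direction;
both functionals are implemented, the residual form is the default, and
the discrepancy is documented rather than resolved.  Agreement
statistics are bias, Bland–Altman limits of agreement
(bias ± 1.96·SD of differences), ICC(2,1) — two-way random effects,
absolute agreement, single measures, the form left unnamed in the
source — with an F-based 95% CI, cross-checked against an independent
implementation in the tests, and Pearson r.

## Preprocessing conventions

Resampling to 1.5×1.5×3 mm uses third-order splines for images and
nearest neighbor for masks, with grid size `round(extent/spacing)` and
endpoint-aligned coordinates; percentile clipping to [0.05, 99.5] uses
the linear-interpolation order statistic; z-scoring uses post-clipping
statistics (clip, then normalize — the order was unstated); coronal
slices are zero-padded centered on a 256×256 canvas, and the crop/pad
record restores native geometry exactly.  Constant volumes normalize to
zeros with a degenerate-input warning.  Masks can never gain labels
anywhere in the module.

## Scaled-down study conditions

The harnesses run the full method at reduced size so the entire suite
executes on one CPU core: 8×64×64 phantoms, depth-3 / 4-channel network
configs, and training budgets of 250–350 iterations (registration),
~320 iterations (segmentation) and 150 iterations (pre-training), all
seeded.  At these sizes the affine stage recovers ≤ 8 px / ≤ 10°
misalignments to < 2 px mean endpoint error, affine + non-rigid
registration lifts warped-mask volume Dice from ~0.8 to ≥ 0.93 with no
folding, held-out kidney Dice on noise-free phantoms exceeds 0.99, and
propagated masks beat direct 5-class segmentation of the low-contrast
channel by a wide margin — every number recomputed at run time by
`scripts/acceptance.py` and the acceptance tests, never asserted as a
constant.

## Known limitations

* 2-D only: no 2.5-D or 3-D variants, and slice correspondence across
  contrasts is by index on the common resampled grid.
* The consistency and warping operators use zero (image) / background
  (mask) borders; fields that sample far outside the grid incur border
  error, which the loss does not mask out.
* The autodiff engine is single-threaded float64 numpy; full-size
  (256², depth-5) training is functional but slow — the shipped
  defaults document the full-scale schedules without reproducing their
  wall-clock.
* Tie-breaks are fixed and documented (argmax → lower class index;
  patch majority → lower label), which matters only on synthetic data
  with exact ties.
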