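# Methods

This note documents the models, the synthetic data, the numerical choices,
and the open design decisions behind `neurofuse`.  It states no empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Synthetic paired-modality cohorts

The pipeline targets cohorts pairing two preprocessed scalar 3-D brain maps
per subject (modality A ~ gray-matter density, modality B ~ FDG-PET) with a
diagnostic label in {AD, MCI-C, MCI-NC, NC}.  Such cohorts are
access-restricted, so the generator emulates the ingredients the method is
sensitive to rather than the anatomy:

- **Severity axis.**  Disease is a single ordinal latent direction:
  NC = 0, MCI-NC = 1, MCI-C = 2, AD = 3.  The shared latent of subject *i*
  is `t_i = shared_effect · severity(label) · e₁ + modality_noise · z_i`
  with `z_i ~ N(0, I)`.  Tying the benign per-subject dispersion to
  `modality_noise` makes a single knob control both biological variability
  and measurement noise, and makes a noise-free cohort fully deterministic
  (a useful exactness regime for tests).
- **Vector cohorts** (`generate_paired_vectors`): each view is
  `X_v = A_v t + modality_noise · ε_v` with view-specific orthonormal
  mixings (or the identity, for pass-through tests).  `latent_dim = 0`
  disables the shared signal entirely — the null regime for CCA tests.
- **Volume cohorts** (`generate_paired_volumes`): four anisotropic Gaussian
  blobs at fixed positions; every blob's amplitude has unit weight on the
  severity coordinate, so the expected blob-peak difference between
  adjacent classes equals `shared_effect` exactly, plus a smaller
  modality-specific mixing (weight 0.3) of the non-severity coordinates.
  Blob positions couple only to non-severity coordinates (the class signal
  is purely amplitude).  A fixed band-limited texture field (amplitude
  0.15, smoothing σ 1.5) guarantees non-degenerate gradient descriptors;
  per-subject, per-modality band-limited noise has SD `modality_noise`
  (smoothing σ 0.8, rescaled).  Background 0.3, modality-B gain 0.9, voxels
  clipped at 0.

Defaults (`n_per_class = 20`, `latent_dim = 4`, `shared_effect = 1.0`,
`modality_noise = 0.2`, 32³ voxels) put the strongest pair (AD vs NC) at a
15σ-of-noise latent separation and adjacent classes at 5σ — a strongly but
not trivially separable regime once the signal has passed through
contrast-normalized local descriptors.

**What the generator does not model:** scanner physics, registration
error, partial-volume effects, anatomical shape variation, or realistic
intensity distributions.  Passing tests therefore demonstrate that the
pipeline recovers a planted shared multimodal signal under controlled
noise — not clinical performance on real images.

## Descriptors

2-D dense SIFT computed slice-wise (every 2nd slice along axis 0 by
default) and pooled per volume: patch 16, stride 8, 4×4 spatial bins, 8
orientation bins (D = 128), hard orientation binning weighted by gradient
magnitude, implemented with per-orientation integral images.  Descriptors
are l2-normalized, clamped at 0.2, and re-normalized (the standard scheme;
after re-normalization components may exceed 0.2 but stay within [0, 1]).
Constant patches yield the zero descriptor and participate in encoding
normally.  A single patch size is used; 3-D descriptors and keypoint
detection are out of scope.  The pyramid is in-slice: layer 1 undivided,
layer 2 a 2×2 half-open grid, "stacked" concatenates both (chosen so
per-cell descriptor counts stay adequate at desk scale).

## Encoding

K-means (Lloyd, `tol=1e-10`, seeded) learns the vocabulary on pooled
training-fold descriptors only.  Assignment is hard (one-hot), via a
k-d-tree with a small approximation slack or an exact linear scan
(`exact=True`), ties toward the lowest centroid index.  BoVW counts and
VLAD residual sums are produced per pyramid cell and concatenated; VLAD
intra-block l2 is available but off by default.  Encoder-class defaults are
K = 256 (BoVW) and 64 (VLAD); the experiment-level `PipelineConfig`
defaults to 64/16 because a desk-scale training fold (~5 000 descriptors)
cannot support 256 stable words.  Both are configurable.

## Normalization order

The stack applies **encode → power(ρ=0.5) → L2AL2W → CCA → kernel map →
SVM**.  The power-then-l2 order follows the established convention for
super-vector encodings; the L2A divisors are computed on training subjects
only and reused for test subjects (no leakage), and L2A normalizes per
feature dimension (per-block normalization would be an alternative
reading).  The two L2AL2W steps do not commute; the across-subject step
runs first.

## CCA

Regularized two-view CCA maximizes `b₁ᵀΣ₁₂b₂` under
`bᵢᵀ(Σᵢᵢ+εI)bᵢ = 1`.  Because encoded feature dimensions far exceed the
subject count, the fit first reduces each view to its row space by an
economy SVD — with a ridge the canonical directions provably lie in that
span, so the reduction is exact — and then solves the small generalized
symmetric eigenproblem.  `ε = 0` with rank-deficient data raises an error
instructing the caller to regularize; the automatic ridge is `1e-3 ×` the
mean diagonal of the pooled covariance.  Components: by default
`min(rank₁, rank₂, n−1)` truncated at correlation 0.01.  Sign convention:
the largest-magnitude entry of each view-1 basis column is positive (the
pair (b₁, b₂) is otherwise determined only up to a joint sign).  The second
projection applies B⁽²⁾ to X⁽²⁾ (the definitional form), and the augmented
representation stacks `[X⁽¹⁾; X⁽²⁾; Z⁽¹⁾; Z⁽²⁾]` without rescaling.

Two placements of CCA are provided.  `cca_stage="encoded"` (default) fits
CCA between the two modalities' encoded + normalized vectors — this stage
is fully determined by the equations above.  `cca_stage="input"` fits CCA
on flattened voxel intensities of the training fold and renders each
subject's two pseudo-modalities as the rank-c shared-structure
reconstruction `B Z + mean` reshaped to the grid (clipped at 0), which
re-enter descriptor extraction; the fused representation then concatenates
the four encoded streams.  How a "projected modality" should be rendered as
an image is genuinely open; the low-rank reconstruction is this package's
choice because it preserves the input contract of the descriptor stage.

## Kernel maps

Hellinger: element-wise square root (exact:
`Ψ(x)·Ψ(y) = Σ√(x_i y_i)`); composed with l2 it coincides with
power(0.5) + l2 on nonnegative input.  Chi-square and Jensen–Shannon use
the sampled homogeneous-kernel-map construction with spectra
`sech(πω)` and `(2/log4)·sech(πω)/(1+4ω²)`; output length is `2n+1` per
input dimension.  The automatic sampling period is 0.8 / 0.5 / 0.4 for
order 1 / 2 / 3 and `2.4/(n+2)` beyond: the period must shrink as the
order grows, otherwise the approximation saturates at the aliasing floor
of the periodicized kernel instead of converging.  The sampled maps
require nonnegative input, so in the augmented representation they are
applied to the X blocks only (nonnegative after normalization for BoVW)
while the CCA blocks pass through linearly; the signed VLAD stream
defaults to the linear map.

## Classification and evaluation

Linear soft-margin SVM (libsvm dual).  The cost C is chosen from
{0.01, 0.1, 1, 10} by one stratified 5-fold split of the training fold
(ties toward the smaller C); the hybrid fusion weight α is chosen from
{0, 0.1, …, 1} on the same inner out-of-fold scores, ties toward 0.5 and
then the smaller α.  Predictions use the sign rule with 0 mapped to the
positive class.  Cross-validation is stratified (the cohorts are
imbalanced across tasks) and repeated; every training fold refits
codebooks, normalization statistics, CCA, C and α from scratch.  Metrics
follow the standard confusion formulas; PPV/NPV with empty denominators
are reported as missing, AUC is the tie-averaged rank statistic; mean ± SD
is taken across all k × repeats folds.  All randomness flows from a single
seed via counter-based streams, so reports are bit-reproducible.

## Problem sizes

The shipped experiments use desk-scale cohorts: 20 subjects per class on
32³ voxel grids with 5-fold cross-validation for the end-to-end checks, 24³
grids and 8 subjects per class for the effect-monotonicity check, and
40-subject 10-dimensional vector cohorts for the CCA/fusion statistics.
These sizes are the package's validation regime; the pipeline itself is
agnostic to grid size and cohort size.

## Known limitations

- Hard assignment only (no soft assignment, GMM/Fisher vectors, LLE or
  sparse coding); no kernel or sparse CCA; no more-than-two views.
- Multi-class classification is out of scope; tasks are binary with MCI
  formed by merging MCI-C and MCI-NC downstream of generation.
- The synthetic generator's free parameters (blob geometry, texture
  amplitude, background) are fixed package constants, not fit to any real
  intensity statistics.
- The approximate nearest-neighbor index is a single exact k-d tree with an
  eps-relaxed query rather than a randomized forest; at desk scale the
  assignment agreement with the exact scan is effectively 100%.
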