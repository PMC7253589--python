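# Methods

## The segmentation problem

The amygdala and its subnuclei (lateral, basal, centromedial and
cortico-superficial groups, bilaterally) occupy roughly 0.05% of the
brain volume in a 1 mm isotropic T1-weighted image. Segmenting them is
dominated by two coupled difficulties: extreme class imbalance (a naive
learner is rewarded for predicting background everywhere) and the need
for context (the subnuclei have weak intensity boundaries, so a voxel's
identity depends on surrounding anatomy). `amygseg` implements a 3D
fully convolutional network designed around this trade-off, together
with its training protocol, tiled whole-volume inference, evaluation
metrics, and a synthetic phantom generator that reproduces the
statistical structure of the task so the full pipeline is testable
without the clinical cohort.

## Model

Every layer runs two parallel 3×3×3 convolution branches over the same
input and fuses them by element-wise summation

    F_l = F_dilated + F_standard ,

where each branch applies convolution → batch normalization → ReLU.
The standard branch keeps all dilations at 1; its nine-layer stack sees
a 19³ receptive field, just large enough to enclose a whole amygdala, so
most voxels influencing a prediction are near the target. The dilated
branch uses the schedule {1, 2, 4, 2, 8, 2, 4, 2, 1}; since a k³ kernel
at dilation D covers k + (k−1)(D−1) voxels per axis and a serial chain
of such layers sees 1 + (k−1)·ΣD, its receptive field is 53³,
supplying wider context without extra weights. Layer widths are
30, 30, 40, 40, 40, 40, 50, 50, 50 per branch; a 1×1×1 convolution maps
the final features to class scores. All convolutions are stride-1 and
zero-padded, so spatial shape is preserved and the network is
patch-size agnostic.

Residual connections group layers 2–3, 4–5, 6–7 and 8–9 into blocks
(layer 1 acts as a stem); the skip is the identity when widths match
and a 1×1×1 projection otherwise. The grouping follows the printed
width plateaus; the original figure does not pin it down exactly, which
is also why the ~0.8M parameter total reported for the original architecture is treated as a sanity
band (0.70–0.90M) rather than an equality — projection and bias
conventions are unspecified. This implementation puts no additive bias
on convolutions (the batch-norm shift subsumes it); the classification
head keeps its bias.

### Top-down attention-guided refinement

On each residual connection, per-channel coefficients

    α_c = σ( ReLU( BN( Conv1×1×1( AvgPool(F_high) ) ) ) )

are computed from high-level features and rescale the low-level
features before they are aligned by a 1×1×1 convolution d and added
back:

    F'_high = F_high + d(α ⊗ F_low) .

Because the ReLU precedes the sigmoid, α ∈ [0.5, 1] structurally — the
unit reweights, it cannot sign-flip. Two placements are provided:
*local* (each block's own output guides its input; the default) and
*global* (the deepest feature map guides every block). The global
variant needs the deepest features before the skips are refined, so the
network runs one attention-free pass (using d as the projection) to
obtain the guide, then the refined pass; batch-norm running statistics
are only updated on the refined pass. A squeeze-and-excitation (SE)
unit — coefficients computed from the skip input itself, with a
reduction ratio of 2 by default — is included as the channel-attention
baseline. The printed formula reads "d(α ⊗ F_low)", so multiplication
precedes alignment here; the alternative order is representable but not
what the equation states.

Parameter overhead of local and global placements is nearly but not
exactly equal under this wiring (+1.55% vs +1.64% on the default
configuration — the guide widths differ per block), consistent with
both rounding to the same reported +1.6%.

## Numerical engine

No GPU framework is used: the network runs on a compact reverse-mode
tape over numpy arrays (`amygseg.nn`). Convolutions are evaluated by
"z-lowering": only the k z-shifted copies of the padded input are
materialized and the k² in-plane taps each contribute one BLAS matrix
product accumulated through a shifted view. On a single CPU this keeps
copied volume at k× the input rather than k³ (full im2col) while all
arithmetic stays in GEMM; the data gradient of a stride-1 same-padded
convolution is itself such a convolution with the spatially flipped,
channel-transposed kernel. Every operation's gradient is verified
against central-difference numerical gradients in the test suite.
Networks run in float32; gradient checks run in float64.

Weights are He-initialized: zero-mean Gaussians with standard deviation
sqrt(2 / fan_in), fan_in = Cin·k³; biases and batch-norm shifts start
at zero. One integer seed controls initialization and all sampling.
Batch normalization uses momentum 0.1 and eps 1e-5, with biased batch
variance for both normalization and the running estimates.

## Training protocol

Voxel-wise unweighted categorical cross-entropy, optimized by Adam
(β₁ 0.9, β₂ 0.999, eps 1e-8) under polynomial decay

    lr = lr₀ · (1 − iter/total)^0.9 ,  lr₀ = 0.001 ,

which reaches exactly zero at the final iteration. Training patches
default to 59³ and inference tiles to 105³. The default batch size is
14 patches; the source protocol states both 14 patches per batch and 11
patches sampled per iteration, an unresolved discrepancy, so the value
is a config key. Because foreground is ~0.05% of the brain, a
configurable fraction of patches (default 0.5) is centered on a
uniformly drawn foreground voxel, the rest on uniformly drawn
brain-mask voxels (Otsu threshold when no mask is given). Volumes are
z-scored (global mean/std) before sampling by default
(`normalize_volumes`); a model trained this way must see normalized
volumes at inference, which the CLI does by default.

Cross-validation uses a rotation design (with 14 subjects, 7 folds of
10 train / 2 validation / 2 test; test blocks partition the cohort).
Model selection takes the epoch with the highest mean validation Dice
over foreground classes, earliest epoch on ties.

## Inference

Whole volumes are segmented by tiling: stride = patch_edge − 2·margin,
each tile contributing only its central region, so the cropped cores
partition the volume and stitching is order-independent. The default
margin (53−1)/2 = 26 discards all predictions within the dilated
branch's receptive-field radius of a tile face, where the zero-padded
context is incomplete. Volumes are padded symmetrically (repeated
reflection when a pad exceeds the axis length). Labels are the
per-voxel argmax of the stitched probabilities; ties break to the
lowest class index.

## Evaluation metrics

Dice: DSC = 2|A∩M| / (|A|+|M|). ASSD: the symmetric average of
nearest-border-voxel distances in both directions, in mm. Border voxels
are mask voxels with at least one 6-connected neighbour outside the
mask; voxels on the array boundary count the out-of-array side as
outside; distances are Euclidean between voxel centers scaled by the
voxel spacing. Neither convention is forced by the defining formulas
(surface meshes and other connectivities exist in the literature), so
both are fixed and documented here for reproducibility, and the
implementation is tested for exact agreement with an all-pairs
brute-force evaluation of the double sum on small masks. Undefined
cells — an empty mask for ASSD, a class absent from the truth — are
reported as N/A, never as zero.

## Phantom generator

A phantom is a brain-shaped ellipsoid on a dark background with two
mirrored ellipsoidal target structures, each cut into four compartments
by three sequential planes; cut offsets are placed at quantiles of the
voxel projections so compartment volume fractions (0.35/0.30/0.20/0.15)
hold under jitter. Septa — one-voxel-scale low-intensity sheets along
the cut planes, emulating the white-matter boundaries used as tracing
landmarks — modify intensity only; labels partition the whole
structure. Intensity = tissue mean × smooth multiplicative bias field
(low-order cosine mixture, ±5% by default, the residual inhomogeneity
left after bias correction) + Gaussian noise (σ 6 on a brain mean of
100 ≈ SNR 17). Structure size is derived analytically from the target
foreground fraction (default 0.05% of brain voxels, matching the real
cohort's imbalance). Cohorts jitter centers (±2 voxels), semi-axes
(±10%) and tissue means (±3%) independently per subject. Intensity-only
domain shifts (scale, offset, contrast inversion, noise/bias overrides)
leave labels bit-identical, emulating multi-site contrast variability.

What the phantom does **not** emulate: anatomy (the compartments are
geometric surrogates), MR physics, pathology, or the preprocessing
chain of real data. Passing the phantom checks therefore demonstrates
that the architecture, loss, sampling and inference machinery work as
designed under the stated statistical structure — not that the model
reaches any particular accuracy on clinical images.

### The fast-CPU preset and desk-scale checks

`PhantomSpec.small()` is a 48³ preset for CPU-scale training tests:
foreground ≈1% of the brain (structures ~11 voxels across, the top of
the scaled-up-imbalance band), bilateral labels 1–4 (the preset tests
compartment discrimination, not laterality), compartment means
(40, 80, 140, 180) against brain 100 at noise σ 5, and no septa — at
this scale a one-voxel sheet would not be thin relative to the
structure, and per-voxel contrast has to carry the signal that richer
context supplies at full scale. These values were calibrated once so
that the pipeline's scaled-down learning check (tiny dual-branch
network: widths 8/8/12/12, dilations {1,2,2,1}; 500 iterations, batch
4, 25³ patches, 30 phantoms, all-foreground-centered sampling) clears
mean test Dice 0.6 with margin (observed ≈0.67–0.73 across seeds), and
are frozen.

Problem sizes used by the test suite were chosen to fit a single-CPU
run: the headline learning check runs at the sizes above (≈4 minutes);
the dual-versus-single-branch ordering comparison runs 3 seeds × 3
models at a reduced size (250 iterations, 19³ patches, 12 phantoms) and
asserts the soft ordering dual ≥ max(single) − 0.02. At these budgets
absolute Dice values are far below the converged regime; only the
ordering is meaningful there.

## Known limitations

- Real-data accuracy is out of reach of this repository by design: no
  clinical volumes ship with it, and desk-scale budgets stop far short
  of convergence.
- The batch-norm convention (per-branch BN before fusion) and the
  residual grouping are the most plausible readings of the source
  figures, not uniquely determined facts; both are isolated behind the
  config so alternatives are cheap to express.
- Multi-site harmonization itself (image-to-image translation) is not
  implemented; the phantom's domain-shift variants only provide the
  evaluation side of that experiment.
- The engine is single-threaded numpy/BLAS; it is adequate for the
  desk-scale checks and small studies, not for full-scale training.
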