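# Methods

## Problem and model

`unwseg` segments cell nuclei in stained pathology images under *domain
shift*: the test images may come from a different stain chemistry, scanner
or lab than the training images, so their colour statistics differ while
the underlying morphology does not. The package implements a U-shaped
encoder–decoder (UNW) with two plug-and-play alignment blocks inserted at
the bottleneck:

**Instance normalization / whitening primitives.** For a feature map
`F ∈ R^{N×K×H×W}`, instance normalization standardises each channel of each
sample by its own spatial mean and population deviation,
`(x − μ)/√(σ² + β)`, removing per-image style. The instance-whitening loss
penalises the entrywise L1 distance between each sample's K×K channel
covariance (population convention, divisor `H·W`) and the identity,
removing inter-channel correlation. The entrywise L1 norm (not the induced
operator norm) is the convention in the whitening-loss literature and makes
the loss separable per entry.

**Feature Center Alignment (FCA).** Class-region instance normalization:
with labels `L`, each class region of each channel is standardised by the
statistics over that region only, then transformed by a learnable per-class,
per-channel affine (α, ε; initialised to identity). At inference no labels
exist, so a *pre-segmentation branch* — a 1×1 softmax classifier over the
bottleneck features — supplies class-probability maps `M`. The label-free
pipeline is: highlight each class (`F ⊙ M^c`), refine with FR (channel-wise
max/mean pooled descriptors + `M^c` → 3×3 conv → sigmoid gate `A`, output
`F″c = F^c + A ⊙ F^c`), derive a binary region mask by thresholding a
sigmoid response at `t = 0.8`, region-normalise inside the mask (masked-out
positions pass through bit-identically; an empty region passes through),
and sum the class branches to `F̄`. The FCA objective is the pixel-averaged
cross-entropy of `M` against `L` plus the element-mean L1 distance
`‖F̄ − FC‖₁`, pulling the label-free normalization toward the label-guided
one `FC`.

**Pre-segmentation robustness.** The pre-segmentation classifier reads the
*instance-normalized* bottleneck features (`preseg_on_normalized`, default
on). Its class maps steer the entire FCA pipeline multiplicatively
(`F ⊙ M^c`), so a style-sensitive classifier is a single point of failure:
if a shifted image makes it predict all-background, the nucleus branch is
erased and the model outputs nothing, regardless of how good the
normalization downstream is. Exactly this collapse mode appeared in
cross-style probe runs with a raw-feature classifier and disappeared with
the normalized input. IN is the style remover the whole architecture is
built on; using it in front of the one component that must be
appearance-robust is the same design principle applied once more.

**Feature Distribution Alignment (FDA).** The pre-segmentation classifier's
weight matrix `w ∈ R^{C×K}` scores every channel's relevance to every
class. Channels are ranked per class (descending weight, ties by ascending
index) and assembled greedily into `⌊K/C⌋` disjoint groups of one
not-yet-assigned top channel per class. For each sample and group, the
grouped channels are scaled by their classifier weights, their C×C
covariance computed, and `(1/N) Σ ‖Σ − I‖₁` penalised — whitening *across*
classes within each group, which separates class feature distributions
while leaving within-class structure alone.

**Total objective.** `λ_seg·CE(final, L) + λ_FCA·(CE(M, L) + ‖F̄ − FC‖₁)
+ λ_FDA·L_FDA`, all λ defaulting to 1. When FDA is enabled without FCA the
pre-segmentation branch is still supervised by its cross-entropy (otherwise
the ranking weights would be meaningless noise). Optimiser: SGD with
momentum 0.9, weight decay 5e-4, learning rate 5e-4, batch 6 at 512×512 for
200 epochs — the full-scale defaults, all overridable.

## Implementation notes

* **Autodiff engine.** The network runs on the package's own compact
  reverse-mode autodiff over NumPy (`unwseg.autodiff`): conv via
  channels-innermost im2col + BLAS GEMM, float32 on the network path. All
  operator gradients are checked against central differences in the test
  suite. The alignment math is written once and runs on plain arrays
  (fast, for analysis and oracles) or on tensors (differentiable).
* **Gradient contract.** Label masks and thresholded region masks are
  non-differentiable constants inside the normalization statistics.
  Thresholding passes no gradient, so the region-mask head keeps its
  initial weights; its bias is initialised to `logit(t)` so the mask is
  live (input-dependent) from the start — a zero bias would leave
  `sigmoid(0) = 0.5 < 0.8` and the mask permanently empty, making region
  normalization dead code.
* **FR combination.** The refined map is the gated residual
  `F″c = F^c + A ⊙ F^c` rather than the plain sum `F^c + A` (adding an
  attention field to features mixes units).
* **Degenerate inputs.** A spatially constant channel (or constant masked
  region) with β = 0 raises a division-by-zero error rather than produce
  NaN; a class absent from a sample, or an empty region mask, passes
  features through unchanged. Undefined metric ratios (zero denominator)
  score 1 and are flagged, never NaN.
* **Grouping edge cases.** When C does not divide K the lowest-ranked
  leftover channels are excluded from the FDA loss. Groupings are rebuilt
  from the live classifier weights every step.
* **Determinism.** All randomness flows from explicit seeds through
  NumPy's PCG64; single-threaded BLAS makes training bit-reproducible.
  Argmax ties in prediction resolve to the lower class index.
* **Label downsampling.** Nearest-neighbour (top-left convention) to the
  bottleneck resolution, preserving class ids.

## Synthetic data

The generator emulates stained tissue tiles: filled rotated ellipses
(nuclei) of seeded count, size, eccentricity and orientation — dense enough
to overlap and clump — over low-frequency textured background, under named
style domains (tissue/nucleus RGB, contrast, additive noise, grain).
Rasterisation is an exact analytic ellipse test on the pixel grid, so
datasets are byte-reproducible. Four styles ship by default: `hne` (bright
pink/purple H&E), `dark` (the same stain family heavily stained /
under-exposed: much darker, higher contrast, noisier), `blue` (cool
scanner-like hue shift) and `dab` (brown-on-cream immunostain palette).
The default benchmark trains on `hne` and tests on `dark`. A global
intensity/contrast swing is the canonical stain-variation failure mode
that per-image feature normalization is designed to remove, and it sits in
the informative middle of the difficulty range: the milder `blue` shift
leaves even an unaligned baseline intact, while the stain-chemistry
inversion of `dab` collapses every small model trained on `hne` — both
ends make the ablation uninformative.

What the generator does *not* emulate: real chromatin texture, nucleoli,
out-of-focus blur, anisotropic illumination, touching-nucleus boundary
ambiguity, or annotation noise. Passing cross-style tests therefore shows
that the alignment machinery removes global appearance shift on
ellipse-like objects; it does not certify performance on real clinical
slides.

The augmentation set is the dihedral subset used for training expansion:
horizontal/vertical flips and 90/180/270° rotations, sampled uniformly
(with identity) during training; image and mask always transform together.
Splits are seeded shuffles at ratio 0.7 by default, with a 5-fold partition
utility.

## Desk-scale experiment protocol

Full-scale training (512×512, 200 epochs) is out of reach on one CPU, so
the canned experiments (`unwseg.experiments`) use a deliberately small
instantiation whose sizes are package choices:

* backbone widths (4, 8, 32), one conv per stage — cheap early stages and a
  wide bottleneck where the alignment blocks act; 64×64 inputs, bottleneck
  16×16;
* no skip connections in the benchmark models: raw skips carry the input
  style straight to the decoder around the alignment blocks, and in probe
  runs the decoder's cross-style behaviour was completely insensitive to
  what the bottleneck delivered (replacing F̄ with label-guided FC, or even
  raw F, changed cross-style DSC by < 0.01) — the ablation would then
  compare decoder shortcuts, not alignment. Skip concatenation remains the
  full-scale default (`skip_connections=True`);
* SGD lr 0.05, batch 10, 20 epochs, global gradient-norm clip 5;
* `λ_FDA = 0.01` in this regime: the grouped-whitening sum over `⌊K/C⌋`
  groups is not normalised by group count, so at K = 32 its raw magnitude
  swamps the cross-entropy terms and stalls segmentation learning on short
  schedules; the scaled weight brings its contribution to the same order as
  the CE terms. Full-scale defaults remain λ = 1.
* the cross-style benchmark: 200 training images (`hne`), 60 test images
  (`dark`), disjoint seeds; the ablation trains Baseline / +FCA / +FDA /
  All under identical data and seeds.

On this benchmark the unaligned baseline loses a large fraction of its
Dice score under the intensity shift while the aligned variants retain
most of theirs; the full model is the strongest variant, with FCA
contributing the larger share — the alignment blocks are doing the work
they were designed for. The experiments report all four variants and all
five metrics.

## Known limitations

* The backbone is intentionally small and configurable; no claim is made
  about matching any particular published parameter count.
* Region-mask heads are untrained by construction (see gradient contract);
  their usefulness rests on the threshold-logit initialisation.
* Multi-class (C > 2) paths are implemented and exercised only lightly;
  metrics default to binary nucleus-vs-background evaluation.
* The optional Gaussian-blur denoise hook is a placeholder pre-processing
  step, not a learned denoiser.
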