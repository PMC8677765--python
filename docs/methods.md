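# Methods

This note documents the models, statistics and design choices behind
`convsel`, in the spirit of the methods documentation of simulation packages:
what is computed, under which assumptions, with which defaults, and what the
synthetic test bed does and does not show.

## The untrained network model

The feature extractor is the classic five-convolution AlexNet stack
(conv1 96×11×11 stride 4 → 3×3/2 max-pool → conv2 256×5×5 pad 2, 2 groups →
pool → conv3 384×3×3 pad 1 → conv4 384×3×3 pad 1, 2 groups → conv5 256×3×3
pad 1, 2 groups → pool), with ReLU after every convolution and a 227×227×3
input. The fully connected classification head is deliberately absent: the
object of study is the response of individual units in an untrained
hierarchy, not task performance. Local response normalization after
conv1/conv2 is implemented but off by default; enabling it reproduces the
literal Krizhevsky stack.

Weights are never trained. Each conv layer's weights (and, by default, its
biases) are drawn i.i.d. from a zero-mean Gaussian or uniform distribution
with standard deviation

    sigma = sqrt(1 / fan_in) * scale / 100,    fan_in = k^2 * C_in / groups,

the "efficient backprop" scaling that keeps signal variance roughly constant
across layers. The uniform variant uses half-width `sqrt(3)*sigma` so its
variance matches. `scale` (percent) sweeps initialization strength; a
`zero_bias` flag exists because with zero biases the whole stack is
positively homogeneous — multiplying all weights by c > 0 multiplies layer-L
responses by c^L exactly — which gives an exact invariance test for every
scale-free statistic downstream (selection labels, FSI). Bias handling is a
genuine unknown for this initialization family, so both conventions are
supported rather than asserted.

Unit responses are recorded post-ReLU, pre-pool, so conv5 exposes
13×13×256 = 43,264 units; a "unit" is one spatial position of one channel.
The forward pass is numpy im2col + BLAS matmul in float32; there is no GPU
path and no autograd. A desk-scale variant (quarter-width channels, 127×127
input, conv5 = 6×6×64 = 2,304 units) exists purely to make multi-network
experiments cheap on one CPU; all statistics are size-agnostic.

## The synthetic stimulus generator

The generator emulates a similarity-controlled object stimulus set:
grayscale square images, one foreground object per image from six classes
(face, scrambled face, hand, horn, flower, chair), composed onto
phase-scrambled backgrounds, with per-image luminance (mean 0.5) and RMS
contrast (0.18) normalized iteratively to compensate clipping, and object
bounding-box area normalized so `sqrt(area)` is a fixed fraction (0.48) of
the image. Objects are parametric schematics: a face is a head ellipse, two
eye ellipses, a nose and a mouth with seeded geometry; the other classes are
distinct parametric silhouettes. Each exemplar is determined by an identity
seed (shape parameters) plus a variation seed (residual jitter), so novel
exemplars of known identities are producible for generalization tests.

Two design features matter for realism and were fixed while validating the
generator against its own statistical targets:

* **Surface texture.** Flat-shaded shapes have local patch statistics
  radically unlike a textured background, which lets first-layer units
  separate classes from local cues alone — something photograph stimuli do
  not permit. Objects therefore carry a seeded 1/f noise texture
  (pixel std 0.15), bringing local statistics of figure and ground close and
  pushing class information toward configuration.
* **Graded within-class variability.** Classes carry a geometric-jitter
  multiplier (flower 0.5 … horn 1.3) assigned inversely to each schematic's
  intrinsic feature distinctiveness, so that class separability in response
  space spans a broad range — the structure that the clustering-vs-
  selectivity analysis probes. With it, mean pairwise pixel correlation
  among composed face stimuli is a small positive value (~0.2–0.3), far
  below that of aligned flat schematics.

The scrambled-face class patch-scrambles the textured face exemplar inside
its bounding box on a 6×6 grid (grid size is a package default; nothing in
the underlying protocol fixes it). A windowed phase scramble
(`local_texture_scramble`) provides a local-texture control that preserves
windowed spectra while destroying global form; it is a stand-in in the
spirit of texform stimuli, not the original texform synthesis. Affine object
transforms (size, position, rotation — 180° being inversion) are exact
affine warps about the object centroid with a clipping guard.

The viewpoint set renders a schematic head at yaws {−90°, −45°, 0°, +45°,
+90°} × identities, with feature positions foreshortened by cos(yaw) and
shifted by sin(yaw). Negative yaws are constructed as exact horizontal
mirrors of the corresponding positive-yaw image (backgrounds mirrored too),
and the frontal view is symmetrized, so the mirror property holds
pixel-exactly — which the mirror-symmetry analyses rely on.

Per-class partitions follow the 200:40:20 protocol proportionally
(selection / classifier-train / classifier-test, disjoint by construction).

What the generator does **not** emulate: photographic texture statistics
beyond second order, hair/clothing context, 3D shading, within-class
photometric variation. Tests passing on this bed show the analysis machinery
behaves correctly and that the qualitative phenomena are reproducible under
controlled conditions; they are not evidence about any particular real
image set.

## Selectivity statistics

A unit is selective to a target class iff, against **every** other class,
the two-sided Wilcoxon rank-sum p is below alpha (default 0.001,
uncorrected, matching the original protocol's annotation) and the target
mean is strictly greatest. p-values use the tie-corrected normal
approximation with continuity correction; for combined samples of at most
12 the exact tie-aware enumeration over midrank assignments is used (the
two agree with a brute-force permutation oracle by construction, which the
tests verify). Face tuning strength is

    FSI = (R̄_face − R̄_nonface) / sqrt((σ²_face + σ²_nonface) / 2)

with sample variances (n−1; the convention is a package choice) and the
non-face pool defaulting to all five non-face classes, scrambled faces
included. FSI is invariant to common positive rescaling and common shifts
of the responses; 0 means no preference and the sign follows the mean
difference. Degenerate cases: equal means with zero variance → 0; unequal
means with zero variance → signed infinity marker. Null calibration is by
label permutation (`shuffled_fsi_null`), whose mean is zero under
exchangeability. Z-scoring is per unit across stimuli; bitwise-constant
units are flagged and excluded from z-profiles (a tolerance of 1e-12
relative absorbs floating-point rounding of the mean).

## Reverse-correlation preferred feature images

Probes are single signed 2D Gaussian bumps (σ uniform in [4, 16] px,
amplitude ±0.25, polarity equiprobable, position uniform) on a neutral-gray
canvas. Each iteration presents probes superimposed on the current PFI,
accumulates `(response − batch mean) × bump` and renormalizes the PFI to
zero mean and fixed RMS (0.12). Mean-centering the weights removes the DC
bias of strictly-positive ReLU responses; renormalization prevents
blow-up — both are package choices since the original description fixes
neither probe geometry nor mixing. For a linear-plus-ReLU unit the
procedure provably recovers the filter up to scale, which the test bed
checks on a known Gaussian-template unit (correlation > 0.95 at 150 probes
× 100 iterations). Units that never respond in any iteration are returned
flagged degenerate rather than raising.

The face-configuration index (FCI) of a PFI is its mean pixel-wise Pearson
correlation with the face images used for unit selection (resampled
bilinearly if resolutions differ); it is affine-invariant in the PFI and
NaN for a constant PFI.

## Detection protocol

Decoding is face vs. non-face with a linear SVM (C = 1) trained on the
train partition (40 per class-group at full scale) and evaluated on the
test partition (20 per class-group), both disjoint from the selection
partition — the double-dipping guard is asserted at run time on stimulus
ids. Because the pools are 1:5 face:non-face, the SVM uses balanced class
weights and accuracy is reported as balanced accuracy (mean of per-class
recalls), which fixes the chance level at 0.5 for any split — the
calibration the shuffled control is tested against. Units are drawn without
replacement per trial from a named population (face-selective,
other-selective, any-selective, non-selective, all, or a shuffled control
whose sampled unit responses are permuted across stimuli). Transform
transfer trains on canonical views only and evaluates on size / position /
rotation variants of the same exemplars.

## Viewpoint tuning taxonomy

Among face-selective units: *invariant* iff the 5-group one-way ANOVA p,
Bonferroni-multiplied by 5, exceeds 0.05; *specific* iff one yaw's mean
exceeds every other yaw with pairwise two-group ANOVA (adjusted) p < 0.05;
*mirror-symmetric* iff the top two yaws are a {−θ, +θ} pair, each
significantly above the remaining yaws and not significantly different from
each other. The mirror rule is an operationalization of a verbally-defined
category ("peaks at ±45° or ±90°") and is flagged as such; the categories
are mutually exclusive by construction, with `none` for units fitting no
rule. The invariance index is 1/std (sample, n−1) of the per-yaw mean
responses, +inf for flat tuning. Degenerate ANOVA inputs follow fixed
conventions (zero within-group variance: p = 1 if means equal, else 0). The
inversion effect compares per-unit mean responses to upright vs
180°-rotated exemplars (paired sets) with a one-sided rank-sum across units.

## Representational clustering

Final-layer responses to the selection images are PCA-embedded (all
components by default — an orthogonal transform, so distances are
preserved and the silhouette is unchanged; the 2-component view is for
plotting only). The silhouette of point i in the centroid variant used
here ("paper" mode) is

    SI_i = (b_i − a_i) / max(a_i, b_i)

with a_i the Euclidean distance from point i to its own class centroid and
b_i the mean distance from that centroid to the other class centroids; the
classic Rousseeuw per-point silhouette is available as `mode="classic"` for
sensitivity analysis. The centroid variant is the literal reconciliation of
a per-point index with class-level distance definitions; both modes are
rigid-motion invariant. Class-level mean SI is then correlated (Pearson)
with the per-class count of selective units. Distances are computed in
response/PCA space with the Euclidean metric (a package choice).

## Orchestration, seeds and problem sizes

`pipeline.run_experiment` drives stimuli → responses → selectivity →
optional detection / clustering / PFI / viewpoint stages from a strict YAML
config (unknown keys are rejected before any compute); every module seed is
derived from one master seed plus fixed offsets, so identical configs
reproduce outputs bit-for-bit, recorded in a manifest with a config hash.
Two presets ship: `paper` (full AlexNet, 6 × 260 images, 100 networks) and
`desk`. The desk study — the package's standing replication experiment —
uses 10 quarter-width networks at 127×127, 6 classes × 130 images
(100/20/10 split), decoding with 20 units × 30 trials, and reverse
correlation at 150 probes × 10 iterations for 7 face-selective and 7
non-selective conv5 units in each of the first 5 networks (the full-scale
protocol of 2,500 probes × 100 iterations per unit is ~60× more forward
passes per unit than a single-CPU session can spend across dozens of
units). These sizes are the package's fixed desk-scale conditions; the
statistics at this scale are reported with their sample sizes.

## Known limitations

* Schematic stimuli are far simpler than photographs; absolute selective-
  unit counts and FSI magnitudes at desk scale are not comparable to values
  measured on photograph sets — only the qualitative contrasts are.
* The exact rank-sum branch is O(C(n, n_x)) and intentionally capped at
  combined n = 12.
* Reverse correlation at desk scale is noisy per unit; group contrasts
  (face-selective vs non-selective FCI) are the supported readout, not
  individual PFIs.
* The viewpoint renderer's profile views are stylized; mirror symmetry is
  exact by construction, so it tests the analysis, not the renderer.
* No GPU, no training, no pretrained-weight loading, and no generative
  (GAN-based) preferred-stimulus synthesis — the latter requires pretrained
  generator weights and is out of scope.
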