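# convsel

Class-selective units in **untrained** convolutional hierarchies: tools to
reproduce, on a fully synthetic test bed, the finding that face-selective
model neurons emerge in randomly initialized AlexNet-style networks — and to
characterize them (selectivity statistics, preferred feature images,
viewpoint tuning), use them (face vs. non-face decoding) and relate their
emergence to representational clustering.

The package is aimed at computational-neuroscience and NeuroAI researchers
who want a controlled, dependency-light sandbox for "innate selectivity"
analyses: every experiment runs from a seed on one CPU, with no downloads
and no training.

## The model and statistics

A network is the five-convolution AlexNet feature stack with ReLU and
max-pooling, weights drawn once from a zero-mean distribution with
`sigma = sqrt(1 / fan_in)` (fan_in = k²·C_in/groups) and never updated; unit
responses are taken post-ReLU in each conv layer, so conv5 exposes
13×13×256 = 43,264 units. On a six-class, similarity-controlled stimulus set
(face, scrambled face, hand, horn, flower, chair; matched luminance,
contrast, size, position; phase-scrambled backgrounds), a unit is
*face-selective* when its mean response to faces exceeds that to **every**
other class (two-sided rank-sum, p < 0.001, uncorrected). Tuning strength is
the d′-like face-selectivity index

    FSI = (R̄_face − R̄_nonface) / √((σ²_face + σ²_nonface) / 2),

preferred features are estimated by iterative reverse correlation with
Gaussian-bump probes and scored by the face-configuration index (mean
pixel-wise correlation with the selection faces), decoding uses a linear SVM
on disjoint train/test partitions (balanced accuracy; chance 0.5), viewpoint
tuning over yaws {−90°…+90°} is classified as invariant / specific /
mirror-symmetric by Bonferroni-adjusted ANOVA, and clustering is quantified
by the centroid silhouette SI_i = (b_i − a_i)/max(a_i, b_i). The synthetic
stimulus generator is itself first-class, tested code (exact amplitude-
preserving phase scrambles, patch scrambles, affine transform sweeps, a
pixel-exact mirror-symmetric viewpoint renderer). See `docs/methods.md` for
the full account.

## Worked example

`examples/find_face_units.py` builds one untrained desk-scale network
(quarter-width AlexNet, 127 px input), generates the stimulus set and counts
face-selective units per layer:

```
layer     units  face-selective      %  mean FSI
conv1     21600             340   1.57      1.00
conv2     12544             132   1.05      1.03
conv3      3456              36   1.04      1.01
conv4      3456              25   0.72      1.06
conv5      2304              15   0.65      1.02
```

Fifteen conv5 units of this never-trained network respond significantly more
to faces than to every other object class, with a mean FSI around 1 (face
responses about one pooled standard deviation above non-face responses) —
the headline phenomenon. The other scripts in `examples/` demonstrate one
capability each: decoding (`face_detection.py`), reverse-correlation
preferred features (`preferred_feature_images.py`), viewpoint tuning
(`viewpoint_invariance.py`) and the silhouette/selectivity relation
(`clustering_vs_selectivity.py`).

For multi-network experiments use the library pipeline or the thin CLI:

```bash
convsel run --preset desk --seed 1 --outdir runs/desk1
convsel summarize runs/desk1
```

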