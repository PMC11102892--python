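# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite establishes.

## Problem setting

A cystic renal lesion (CRL) is malignant, for the purposes of this package,
exactly when it contains a solid component that *enhances*: its mean HU gain
over the unenhanced baseline reaches **15 HU** in at least one post-contrast
phase. Two phases are modelled, in fixed order: corticomedullary (early,
bright renal cortex) and nephrogenic (later, more homogeneous kidney).
Malignant enhancement follows one of two trajectories — *fast-in, fast-out*
(strong corticomedullary gain, washed out by the nephrogenic phase, the
clear-cell pattern) or *gradual/homogeneous* (moderate gain in both phases,
the papillary/chromophobe pattern). Benign lesions are pure fluid or carry a
non-enhancing (< 15 HU) component.

## Synthetic phantoms (`crl.phantom`)

Real CRL cohorts are private; the phantom generator is first-class,
seed-deterministic code that renders what the models need to see:

* **Scene**: background at −30 HU → kidney ellipsoid (bright cortex shell,
  darker medulla core; cortex 170 HU corticomedullary / 130 HU nephrogenic)
  → spherical fluid lesion (10 HU, phase-constant) → optional solid
  component. Paint order resolves overlaps; Gaussian smoothing (σ = 1 mm, a
  partial-volume surrogate) precedes additive Gaussian HU noise (sd 10).
* **Solid components**: mural nodules (spheres on the cyst wall, radius
  0.35–0.5 lesion radii) or septa (planar slabs through the centre).
  Malignant septa are rendered *thickened* (3–5 mm — the Bosniak III cue);
  benign septa are thin (1–2 mm). The solid fraction is kept below 25% of
  the lesion volume, matching the cohort inclusion rule the system targets.
* **Cohorts**: the malignant count is `int(n·prevalence + 0.5)`; malignant
  trajectories split 50/50 between fast-in/fast-out (ΔHU ~ U(30,50) then
  U(4,12)) and gradual (U(18,30) then U(20,35)); half the benign lesions get
  a non-enhancing component (ΔHU ~ U(0,10)) so component *presence* alone
  does not reveal the label. Lesion radii are drawn from 0.15–0.25 of the
  grid extent — cohort lesions are large (several cm) relative to the
  kidney, and at coarse grids this keeps solid components several voxels
  wide after smoothing.
* **Grids**: the generator default is 64³ at 1.5 mm isotropic; the test
  suite and the acceptance script use 32³ at 1.5 mm, the size at which the
  numpy networks train in minutes while all structures stay resolvable.

What the phantoms do **not** model: CT physics (beam hardening, streaks,
partial volume beyond Gaussian blur), calcifications, Bosniak categories
beyond the benign/malignant dichotomy, anatomy beyond one kidney, and
inter-scanner variability. Passing tests therefore demonstrate that the
implementation recovers a cleanly rendered enhancement signal end-to-end —
not clinical performance.

`simulate_enhancement_check` measures the rendered ΔHU as the mean over the
solid mask eroded by ~2 smoothing supports (full mask if erosion empties
it), so partial-volume edge voxels do not bias the estimate; on noiseless
phantoms it recovers the generated ΔHU to ±0.5 HU.

## Geodesic interaction encoding (`crl.geodesic`)

Distance from a click set is the shortest path over the 26-connected voxel
graph with edge weight `sqrt(‖a−b‖²_spacing + λ²(I(a)−I(b))²)`; intensities
are first clip-rescaled to [0,1] over the (−100, 300) HU window, and λ
defaults to 1 (a full-window intensity jump costs like a ~1 mm step). The
fast path is Toivanen-style raster sweeps — **8 sweeps by default**: on 200
random ≤16³ volumes the worst-case error vs exact Dijkstra is 0.7% with 8
sweeps but 8.5% with 4, so 4 does not meet the 5% accuracy contract the
oracle test enforces. The raster result always upper-bounds the true metric.
Empty click sets map to a constant fill equal to the normalization bound
`F = P + λR` (P = Manhattan grid diameter in mm, R = intensity range); all
channels are divided by `F` and clipped to [0,1], so "no interaction" is the
all-ones channel.

## Segmentation networks (`crl.segmodel`)

P-net and R-net share one 3D U-Net implementation: 4 resolution levels,
base width 8, two conv(3³)–instance-norm–ReLU per level, 2× max-pool /
nearest-neighbour upsampling, skip concatenation, 1×1×1 logit head. Inputs
are padded to a multiple of 2^(depth−1) and cropped back. P-net takes the
normalized image (1 channel); R-net takes image + initial probability + the
two geodesic channels (4 channels). Training: Dice + cross-entropy loss
(configurable to pure Dice), Adam (lr 3e-3), batch 2, 8 epochs at test
scale, best-validation-Dice checkpointing on a seeded 80/20 split. R-net
training pairs are built by running the trained P-net on each study and
letting the robot user place 3 clicks against the ground truth. The binary
mask is probability ≥ 0.5, ties foreground.

## Robot user and refinement loop (`crl.interact`)

The robot labels the k = 3 largest connected false-negative components with
positive clicks and the k largest false-positive components with negative
clicks, each at the component's most interior voxel (max spacing-aware
Euclidean distance transform, lexicographic (z,y,x) tie-break — exactly
reproducible, and pinned against an exhaustive search in tests). The loop:
round 0 is P-net; each round accumulates clicks (seed sets are monotone
non-decreasing) and re-runs R-net on the *initial* P-net probability plus
all clicks so far; stop at max_rounds (default 4), on a perfect mask, or
when the Dice gain falls below ε = 0.001.

## SETD classifier (`crl.setd`)

Per phase: a cubic crop around the lesion-mask centroid (24³ at test scale;
48³ default at 64³ grids), HU-normalized and **gated by the lesion mask** —
raw crops are dominated by renal cortex, which is brighter than any nodule,
so ungated crops carry essentially no class signal at phantom scale. The
shared encoder is a reduced-depth residual conv-net (stage widths 4/8/16,
one basic two-conv block per stage, 1×1×1 widening + 2× max-pool between
stages; the classic [3,4,6,3] stage pattern is reachable by config, with
basic rather than bottleneck blocks). Three deliberate choices, each driven
by the physics of the signal:

* **No normalization layers by default** — the class cue is the *absolute*
  HU level of the solid component; instance norm erases it per sample.
* **Global average + max pooling, concatenated** — enhancing nodules/septa
  occupy few voxels; average pooling alone dilutes them away.
* **Box-filter/identity-biased initialization** — stem kernels start near a
  local mean, stage transitions near identity, so the pooled features
  approximate lesion intensity statistics at initialization and the GRU
  head starts one linear step from the enhancement rule. This plays the
  role a pretrained encoder plays at scale; with purely random
  initialization at n ≈ 50 training studies, convergence was strongly
  seed-dependent. (A `pretrained` weights path remains config-exposed,
  default none.)

The two-layer GRU (hidden 16 at test scale) decodes the 2-step feature
sequence; the final hidden state feeds a linear sigmoid head. Training:
weighted binary cross-entropy with inverse-class-frequency weights
(equivalent to two-way weighted CE with one logit), Adam lr 3e-4 with
decoupled weight decay 1e-3, batch 4, 60 epochs, random axis flips and
±2-voxel crop-centre jitter as augmentation, early stopping on validation
AUC (patience 20) restoring the best — among equal validation scores the
most recent — weights. The recipe was validated across three encoder seeds
(held-out AUC 1.0 each) on a 60-phantom cohort before being frozen.

## Evaluation statistics (`crl.evalstats`)

* Overlap: Dice, IOU, SEN, SPE at voxel level; both-empty masks score Dice 1;
  cohort tables report mean ± *sample* (n−1) sd.
* ROC/AUC: empirical curve (ties ½), so a binary rater scores (SEN+SPE)/2 —
  this reproduces the published Bosniak-rater AUCs (0.840 validation, 0.869
  test) from the printed count fractions. 95% CI by seeded stratified
  bootstrap percentile (default 2000 draws); DeLong-variance CI by flag.
* DeLong: mid-rank structural components, paired z test; a zero-variance
  comparison (model vs itself) reports p = 1 with a degenerate flag.
  Components, variance and covariance are pinned to a brute-force
  U-statistic oracle at 1e-10.
* Decision curves: `nb(t) = (TP − FP·t/(1−t))/n` on a 0.01–0.99 grid,
  against `nb_all(t) = π − (1−π)t/(1−t)` and `nb_none ≡ 0`.
* Classification SEN/SPE/ACC at threshold 0.5 (ties positive) unless
  configured.

One published inconsistency is deliberately not reproduced: the source
table prints a test-cohort accuracy of 0.988 alongside count fractions
(17/17, 141/145) that imply 158/162 ≈ 0.975; this package always computes
accuracy from counts.

## End-to-end pipeline (`crl.cli_app`)

`crl run` executes phantoms → P-net → R-net (robot pairs) → refinement on
the held-out split → SETD → prediction → evaluation, with every stage seed
derived from the global seed via CRC-tagged seed sequences, a config
snapshot archived in the run directory, and per-stage wall time logged. A
**synthetic Bosniak-style rater** provides the paired baseline for the
DeLong test and the second decision curve: it measures the rendered ΔHU
over the (eroded) solid region on the *noisy* corticomedullary phase and
over-calls at a 5 HU margin — well below the 15 HU rule — reproducing the
high-sensitivity / lower-specificity profile of radiologist Bosniak
dichotomization.

## Numerical and testing notes

* All layer gradients (conv, instance norm, GRU, pooling, the full U-Net and
  SETD graphs) are verified against central finite differences in float64.
* Training is deterministic given seeds in single-threaded BLAS; logs and
  checkpoints depend only on (data seed, init seed, shuffle seed).
* Problem sizes in tests/acceptance: 40-phantom segmentation cohort
  (30 train / 10 held-out), 60-phantom classification cohort (48/12), 32³
  grids; chosen so the whole suite trains every network from scratch in
  roughly ten minutes of CPU.
* Known limitations: no sliding-window inference path is exercised at test
  scale; scribbles are represented as click sets (single voxels); the
  phantom rater and the SETD model see the same rendering pipeline, so
  their comparison measures relative — not absolute — discrimination.
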