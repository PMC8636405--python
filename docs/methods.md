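# Methods

## Problem

An activity cliff (AC) is a pair of structurally analogous compounds
with a large potency difference against the same target. Cliffs mark
the discontinuous parts of a structure–activity relationship and are
disproportionately informative for compound optimization. `cliffpix`
asks whether cliffs can be predicted *from images*: each candidate pair
is drawn as a standardized picture and a small convolutional network is
trained to tell cliff pairs from non-cliff pairs, with gradient-based
attribution used to inspect what the network looked at.

## Pair definition and enumeration

Structural analogs are formalized as matched molecular pairs (MMPs):
two compounds that share a core and differ by one substituent exchange
at a single site. Enumeration is the classical index-table scheme:

1. every acyclic single bond between two heavy atoms of every compound
   is cut once ("exocyclic single bond"); ring bonds and bonds to
   hydrogen are never cut, so both fragments always carry at least one
   heavy atom;
2. the larger fragment is taken as the core, the smaller as the
   substituent (the admissibility rule below forces the core to be the
   strictly larger side, so no decomposition is lost);
3. fragmentations are grouped in a table keyed by the canonical core
   SMILES (attachment point written as `*`); any two compounds meeting
   at the same key with different substituents form a candidate pair.

A candidate is admissible when the substituents have at most 13 heavy
atoms each, the core has at least twice as many heavy atoms as the
larger substituent, and the substituents differ by at most eight heavy
atoms. These transformation size restrictions keep pairs that look like
typically observed analogs. All three bounds are configurable.

When a pair matches on several cores, one record is kept via the
largest core, ties broken by the lexicographically smallest canonical
core key (`keep_all_cores=True` disables the reduction). Within a pair,
`compound_a` is always the more potent compound; this fixes the panel
order of the image deterministically.

The test suite checks the enumeration against a brute-force oracle that
compares every compound pair directly over all single cuts; the two
routes must agree exactly.

## Potency curation and labels

Potencies are pKi values (−log10 of the inhibition constant; one unit =
one order of magnitude). Repeated measurements of a compound are
averaged arithmetically on the pKi scale provided all values fall
within the same order of magnitude, operationalized as max−min < 1.0
pKi units (strict; both the bound and strictness are configurable, and
averaging on the Ki scale is available). Otherwise the compound is
discarded. Structures are canonicalized on load; for multi-component
inputs the largest covalent component is kept, with a logged warning.

Pair labels come from the absolute potency difference ΔpKi:

* **AC** (cliff) if ΔpKi ≥ 2.0 — at least a 100-fold difference;
* **NON_AC** if ΔpKi ≤ 1.0 — at most tenfold;
* **EXCLUDED** for the open interval in between, which is removed from
  modeling so that borderline pairs cannot blur the class boundary.

Both thresholds are inclusive at their boundary and configurable.

After labeling (and after dropping the excluded gap — the order is
configurable), MMPs are only retained if their compounds and their core
occur in more than one MMP. The criterion is re-evaluated after each
simultaneous removal round until a fixed point, which makes the result
independent of input order; a single-pass variant exists for
comparison. "Multiple" means an occurrence count of at least two,
pooled over both label classes.

## Images

Every unique core and substituent is drawn once as a 500×500 RGB raster
(RDKit 2D depiction, white background, attachment point as an
asterisk), resized to square panels with bilinear interpolation, and
three panels are concatenated horizontally — core, substituent of the
more potent compound, substituent of the less potent compound — into a
300×900×3 tensor (150×450×3 in the reduced profile). Pixel values are
divided by 255 into 32-bit floats so the white background is exactly
1.0 in every image; per-image min-max scaling was rejected because it
would make white vary across images. Rendering is deterministic:
repeated runs produce bit-identical tensors, and fragment panels are
cached so each unique fragment is drawn once.

The substituent panel order (more potent first) is a deliberate
convention: the literature leaves the order open, and an uncontrolled
order would inject label-correlated noise.

## Classifier

The network is intentionally small:

    input -> conv(32 filters, 3×3) -> ReLU
          -> conv(32 filters, 5×5) -> ReLU
          -> max-pool 2×2 -> dropout(0.25)
          -> flatten -> dense(128) -> ReLU -> dense(2) -> softmax

with "same" padding so feature maps keep the input geometry (which
makes attribution maps align with the image trivially). Training uses
Adam (lr 1e-3), categorical cross-entropy, and keeps the natural class
imbalance (no class weights) by default, since cliffs being rare is
part of the problem; optional inverse-frequency weighting is available.

The implementation is plain NumPy (float32, channels-last). Convolution
is im2col + BLAS GEMM, blocked over image rows so the column buffer
(~22 MB) stays cache-resident, with the column layout chosen to match
`sliding_window_view`'s memory order so no strided transpose is ever
materialized. All layers and the optimizer write into preallocated
buffers; at these activation sizes fresh per-step allocations make page
faults, not arithmetic, the bottleneck. Gradient correctness is tested
against `scipy.signal.correlate` (forward) and central finite
differences (parameter and input gradients of the linear layers; the
whole-net softmax/cross-entropy gradient is checked separately because
finite differences across ReLU kinks are unreliable in float32).

A fixed `InputCenter` layer subtracts 1.0 from the input so the white
background maps to 0. Pair images are line art on white; without
centering, the constant background drives large correlated
pre-activations and, for some seeds, the network collapses into a dead
constant predictor within an epoch. The shift is equivalent to a
particular bias initialization of the first convolution and does not
change the stored image format.

Determinism: a single config seed derives (via `SeedSequence`) the
initialization and the training stream (batch order, dropout); the full
train→predict path is bit-reproducible on a fixed machine, and the
test suite asserts this at small scale.

### Hyperparameters

| parameter | default | reduced profile | notes |
| --- | --- | --- | --- |
| input shape | 300×900×3 | 150×450×3 | three square panels |
| filters per conv | 32 | 32 | fixed architecture |
| filter sizes | 3×3, 5×5 | same | fixed architecture |
| dropout rate | 0.25 | 0.25 | in (0, 1) |
| dense units | 128 | 128 | |
| optimizer / lr | Adam, 1e-3 | Adam, 1e-3 | |
| batch size | 32 | 16 | |
| epochs | 30 | 2 | see below |

The reduced profile is the package's desk-scale configuration: half
resolution, two epochs, two trials. On the packaged benchmark the
planted signal is strong enough that two epochs reach test AUC ≈ 1.0;
the short schedule keeps a full benchmark run (two trials, ~210
training images each) around ten minutes on one CPU. The full-size
profile is exposed but unexercised by the packaged benchmark.

## Performance measures

With cliffs as the positive class: MCC, F1, overall accuracy
(TP+TN)/N and balanced accuracy from the confusion matrix, plus ROC
curves with trapezoidal AUC from a full threshold sweep (equal to the
Mann–Whitney concordance probability, ties counted half). Two
formula-level quirks found in the source literature are handled
explicitly: a printed single-threshold "AUC" expression algebraically
equals balanced accuracy and is provided as `auc_single_point` but
never reported, and a printed accuracy variant (TP+FN)/N measures class
prevalence rather than correctness and is kept only as
`accuracy_tp_fn_variant`. Zero denominators yield 0 with a logged
warning. Aggregation over trials reports mean and sample (n−1)
standard deviation.

Repeated trials use stratified random halving: per label class, a
seeded shuffle puts ⌈n/2⌉ pairs in training and the rest in test, with
per-trial seeds derived deterministically from a base seed. Random
halving shares cores (and compounds) between training and test; that
mirrors the evaluation protocol this package reproduces, and is a known
optimistic bias of that protocol. Group-aware (core-disjoint) splitting
is deliberately out of scope.

## Attribution

Attribution works on either convolutional layer from the gradient of
the target class logit with respect to the layer's post-ReLU feature
maps. The grid is rectified, max-normalized per image (so each overlay
uses the full color range), and bilinearly upsampled to the input
geometry. Three aggregations are implemented:

* `elementwise` (default): per-position sum over channels of
  gradient × activation — the first-order contribution of each spatial
  position to the logit.
* `gradcam`: the classic formulation — gradients spatially averaged
  into one weight per channel, then a weighted channel sum.
* `channel_mean`: the weighted channel mean; identical to `gradcam`
  after max-normalization.

The element-wise default is a deliberate departure from the classic
formulation. Classic Grad-CAM assumes the spatial gradient pattern is
roughly position-independent (true after a global-average-pooling
head). This network instead flattens the pooled maps into a dense
layer, so every spatial position has its own read-out weights; spatial
averaging then mixes opposing signs, and on small inputs the averaged
weights can cancel to entirely negative (hence empty, after
rectification) maps. Position-resolved gradient × activation keeps the
spatial sign structure and is the faithful first-order attribution for
this architecture; the classic modes are retained for comparison.
Overlays alpha-blend (0.5) a continuous colormap over the grayscaled
base image.

Because the image is three panels, integrating the upsampled map over
width thirds gives interpretable per-panel heat fractions (core /
substituent-hi / substituent-lo), which is how "the model looked at the
substituents" is quantified and tested.

## Synthetic benchmark

The generator emulates combinatorial analog series: `n` structurally
unrelated scaffolds, each decorated at one open position with every
member of a substituent library, with additive potency

    pKi = base(core) + effect(substituent) + N(0, noise_sd).

The packaged benchmark uses 4 scaffolds (15–17 heavy atoms) × 15
substituents (60 compounds → ~420 MMPs after filtering). Fourteen
ordinary substituents (alkyl/ether/halide/nitrile, ≤ 6 heavy atoms)
span 0.52 pKi units of effect, so ordinary exchanges are non-cliffs;
one cliff substituent — a piperazine, drawn as a distinctive
nitrogen-containing ring — sits 2.8 units above the weakest, so
cliff-vs-ordinary exchanges differ by 2.28–2.80 units and cross the
cliff threshold robustly. Cliff pairs are ~13% of the data, inside the
5–15% minority band that mirrors the imbalance of real MMP data sets.
Measurement noise defaults to 0.1 pKi units (≈ the reproducibility of
careful Ki assays); at zero noise the pipeline's labels equal the
analytic labels exactly, which the tests assert.

What the benchmark does *not* emulate: real SAR (no nonadditivity, no
activity-class-specific chemotypes), assay heterogeneity, or series of
unequal size. Passing the learning property therefore shows that the
pipeline is wired correctly and that the network can read a
substituent-borne signal out of pair images — not that cliffs in real
activity classes are predictable at any particular accuracy.

## Numerical and degenerate-input conventions

* Potency-curation mean is clamped into [min, max] of the inputs to
  absorb float round-off.
* Equal-sized fragments at a cut (core undefined) are ordered by
  canonical SMILES; such cuts can never pass the size filter.
* Max-pooling with odd trailing rows/columns drops them; gradient ties
  at exactly equal pooled values propagate to all tied positions.
* Grad-CAM of an all-zero grid (e.g. a zero output head) stays all
  zero; per-panel fractions of a zero map are reported as uniform 1/3.
* Empty metric denominators return 0 (warned); ROC requires both
  classes and raises otherwise.
* A label class with fewer than two members cannot be halved and
  raises.

## Known limitations

* Random halving leaks cores between train and test (see above).
* The NumPy network is single-CPU; the full-size 300×900 profile
  trains, but slowly (~4× the reduced cost per image).
* Bit-reproducibility holds per machine/BLAS build, not across them.
* Grad-CAM resolution is bounded by the feature-map grid; with same
  padding it matches the input grid here, but heat is still smoothed
  by upsampling and max-normalized per image, so heat is comparable
  within, not across, images.
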