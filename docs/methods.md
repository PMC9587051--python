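# Methods

`estrocycle` implements an automated staging pipeline for rodent vaginal
cytology: a softmax image classifier over the four canonical estrous stages
(diestrus, proestrus, estrus, metestrus), a confidence measure on its
output, and a temporal layer that fits sequential classifications to an
archetypal estrous cycle to flag likely misclassifications, transition
stages and cycle disruptions. This note records the model, its
assumptions, the defaults and the design decisions that were genuinely
open.

## Staging model and stage encoding

Stages are treated as four discrete classes in the cyclic order
D → P → E → M → D. For cycle fitting each stage is encoded by the midpoint
of a unit interval (D = 0.5, P = 1.5, E = 2.5, M = 3.5), with the integer
boundaries naming transitions; 0.0 ≡ 4.0 is the metestrus/diestrus
boundary. Residuals between observed and fitted stage numbers are measured
on the 4-unit circle (distance modulo 4), since the linear encoding would
otherwise make metestrus→diestrus — cyclically adjacent — look maximally
distant.

## Image preprocessing

- **Luminance alignment.** The intensity histogram peak is shifted
  additively to a reference level of 0.8. The peak is located on a
  histogram of `img − img.min()` with fixed bin width 1/64 and refined as
  the mean of the values in the modal bin. Measuring the peak relative to
  the minimum on fixed-width bins makes the operation invariant to
  pre-clip additive offsets and idempotent (to floating-point precision,
  when the shift induces essentially no clipping). The reference level and
  bin count are free choices exposed in the config.
- **Grayscale.** RGB is collapsed with ITU-R 601 luma weights and
  replicated to three identical channels, so stain color is discarded
  while the 3-channel input contract of standard backbones is met.
- **Quadrisection.** Images are split 2×2; odd dimensions give the extra
  row/column to the top/left quadrants. Quadrisection happens *after* the
  train/validation/test split, so quadrants of one image can never
  straddle a partition boundary (a leakage the alternative ordering would
  invite).
- **Augmentation.** One random reflect/rotate/scale/translate transform
  per call, drawn from user-configurable ranges (defaults: reflection
  p = 0.5 per axis, rotation ±30°, scale 0.9–1.1, translation ±10%),
  edge-replication fill, rotation/scaling about the image center, and a
  mandatory seed.
- **Split.** Seeded stratified 80/10/10 sampling without replacement, with
  strata formed by the joint (stain, species, lab, magnification) key and
  largest-remainder rounding inside each stratum; strata smaller than 3
  records are pooled globally with a logged warning.
- **Balancing.** Stages are downsampled without replacement to the
  smallest per-stage count.

Seeding everywhere is a deliberate departure from unseeded randomization:
reproducibility is a requirement for a testable artifact.

## Classifier and training schedule

The training harness implements the transfer-learning schedule: RMSprop
with squared-gradient moving-average coefficient ρ = 0.99, minibatch
gradient descent with per-epoch shuffling, and a piecewise step-decay
learning rate

    lr(epoch) = max(lr_floor, lr0 · drop^⌊epoch / epochs_drop⌋)

with defaults lr0 = 1e-5, drop = 0.1, epochs_drop = 1, three epochs. Epoch
indexing starts at 0, so the first epoch runs at lr0. Both a floor
function in the exponent and an `lr_floor` clamp (default 0) are
implemented; the clamp covers configurations that want a minimum rate.

Zoo backbones (ResNet-50, VGG-19, Inception v3, MobileNet v2) are
consumed from torchvision when the optional torch backend is installed —
their internals are deliberately not re-implemented. The bundled
`smallcnn` backbone is a three-layer NumPy CNN (two 3×3 convolutions with
2×2 max pooling over a 4× average-pooled 56×56 grayscale input, then a
softmax head) designed to train from scratch on a CPU in about half a
minute. Its inputs are centered at 0.8, the luminance-alignment target, so
backgrounds sit near zero.

`smallcnn_config()` is the documented from-scratch preset: lr0 = 3e-3,
minibatch 8, gradient-norm clipping at 1.0, leaky-ReLU activations
(negative slope 0.05). The fine-tuning defaults (lr0 = 1e-5, minibatch 80)
are appropriate for a pretrained backbone but far too conservative for a
randomly initialized network given ~100 optimization steps; plain ReLU at
this step count also collapses entire runs through unit death, which the
leaky slope prevents.

At inference the preprocessing chain (luminance alignment → 3-channel
gray → resize to 224×224×3) is applied; optional quadrant aggregation
averages the four quadrant softmax vectors and renormalizes. Argmax ties
break toward the canonical stage order.

## Confidence Index

CI = (P_max − P_max−1)/(P_max + P_max−1) over the two largest softmax
probabilities: 1 when all mass is on one stage, 0 when the top two tie.
It is strictly increasing in the margin at a fixed top-two sum.

## Archetypal cycle and phase fitting

The archetypal cycle is a periodic waveform with a 4.8-day period mapping
time to stage number, built through five anchors: the metestrus/diestrus
boundary at (0, 0.0), the four stage temporal midpoints at their stage
numbers, and the wrap anchor at (4.8, 4.0). The default per-stage duration
fractions — D 0.35, P 0.15, E 0.30, M 0.20 — are **placeholders chosen to
respect the usual ordering (diestrus longest, proestrus shortest), not
measured values**, and are config-overridable.

Two waveform constructions are provided, because the anchor-interpolation
form is genuinely under-specified: the default is shape-preserving
monotone (PCHIP) interpolation through the anchors, and an alternative
two-term Fourier fit (a·sin + b·cos + c at the cycle frequency, least
squares on the anchors) can be selected in the config. Both are periodic;
the monotone form passes through every anchor exactly.

Fitting shifts the phase over the grid {0.0, 0.1, …, 0.9} cycles and keeps
the shift maximizing the Pearson correlation between observed stage
numbers and the shifted waveform; ties break toward the smaller phase.
Correlation is computed on stage numbers (the classifications), not on
probabilities. By default the waveform side of the correlation is also
discretized to stage numbers (the stage the waveform position falls in):
observations are inherently discrete labels, and correlating them against
the continuous waveform value systematically biases the fitted phase when
stage durations are unequal — enough to miss the nearest grid phase even
on noiseless sequences. A `correlation="continuous"` mode retains the raw
waveform values for comparison. Fitting requires more than four days of
data (n > 4x at sampling frequency x/day) and rejects constant label
sequences as degenerate. Samples deviating from the fitted (discretized)
waveform by more than 1.0 stage units (circular distance) are flagged as
outliers. Phase recovery is reliable from roughly two cycles of daily
samples upward; near the n > 4x floor the grid argmax is noise-sensitive.

## Combining net and cycle predictions

For each sample the fitted waveform position gives a cyclicity stage.
Agreement passes the net stage through. Disagreement with CI ≥ 0.30 raises
an outlier flag and keeps the net stage — the interactive choice a GUI
would offer is deferred to the caller, and the non-interactive default
favors the image evidence. Disagreement with CI < 0.30 produces a
transition suggestion: the transition label of the integer boundary
nearest the fitted waveform position (e.g. position 1.95 →
"proestrus/estrus").

## Cycle disruption flags

- **Pseudopregnancy.** Consecutive diestrus samples form runs whose
  duration is the sample count times the typical (median) sampling
  interval. A run is flagged at the first sample where its running
  duration strictly exceeds 1.5× the mean duration of previous completed
  runs; at least one completed prior run is required, otherwise the
  detector reports insufficient history. The mean (rather than the
  maximum) of prior runs is used as the baseline — an open choice,
  documented here.
- **Anestrus from counts.** A flag iff some consecutive span with
  leukocyte fraction strictly above 0.9 lasts strictly longer than 2 days.

## Synthetic cytology generator

The generator emulates the statistical structure the pipeline relies on —
per-stage cell-type composition and cell-size/appearance differences — and
nothing else. Cells are parametric shapes on a light background:
leukocytes small dark discs (radius 2–4 px at the native 448 px render),
nucleated epithelial cells medium discs (6–9 px) with a darker nucleus,
cornified epithelial cells large irregular polygons (12–16 px, no
nucleus). Stage mixtures are Dirichlet draws (concentration 80) around
per-stage means — diestrus (0.85, 0.05, 0.10), proestrus (0.10, 0.10,
0.80), estrus (0.05, 0.90, 0.05), metestrus (0.40, 0.30, 0.30) as
(leukocyte, cornified, nucleated) — chosen to respect the qualitative
stage descriptions; transition labels use the mean of their flanking
stages. Per-stage total-cell ranges (diestrus 120–240, proestrus 80–160,
estrus 50–90, metestrus 80–160) keep every image above the 10-cell
exclusion floor and within packing densities the renderer can place
without overlap.

Two renderer properties are design invariants, not accidents: cells are
placed by dart throwing with a minimum separation (so no two cells touch),
and each cell type occupies a disjoint intensity band. Together these make
the ground truth exactly recoverable from a noise-free render by
thresholding and connected-component counting, which the test suite uses
as a self-consistency oracle. Clumping draws cornified cells near cluster
centers (strength 0.7, spread 28 px) subject to the same separation, so
estrus images show adjacent-but-disjoint sheets. Stain tints are uniform
RGB multipliers; Gaussian pixel noise (σ = 0.01) is added last.

Sequences sample the archetypal cycle at a true phase; label noise
replaces a stored label with a uniformly random other stage without
touching the rendered image; after a pseudopregnancy onset day the true
stage locks to diestrus and leukocyte fractions are drawn ≥ 0.9.

What the generator does *not* emulate: real stain chemistry and color
variation, mucus and debris, out-of-focus blur, cell overlap, or the
subtle morphological continua between substages. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the
classifier can learn cell-composition signal — not that any particular
accuracy transfers to real smears.

## Problem sizes used in tests

The test suite trains `smallcnn` on the generator's default study scale of
200 images per stage (800 images, 80/10/10 split, 3 epochs) and evaluates
on the held-out partition; this trains in well under a minute per seed on
one CPU. Phase-recovery statistics use 100 seeded 10-day sequences; the
grid-search/brute-force equivalence check uses 200 random sequences; the
exact-test comparison enumerates all 2×2 tables with group sizes ≤ 15.

## Known limitations

- The synthetic classes are far more separable than real cytology;
  held-out accuracies here say nothing quantitative about real data.
- Zoo backbones require an optional dependency and are untested in this
  environment; only `smallcnn` model directories can be reloaded.
- The stage-duration fractions and all generator appearance parameters
  are package defaults, not fitted to data.
- A label permutation control retains ~25% correct labels on a balanced
  set, so permuted-label accuracy sits modestly above chance (~0.35–0.4)
  rather than at 0.25; the leakage test asserts collapse relative to
  intact-label performance.
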