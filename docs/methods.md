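# Methods

This note documents the models and procedures implemented in `bitbrain`,
the parameters that matter, the numerical choices made where the design
was genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Model summary

The classifier composes three stages.

1. **Unsupervised feature formation.**  Each address decoder element
   (ADE) computes a weighted sum over *n* subsampled pixels of the
   centred image (raw − 127) and fires when the sum reaches its
   threshold (inclusive).  Synapse pixels are drawn from the square root
   of the per-pixel sum of training values ("ink mass") by a
   random-walk Metropolis chain; the square root both stabilises the
   Poisson-like variance of the mass bins and flattens the target so
   synapses can land slightly outside the training footprint.
   Thresholds adapt homeostatically toward a target firing probability;
   a longevity rule plus synapse replacement lets elements home in on
   features.  No labels are read.
2. **Single-pass supervised writes.**  Every pairwise coincidence of
   firing elements between (or within) decoders addresses one location
   of a 2D bit memory holding one bit per class; the example's class bit
   is set.  Writes are idempotent ORs: the pass is order-independent and
   repeating it is a no-op.
3. **Bit-count inference.**  The same locations are probed and set bits
   are summed per class across all memories; argmax wins, ties to the
   lowest class index.

The kernel module re-expresses stage 2–3: the unrolled coincidence
vector of an input is a sparse binary feature map, AND-popcount overlap
is a Mercer (set-intersection) kernel, and least-squares classification
on its Gram matrix is the exact counterpart of the memory's write/read
approximation.

## Parameters

| Parameter | Default | Units / range | Notes |
|---|---|---|---|
| `w` (elements per decoder) | 2048 | count | memory size is w² per full SBC; diminishing returns beyond a few thousand |
| `n` (synapses per element) | {6,8,10,12} (4-AD) or {6,10,12} (3-AD) | pixels | different widths per decoder capture feature scales |
| locality radius | {2,3,3,4} / {2,3,4} | pixels (Chebyshev) | box around the element's sampled centroid; radius for width 8 interpolated between its neighbours |
| `target_rate` | 0.01 | probability | homeostatic firing target; sparse patterns keep coincidences informative |
| `interval_t` | 2000 | presentations | counting window for threshold updates and replacement cadence |
| unsupervised presentations | 2 × dataset | count | drawn with replacement to avoid order bias |
| `step` | 1 | activation units | threshold increment; 0 disables threshold learning |
| dead band | ±25% | of target count | no move while the interval count is inside the band |
| longevity default / cap / critical | 16 / 255 / 1 | count | a persistently-losing synapse is replaced after ~16 firings |
| synapse types | `binary` (±1, sign-binarised inputs) or `int8` (uniform ±[1,127], greyscale inputs) | — | presets default to binary |
| LSC ridge | 1e-6 · trace(K)/n | kernel units | exact inversion (ridge 0) raises a descriptive error on singular K |

## Numerical and procedural choices

**Metropolis proposal.**  Uniform over the 7×7 offset box excluding the
null offset, re-proposing at image borders; acceptance
min(1, target[proposal]/target[current]); chain initialised at the
argmax pixel; 1,000 burn-in steps; no thinning.  On images of 4×4 or
smaller the in-bounds proposal is symmetric and the stationary law is
exactly the normalised target (this is what the goodness-of-fit test
checks); on 28×28 images border asymmetry introduces a small, harmless
bias.  Rejected proposals repeat the current state; the multapse and
locality rejection rules absorb the duplicates.  Sampling failure after
10,000 rejections raises an error naming the centroid rather than
livelocking.

**Threshold calibration.**  The first interval sets each threshold to
the activation value whose empirical exceedance rate is closest to the
target — choosing between the two distinct values bracketing the
(1 − target) quantile.  Activation distributions on raster data are not
smooth: every image that inks none of an element's pixels produces the
identical sum (a large atom, often at the distribution's extreme for
negative-sum weight draws).  Coarse distributions mean the exact target
may be unachievable; calibration picks the nearest achievable rate.
When the calibration sample cannot resolve the target at all
(m · target < 1, e.g. one-shot training sets), the threshold sits at
the maximum activation — the smallest nonzero rate — because a silent
element contributes nothing downstream.

**Guarded ±step adaptation.**  Later intervals compare each element's
fire count to the target count and move the threshold one step, with two
restraints: the ±25% dead band, and a guard that blocks a move whose
post-move interval count would be *further* from the target than the
current one.  The guard matters precisely because of the activation
atoms: a blind downward step from a just-above-the-atom threshold sends
the rate from ≈0 to the atom's mass (tens of percent), and the next
interval steps it back — a limit cycle whose snapshot at the end of
training is arbitrary.  With the guard, such elements park at their
closest achievable rate.  On a constant input stream the threshold still
converges to within one step of the activation value.

**Replacement ordering.**  Weak synapses are replaced at interval
boundaries, implemented at the *start* of the following interval, and a
rewired element is re-calibrated by that interval (replacement is "the
same mechanism as original setup", and a redrawn 8-bit weight shifts the
activation scale by amounts a ±1 step could never track).  Replacement
pixels honour the original centroid, the locality box, and the multapse
prohibition; longevity resets to the default and the weight is redrawn.

**Tie rules.**  Plasticity: smallest/largest signed contributor by value,
ties to the lowest synapse position; if argmin and argmax coincide the
update is a no-op.  Prediction: argmax with ties to the lowest class
index, and an all-zero count vector raises a "no evidence" warning while
defaulting to class 0.

**Half-size memories** store the strict upper triangle (j < k) of
within-decoder coincidences; the diagonal is a self-coincidence carrying
no pairwise information.  Serialization packs bits little-endian at
address ((j·w_col)+k)·n_classes+l with a JSON sidecar carrying per-class
popcounts; loads verify the popcounts and the format version.

**Noise semantics.**  Gaussian (clamped to [0, 255], rounded half away
from zero) and salt-and-pepper (replacement with 0 or 255, equiprobable)
are applied on the raw pixel scale before centring.  Frozen ("static")
noise derives one realisation per image from (seed, image index), so
repeated freezes are bit-identical and subsetting a dataset does not
reshuffle its noise.  Training noise, when configured, is frozen once
and used by both the unsupervised and the supervised phase.

## The synthetic generator

Classes are fixed sets of 2–3 px filled discs with centres drawn
uniformly from the central (rows−8)×(cols−8) window; samples are the
prototype translated by ±1 px and with per-stroke intensities perturbed
by clamped N(0, 8).  This reproduces the two structural properties the
method relies on — border pixels carry no ink (≥25% of pixels have zero
global mass) and classes differ in local features — and nothing else.
It does **not** emulate continuous stroke-intensity profiles,
anti-aliasing, elastic deformation, or the within-class shape diversity
of handwriting.  Two consequences worth naming: the synthetic task is
much easier than MNIST (the default benchmark is solved exactly at
w ≥ 512), so passing tests demonstrate mechanism correctness, not
real-data accuracy; and binarised inputs take exactly two values on
disc images, giving binary-synapse elements only n+1 possible
activations, so their achievable firing rates are coarse (sweep-mean
≈0.4% against a 1% target, versus 0.9–1.0% for int8 elements, whose
greyscale×weight sums are nearly continuous).  The rate-target checks
therefore use int8 decoders; binary decoders get an order-of-magnitude
check.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run reduced configurations
chosen to exercise every mechanism at full fidelity while staying quick:
decoders of w = 96–512 (the presets' w = 2048 is exercised once in the
benchmark-bar test), synthetic sets of 120–2,000 images, 10⁵-step chains
for the statistical checks, and 1,000 Monte-Carlo draws for the
expected-coincidence count.  The homeostasis measurement uses the full
spec of its study conditions (2,000 images, w = 512, widths 6 and 10,
interval 2,000, twice-the-set presentations).

## Known limitations

- The guarded step keeps elements whose achievable rates bracket the
  target parked on one side rather than dithering; the sweep-mean rate
  is the honest summary, and per-element rates on coarse data are not
  individually near 1%.
- Half-size memories require row and column to be the same decoder; the
  optional two-in-one physical packing mentioned in the storage design
  is not implemented (logically invisible either way).
- The kernel path materialises Gram matrices densely: O(n²) memory in
  the training subset size.  Use stratified subsets for large sets.
- Continuous-learning support is mechanism-only (`random_forget`); no
  cadence policy is provided or defaulted.
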