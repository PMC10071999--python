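"""Address decoders: sparse binary feature detectors with homeostasis.

An address-decoder element (ADE) subsamples ``n`` input pixels through
weighted synapses and fires when its activation

    activation_j = sum_i input_i * weight_i

reaches a per-element threshold theta_j (inclusive).  An address decoder
(AD) is an ordered vector of ``w`` ADEs of equal width; its set of firing
elements for an input is the AD's firing pattern, which downstream
coincidence memories consume.

Two synapse flavours are supported.  ``binary`` synapses have weights of
+-1 and see binarised inputs (sign of the centered pixel, with 0 mapped
to -1), matching event-based front ends.  ``int8`` synapses carry signed
8-bit weights drawn uniformly from [-127, -1] u [1, 127] and multiply the
centered greyscale values directly.

Unsupervised learning shapes the decoders without ever reading labels:

* homeostatic threshold adaptation drives every ADE toward a target
  firing probability (~1% by default), producing sparse patterns;
* a Hebbian longevity rule rewards, per firing event, the synapse with
  the largest signed contribution to the crossing sum and penalises the
  smallest contributor;
* structural plasticity replaces synapses whose longevity has decayed
  below a critical value with freshly sampled pixels, letting each
  element home in on a feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .io_encoding import SignedImage
from .sampling import (
    DEFAULT_MAX_REJECTS,
    MetropolisChain,
    SamplingTarget,
    draw_ade_pixels,
    draw_replacement_pixel,
)
from .synthetic_data import LabelledImageSet

__all__ = [
    "Synapse",
    "ADE",
    "AddressDecoder",
    "FiringPattern",
    "UnsupervisedSchedule",
    "build_address_decoder",
    "ade_activation",
    "decoder_firing_pattern",
    "batch_firing",
    "prepare_inputs",
    "adapt_thresholds",
    "plasticity_step",
    "replace_weak_synapses",
    "unsupervised_learn",
]

LONGEVITY_DEFAULT = 16
LONGEVITY_CAP = 255
LONGEVITY_CRITICAL = 1

SynapseType = Literal["binary", "int8"]


@dataclass(frozen=True)
class Synapse:
    pixel: int
    weight: int
    longevity: int


@dataclass
class ADE:
    """View of one decoder element; arrays are shared with the parent AD."""

    pixels: np.ndarray  # (n,)
    weights: np.ndarray  # (n,)
    longevities: np.ndarray  # (n,)
    threshold: int
    centroid: int | None
    synapse_type: SynapseType = "binary"

    @property
    def synapses(self) -> list[Synapse]:
        return [
            Synapse(int(p), int(w), int(l))
            for p, w, l in zip(self.pixels, self.weights, self.longevities)
        ]


@dataclass
class AddressDecoder:
    """An ordered vector of ``w`` ADEs sharing one width ``n``."""

    pixels: np.ndarray  # (w, n) int64 flat pixel indices
    weights: np.ndarray  # (w, n) int16
    longevities: np.ndarray  # (w, n) int16
    thresholds: np.ndarray  # (w,) int64
    centroids: np.ndarray  # (w,) int64, -1 when no locality constraint
    synapse_type: SynapseType
    locality_radius: int | None
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        w, n = self.pixels.shape
        if w < 1 or n < 1:
            raise ValueError("decoder needs w >= 1 ADEs of n >= 1 synapses")
        for j in range(w):
            if len(np.unique(self.pixels[j])) != n:
                raise ValueError(f"ADE {j} has duplicate pixels (multapse)")

    @property
    def w(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_n(self) -> int:
        return self.pixels.shape[1]

    def ade(self, j: int) -> ADE:
        return ADE(
            pixels=self.pixels[j],
            weights=self.weights[j],
            longevities=self.longevities[j],
            threshold=int(self.thresholds[j]),
            centroid=None if self.centroids[j] < 0 else int(self.centroids[j]),
            synapse_type=self.synapse_type,
        )

    @property
    def ades(self) -> list[ADE]:
        return [self.ade(j) for j in range(self.w)]

    def copy(self) -> "AddressDecoder":
        return AddressDecoder(
            pixels=self.pixels.copy(),
            weights=self.weights.copy(),
            longevities=self.longevities.copy(),
            thresholds=self.thresholds.copy(),
            centroids=self.centroids.copy(),
            synapse_type=self.synapse_type,
            locality_radius=self.locality_radius,
            image_shape=self.image_shape,
        )


@dataclass(frozen=True)
class FiringPattern:
    """Sorted indices of the ADEs that fired for one input."""

    active: np.ndarray  # sorted int64 indices in [0, width)
    width: int

    def __post_init__(self) -> None:
        a = np.asarray(self.active, dtype=np.int64)
        if len(a) and (a.min() < 0 or a.max() >= self.width):
            raise ValueError("active indices outside [0, width)")
        object.__setattr__(self, "active", np.sort(a))

    def __len__(self) -> int:
        return len(self.active)


# ---------------------------------------------------------------------------
# Construction


def _draw_weights(
    rng: np.random.Generator, shape: tuple[int, ...], synapse_type: SynapseType
) -> np.ndarray:
    if synapse_type == "binary":
        return rng.choice(np.array([-1, 1], dtype=np.int16), size=shape)
    if synapse_type == "int8":
        mag = rng.integers(1, 128, size=shape).astype(np.int16)
        sign = rng.choice(np.array([-1, 1], dtype=np.int16), size=shape)
        return mag * sign
    raise ValueError(f"unknown synapse type {synapse_type!r}")


def build_address_decoder(
    target: SamplingTarget,
    w: int,
    n: int,
    synapse_type: SynapseType = "binary",
    locality_radius: int | None = None,
    seed: int = 0,
    max_rejects: int = DEFAULT_MAX_REJECTS,
    locality_from: Literal["centroid", "any"] = "centroid",
) -> AddressDecoder:
    """Build ``w`` ADEs of width ``n`` by Metropolis sampling of ``target``.

    All ADEs of the decoder share one chain (burned in once); thresholds
    start at zero and are meaningless until :func:`adapt_thresholds` or
    :func:`unsupervised_learn` calibrates them.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)))
    chain = MetropolisChain(target, seed)
    chain.burn_in()
    pixels = np.empty((w, n), dtype=np.int64)
    centroids = np.full(w, -1, dtype=np.int64)
    for j in range(w):
        centroid, pix = draw_ade_pixels(
            target, n, locality_radius, chain=chain,
            max_rejects=max_rejects, locality_from=locality_from,
        )
        pixels[j] = pix
        centroids[j] = -1 if centroid is None else centroid
    return AddressDecoder(
        pixels=pixels,
        weights=_draw_weights(rng, (w, n), synapse_type),
        longevities=np.full((w, n), LONGEVITY_DEFAULT, dtype=np.int16),
        thresholds=np.zeros(w, dtype=np.int64),
        centroids=centroids,
        synapse_type=synapse_type,
        locality_radius=locality_radius,
        image_shape=target.image_shape,
    )


# ---------------------------------------------------------------------------
# Activation and firing


def _transform_inputs(centered: np.ndarray, synapse_type: SynapseType) -> np.ndarray:
    """Map centered pixels to synapse inputs (binarise for binary synapses)."""
    if synapse_type == "binary":
        return np.where(centered > 0, 1, -1).astype(np.int16)
    return centered.astype(np.int16)


def prepare_inputs(
    images: np.ndarray | LabelledImageSet, synapse_type: SynapseType
) -> np.ndarray:
    """Center a uint8 image stack and flatten to a (m, pixels) input matrix."""
    if isinstance(images, LabelledImageSet):
        images = images.images
    images = np.asarray(images, dtype=np.uint8)
    centered = images.astype(np.int16) - 127
    flat = centered.reshape(len(centered), -1)
    return _transform_inputs(flat, synapse_type)


def ade_activation(ade: ADE, image: SignedImage) -> int:
    """Weighted input sum over one element's synapses."""
    x = _transform_inputs(np.asarray(image.values).ravel(), ade.synapse_type)
    return int(np.dot(x[ade.pixels].astype(np.int64), ade.weights.astype(np.int64)))


def decoder_firing_pattern(ad: AddressDecoder, image: SignedImage) -> FiringPattern:
    """Indices of all ADEs whose activation reaches their threshold."""
    x = _transform_inputs(np.asarray(image.values).ravel(), ad.synapse_type)
    acts = (x[ad.pixels].astype(np.int32) * ad.weights).sum(axis=1)
    return FiringPattern(np.flatnonzero(acts >= ad.thresholds), ad.w)


def _batch_activations(ad: AddressDecoder, X: np.ndarray) -> np.ndarray:
    """(m, w) activation matrix for a prepared input matrix X."""
    out = np.empty((len(X), ad.w), dtype=np.int32)
    chunk = max(1, 2**24 // max(1, ad.w * ad.width_n))
    for s in range(0, len(X), chunk):
        xb = X[s : s + chunk]
        out[s : s + chunk] = (xb[:, ad.pixels].astype(np.int32) * ad.weights).sum(
            axis=2
        )
    return out


def batch_firing(ad: AddressDecoder, X: np.ndarray) -> np.ndarray:
    """(m, w) boolean firing matrix for a prepared input matrix X."""
    return _batch_activations(ad, X) >= ad.thresholds


# ---------------------------------------------------------------------------
# Homeostatic threshold adaptation


def _calibrate_thresholds(
    acts: np.ndarray, target_rate: float
) -> np.ndarray:
    """Per-ADE threshold at the closest achievable firing rate.

    Firing is inclusive (activation >= theta), so for each element we pick
    between the two distinct activation values bracketing the
    ``1 - target_rate`` quantile, whichever empirical rate is nearer the
    target.  With coarse (tied) activation distributions this is the best
    any integer threshold can do.

    When the sample cannot resolve the target (``m * target_rate < 1``,
    e.g. a handful of training images), the threshold sits at the maximum
    activation: the smallest nonzero achievable rate.  Silencing the
    element entirely would leave nothing for downstream learning.
    """
    m, w = acts.shape
    srt = np.sort(acts, axis=0)  # ascending
    k = int(round(target_rate * m))
    if k < 1:
        return srt[m - 1].astype(np.int64)
    theta = np.empty(w, dtype=np.int64)
    for j in range(w):
        col = srt[:, j]
        t0 = int(col[m - k])  # rate >= k/m (ties may inflate it)
        lo = int(np.searchsorted(col, t0, side="left"))
        rate0 = (m - lo) / m
        # next distinct value above t0 (rate strictly smaller), or never-fire
        hi = int(np.searchsorted(col, t0, side="right"))
        if hi < m:
            t1 = int(col[hi])
            lo1 = int(np.searchsorted(col, t1, side="left"))
            rate1 = (m - lo1) / m
        else:
            t1, rate1 = t0 + 1, 0.0
        theta[j] = t0 if abs(rate0 - target_rate) <= abs(rate1 - target_rate) else t1
    return theta


@dataclass
class UnsupervisedSchedule:
    """Presentation plan for the unsupervised phase.

    ``n_presentations`` defaults to twice the dataset size (presentations
    are drawn with replacement, so more passes than images is fine).  The
    dead band keeps thresholds still while the per-interval fire count is
    within ``dead_band_frac`` of the target count, avoiding limit-cycle
    thrash around an unachievable exact rate.

    ``guarded_step`` additionally blocks a threshold move that would land
    the fire count *further* from the target than it already is.  Raster
    data with a constant background puts a large atom in each element's
    activation distribution (every image that inks none of its pixels
    yields the identical sum); a blind downward step can drop the
    threshold onto that atom and send the rate from ~0 to the atom's
    mass.  The guard keeps the same local +-step dynamics but parks such
    elements at their closest achievable rate.
    """

    n_presentations: int | None = None
    interval_t: int = 2000
    target_rate: float = 0.01
    step: int = 1
    dead_band_frac: float = 0.25
    guarded_step: bool = True
    plasticity: bool = True
    replacement: bool = True
    longevity_critical: int = LONGEVITY_CRITICAL
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_rate < 1.0:
            raise ValueError("target_rate must be in (0, 1)")
        if self.interval_t < 1:
            raise ValueError("interval_t must be >= 1")


def _as_stack(images) -> np.ndarray:
    if isinstance(images, LabelledImageSet):
        return images.images
    return np.asarray(images, dtype=np.uint8)


def adapt_thresholds(
    ad: AddressDecoder,
    image_stream,
    target_rate: float = 0.01,
    interval_t: int = 2000,
    step: int = 1,
    n_presentations: int | None = None,
    seed: int = 0,
) -> AddressDecoder:
    """Homeostatic threshold adaptation only (no plasticity, no rewiring).

    Presentations are drawn randomly with replacement to avoid order
    biases.  The first full interval calibrates each threshold to its
    closest achievable rate; every later interval compares the fire count
    against the target count and nudges the threshold by ``step``.
    """
    schedule = UnsupervisedSchedule(
        n_presentations=n_presentations,
        interval_t=interval_t,
        target_rate=target_rate,
        step=step,
        plasticity=False,
        replacement=False,
        seed=seed,
    )
    return unsupervised_learn([ad], image_stream, target=None, schedule=schedule)[0]


def plasticity_step(ade: ADE, image: SignedImage) -> ADE:
    """One Hebbian longevity update after a firing event.

    The signed contribution of synapse ``i`` is ``input_i * weight_i``.
    The smallest contributor loses one longevity point (floor 0) and the
    largest gains one (capped); ties break toward the lowest synapse
    position, and if the same synapse is both smallest and largest the
    update is a no-op.  Calling this on an element that did not fire on
    ``image`` is a contract violation.
    """
    x = _transform_inputs(np.asarray(image.values).ravel(), ade.synapse_type)
    contrib = x[ade.pixels].astype(np.int64) * ade.weights.astype(np.int64)
    if int(contrib.sum()) < ade.threshold:
        raise ValueError("plasticity_step called on an ADE that did not fire")
    _apply_longevity_update(ade.longevities, contrib)
    return ade


def _apply_longevity_update(longevities: np.ndarray, contrib: np.ndarray) -> None:
    lo = int(np.argmin(contrib))
    hi = int(np.argmax(contrib))
    if lo == hi:
        return
    longevities[lo] = max(0, int(longevities[lo]) - 1)
    longevities[hi] = min(LONGEVITY_CAP, int(longevities[hi]) + 1)


def replace_weak_synapses(
    ad: AddressDecoder,
    target: SamplingTarget,
    critical: int = LONGEVITY_CRITICAL,
    seed: int | None = None,
    chain: MetropolisChain | None = None,
    rng: np.random.Generator | None = None,
) -> AddressDecoder:
    """Replace every synapse whose longevity fell below ``critical``.

    The replacement pixel is drawn by the same mechanism as the original
    setup — same chain dynamics, same locality box around the element's
    original centroid, multapses still forbidden — and gets a fresh
    weight and the default longevity.
    """
    if chain is None:
        if seed is None:
            raise ValueError("need a seed when no chain is supplied")
        chain = MetropolisChain(target, seed)
        chain.burn_in()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    weak = np.argwhere(ad.longevities < critical)
    for j, i in weak:
        centroid = None if ad.centroids[j] < 0 else int(ad.centroids[j])
        exclude = np.delete(ad.pixels[j], i)
        new_pix = draw_replacement_pixel(
            chain, centroid, ad.locality_radius, exclude
        )
        ad.pixels[j, i] = new_pix
        ad.weights[j, i] = _draw_weights(rng, (), ad.synapse_type)
        ad.longevities[j, i] = LONGEVITY_DEFAULT
    return ad


def unsupervised_learn(
    ads: Sequence[AddressDecoder],
    dataset,
    target: SamplingTarget | None,
    schedule: UnsupervisedSchedule | None = None,
) -> list[AddressDecoder]:
    """Run the full unsupervised phase over a shared presentation stream.

    Thresholds adapt homeostatically; if enabled, the longevity rule runs
    on every firing event and weak synapses are rewired at interval
    boundaries.  Labels are never read.  Decoders are updated in place
    and returned.
    """
    if schedule is None:
        schedule = UnsupervisedSchedule()
    images = _as_stack(dataset)
    if len(images) == 0:
        raise ValueError("empty image stream")
    if schedule.replacement and target is None:
        raise ValueError("synapse replacement needs the sampling target")

    n_pres = (
        2 * len(images)
        if schedule.n_presentations is None
        else schedule.n_presentations
    )
    if n_pres == 0:
        return list(ads)

    rng = np.random.default_rng(np.random.SeedSequence((schedule.seed, 0xADE)))
    order = rng.integers(0, len(images), size=n_pres)

    X_by_type = {
        st: prepare_inputs(images, st) for st in {ad.synapse_type for ad in ads}
    }
    chains: list[MetropolisChain | None] = []
    for i, ad in enumerate(ads):
        if schedule.replacement:
            c = MetropolisChain(target, int(np.random.SeedSequence(
                (schedule.seed, 0xC4A1, i)).generate_state(1)[0]))
            c.burn_in()
            chains.append(c)
        else:
            chains.append(None)

    # ADEs needing (re-)calibration: all of them at first, then any whose
    # synapses were rewired (replacement re-initialises the threshold by
    # the same quantile mechanism as the original setup)
    needs_calib = [np.ones(ad.w, dtype=bool) for ad in ads]
    t = schedule.interval_t
    for start in range(0, n_pres, t):
        idx = order[start : start + t]
        m = len(idx)
        for a, ad in enumerate(ads):
            # structural replacement runs at interval boundaries, before the
            # interval's activations, so a rewired ADE is recalibrated by
            # the very interval that follows and thresholds are never stale
            if schedule.replacement and start > 0:
                weak = np.unique(
                    np.argwhere(ad.longevities < schedule.longevity_critical)[:, 0]
                )
                if len(weak):
                    replace_weak_synapses(
                        ad,
                        target,
                        critical=schedule.longevity_critical,
                        chain=chains[a],
                        rng=rng,
                    )
                    needs_calib[a][weak] = True
            X = X_by_type[ad.synapse_type][idx]
            acts = _batch_activations(ad, X)
            calib = needs_calib[a]
            if schedule.step == 0:
                # a zero step disables threshold learning altogether
                calib = np.zeros(ad.w, dtype=bool)
            if calib.any():
                ad.thresholds[calib] = _calibrate_thresholds(
                    acts[:, calib], schedule.target_rate
                )
                needs_calib[a] = np.zeros(ad.w, dtype=bool)
            adapt = ~calib
            if adapt.any() and schedule.step != 0:
                _adjust_thresholds(ad, acts, adapt, m, schedule)
            fired = acts >= ad.thresholds
            if schedule.plasticity:
                _run_plasticity(ad, X, fired)
    return list(ads)


def _adjust_thresholds(
    ad: AddressDecoder,
    acts: np.ndarray,
    adapt: np.ndarray,
    m: int,
    schedule: UnsupervisedSchedule,
) -> None:
    """One homeostatic +-step update from an interval's fire counts."""
    counts = (acts >= ad.thresholds).sum(axis=0)
    target_count = schedule.target_rate * m
    upper = target_count * (1 + schedule.dead_band_frac)
    lower = target_count * (1 - schedule.dead_band_frac)
    move_up = adapt & (counts > upper)
    move_dn = adapt & (counts < lower)
    if schedule.guarded_step:
        err = np.abs(counts - target_count)
        if move_up.any():
            up_counts = (acts >= ad.thresholds + schedule.step).sum(axis=0)
            move_up &= np.abs(up_counts - target_count) < err
        if move_dn.any():
            dn_counts = (acts >= ad.thresholds - schedule.step).sum(axis=0)
            move_dn &= np.abs(dn_counts - target_count) < err
    ad.thresholds[move_up] += schedule.step
    ad.thresholds[move_dn] -= schedule.step


def _run_plasticity(ad: AddressDecoder, X: np.ndarray, fired: np.ndarray) -> None:
    """Apply the longevity rule to every firing event, in presentation order."""
    chunk = max(1, 2**24 // max(1, ad.w * ad.width_n))
    for s in range(0, len(X), chunk):
        xb = X[s : s + chunk]
        contribs = xb[:, ad.pixels].astype(np.int32) * ad.weights  # (b, w, n)
        events = np.argwhere(fired[s : s + chunk])
        for bi, j in events:
            _apply_longevity_update(ad.longevities[j], contribs[bi, j])
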