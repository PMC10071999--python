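"""Synapse placement by Metropolis sampling of the global ink distribution.

Feature detectors subsample pixels, and pixels should be sampled in
proportion to how much signal they carry.  The global distribution is the
per-pixel sum of values over a training set; its square root is used as
the (unnormalised) sampling target.  Two reasons: pixel sums are counts,
so the square root is approximately variance-stabilising, and the
flattened target lets synapses land slightly outside the training ink
footprint, which helps with unseen data.

Sampling runs a random-walk Metropolis chain on the 2D pixel grid:
proposals are uniform over the 7x7 offset box around the current pixel
(excluding the null offset, re-proposing at image borders), acceptance is
``min(1, target[proposal] / target[current])``.  The chain needs only
relative probabilities, so the target is never normalised.  Synapse draws
for one detector are filtered through two rejection rules: a Chebyshev
locality box around a centroid (spatial clustering) and uniqueness of
pixels within the detector (no multapses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PixelMassVector",
    "SamplingTarget",
    "SamplingExhaustedError",
    "accumulate_global_distribution",
    "sqrt_transform",
    "MetropolisChain",
    "mh_chain",
    "draw_ade_pixels",
    "draw_replacement_pixel",
]

BURN_IN = 1_000
PROPOSAL_HALF_WIDTH = 3  # 7x7 offset box
DEFAULT_MAX_REJECTS = 10_000


class SamplingExhaustedError(RuntimeError):
    """Rejection sampling could not satisfy the locality/multapse rules."""


@dataclass(frozen=True)
class PixelMassVector:
    """Per-pixel accumulated value sums over a training set (one bin per pixel)."""

    mass: np.ndarray  # (rows*cols,) int64
    image_shape: tuple[int, int]

    @property
    def usable(self) -> bool:
        return bool((self.mass > 0).any())


@dataclass(frozen=True)
class SamplingTarget:
    """Unnormalised relative sampling probabilities: sqrt of the pixel mass."""

    relative_mass: np.ndarray  # (rows*cols,) float64
    image_shape: tuple[int, int]


def accumulate_global_distribution(
    images: Iterable[np.ndarray],
) -> PixelMassVector:
    """Sum every pixel value into one bin per pixel, overflow-safe (int64)."""
    total: np.ndarray | None = None
    shape: tuple[int, int] | None = None
    for img in images:
        img = np.asarray(img)
        if shape is None:
            shape = (img.shape[0], img.shape[1])
            total = np.zeros(shape[0] * shape[1], dtype=np.int64)
        elif img.shape != shape:
            raise ValueError(f"image shape {img.shape} != first shape {shape}")
        total += img.astype(np.int64).ravel()
    if total is None or shape is None:
        raise ValueError("need at least one image")
    return PixelMassVector(mass=total, image_shape=shape)


def sqrt_transform(mass: PixelMassVector) -> SamplingTarget:
    """Elementwise square root; deliberately left unnormalised."""
    return SamplingTarget(
        relative_mass=np.sqrt(mass.mass.astype(np.float64)),
        image_shape=mass.image_shape,
    )


class MetropolisChain:
    """Random-walk Metropolis sampler over the pixel grid of a target.

    The chain starts at the argmax pixel (guaranteed positive mass) and
    must be burned in before use; :func:`mh_chain` and
    :func:`draw_ade_pixels` do this automatically.  Consecutive states may
    repeat when a proposal is rejected — that is standard Metropolis and
    downstream rejection rules absorb the duplicates.
    """

    _BLOCK = 8192

    def __init__(self, target: SamplingTarget, seed: int):
        t = np.asarray(target.relative_mass, dtype=np.float64)
        if not (t > 0).any():
            raise ValueError("sampling target has no positive mass")
        self.rows, self.cols = target.image_shape
        self.target = t
        self._rng = np.random.default_rng(seed)
        self.state = int(np.argmax(t))
        self._burned_in = False
        # proposal offsets: 7x7 box minus (0, 0)
        k = PROPOSAL_HALF_WIDTH
        offs = [
            (dr, dc)
            for dr in range(-k, k + 1)
            for dc in range(-k, k + 1)
            if (dr, dc) != (0, 0)
        ]
        self._off = np.array(offs, dtype=np.int64)
        self._refill()

    def _refill(self) -> None:
        self._prop = self._rng.integers(0, len(self._off), size=self._BLOCK)
        self._unif = self._rng.random(size=self._BLOCK)
        self._pos = 0

    def step(self) -> int:
        """Advance one Metropolis step and return the new (flat) state."""
        r, c = divmod(self.state, self.cols)
        t_cur = self.target[self.state]
        while True:
            if self._pos >= self._BLOCK:
                self._refill()
            dr, dc = self._off[self._prop[self._pos]]
            u = self._unif[self._pos]
            self._pos += 1
            pr, pc = r + dr, c + dc
            if not (0 <= pr < self.rows and 0 <= pc < self.cols):
                continue  # border: re-propose
            prop = pr * self.cols + pc
            t_prop = self.target[prop]
            if t_prop >= t_cur or u * t_cur < t_prop:
                self.state = int(prop)
            return self.state

    def burn_in(self, n_steps: int = BURN_IN) -> None:
        for _ in range(n_steps):
            self.step()
        self._burned_in = True


def mh_chain(target: SamplingTarget, n_draws: int, seed: int) -> np.ndarray:
    """Return ``n_draws`` post-burn-in chain states as flat pixel indices."""
    chain = MetropolisChain(target, seed)
    chain.burn_in()
    return np.fromiter((chain.step() for _ in range(n_draws)), dtype=np.int64, count=n_draws)


def _chebyshev_ok(idx: int, ref: int, radius: int, cols: int) -> bool:
    r1, c1 = divmod(idx, cols)
    r2, c2 = divmod(ref, cols)
    return abs(r1 - r2) <= radius and abs(c1 - c2) <= radius


def draw_ade_pixels(
    target: SamplingTarget,
    n: int,
    locality_radius: int | None,
    seed: int | None = None,
    max_rejects: int = DEFAULT_MAX_REJECTS,
    chain: MetropolisChain | None = None,
    locality_from: Literal["centroid", "any"] = "centroid",
) -> tuple[int | None, np.ndarray]:
    """Draw one detector's pixel set from the chain.

    A centroid is drawn first from the global chain; every synapse pixel
    is then drawn from the same chain and rejected unless it falls in the
    ``(2r+1)``-sided Chebyshev box around the centroid (or, with
    ``locality_from="any"``, around any already-accepted pixel) and is not
    already used by this detector.  Returns ``(centroid, pixels)``;
    the centroid is ``None`` when no locality constraint is requested.
    """
    if chain is None:
        if seed is None:
            raise ValueError("need a seed when no chain is supplied")
        chain = MetropolisChain(target, seed)
        chain.burn_in()
    centroid = chain.step() if locality_radius is not None else None
    refs = [centroid] if centroid is not None else []
    chosen: list[int] = []
    for _ in range(n):
        pix = _draw_one(chain, locality_radius, refs, chosen, max_rejects,
                        locality_from, centroid)
        chosen.append(pix)
        if locality_from == "any":
            refs.append(pix)
    return centroid, np.array(chosen, dtype=np.int64)


def _draw_one(
    chain: MetropolisChain,
    radius: int | None,
    refs: Sequence[int],
    exclude: Sequence[int],
    max_rejects: int,
    locality_from: str,
    centroid: int | None,
) -> int:
    rejects = 0
    exclude_set = set(exclude)
    while True:
        cand = chain.step()
        ok = cand not in exclude_set
        if ok and radius is not None:
            near = any(
                _chebyshev_ok(cand, ref, radius, chain.cols) for ref in refs
            )
            ok = near
        if ok:
            return cand
        rejects += 1
        if rejects > max_rejects:
            where = f" near centroid {centroid}" if centroid is not None else ""
            raise SamplingExhaustedError(
                f"exceeded {max_rejects} rejections drawing a synapse pixel{where}"
            )


def draw_replacement_pixel(
    chain: MetropolisChain,
    centroid: int | None,
    radius: int | None,
    exclude: Sequence[int],
    max_rejects: int = DEFAULT_MAX_REJECTS,
) -> int:
    """Draw a single fresh pixel for structural replacement.

    Keeps the detector's original centroid and honours the same locality
    and multapse rules as the initial setup.
    """
    refs = [centroid] if (centroid is not None and radius is not None) else []
    return _draw_one(chain, radius if refs else None, refs, exclude,
                     max_rejects, "centroid", centroid)
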