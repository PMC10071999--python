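"""Set-intersection kernel view of the coincidence machinery.

Unrolling every 2D coincidence location across all planned memories into
one long binary vector **b** turns each input into a sparse point in an
m-dimensional feature space (m = sum of addressable locations over the
memories; for 3 full-size memories over 2,048-wide decoders,
m = 2048^2 * 3 = 12,582,912).  The logical AND of two such vectors is a
dot product, so the overlap count |a n b| is a valid Mercer kernel (a
set/histogram-intersection kernel) and Gram matrices built from it are
positive semi-definite.

On top of that kernel, least-squares classification (LSC) solves

    (K + ridge*I) h_i = y_i

for one-hot class targets y_i and predicts a new case by the largest
class indicator k* . h_i, where k* holds the new case's kernel values
against the training cases.  A small ridge keeps the solve stable when K
is near-singular; exact inversion corresponds to ridge = 0.

The subset diagnostics relate this back to the coincidence memories: the
per-class bit planes S{b_i} play the role of the hat vectors, and the
overlap of a new case's active-bit set o* with each S{b_i} is exactly
what inference counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .address_decoder import FiringPattern, batch_firing, prepare_inputs
from .pipeline import BitBrainModel
from .sbc_memory import ClassCounts, occupancy, pairwise_intersections, read_counts

__all__ = [
    "CoincidenceBitVector",
    "GramMatrix",
    "HatVectors",
    "SingularKernelError",
    "coincidence_space_size",
    "unroll_bit_vector",
    "unroll_dataset",
    "overlap_kernel",
    "gram_matrix",
    "lsc_fit",
    "lsc_predict",
    "class_subset_report",
]


class SingularKernelError(np.linalg.LinAlgError):
    """The Gram system is singular; add a ridge term to regularise."""


@dataclass(frozen=True)
class CoincidenceBitVector:
    """Sparse binary point in the unrolled coincidence space.

    ``active_bits`` are the sorted global indices of the coincidence
    locations an input activates; ``m`` is the length of the full space.
    """

    active_bits: np.ndarray  # sorted unique int64
    m: int

    def __post_init__(self) -> None:
        a = np.unique(np.asarray(self.active_bits, dtype=np.int64))
        if len(a) and (a[0] < 0 or a[-1] >= self.m):
            raise ValueError("active bits outside [0, m)")
        object.__setattr__(self, "active_bits", a)

    @property
    def cardinality(self) -> int:
        return len(self.active_bits)


@dataclass(frozen=True)
class GramMatrix:
    """Symmetric overlap-kernel matrix plus the ridge recorded for the solve."""

    K: np.ndarray
    ridge: float = 0.0

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=np.float64)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("K must be square")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")
        object.__setattr__(self, "K", K)


@dataclass(frozen=True)
class HatVectors:
    """Solved hat-vector matrix H (n x c) and the one-hot targets Y it fits."""

    H: np.ndarray
    class_targets: np.ndarray


def coincidence_space_size(model: BitBrainModel) -> int:
    """Length m of the unrolled bit vector over all planned memories."""
    return int(sum(sbc.n_locations for sbc in model.sbcs))


def planned_space_size(config) -> int:
    """Length m implied by a configuration, without allocating memories."""
    from .pipeline import expand_sbc_plan

    total = 0
    for e in expand_sbc_plan(config):
        w_row = config.ad_specs[e.row_ad].w
        w_col = config.ad_specs[e.col_ad].w
        total += w_row * (w_row - 1) // 2 if e.layout == "half" else w_row * w_col
    return total


def _sbc_offsets(model: BitBrainModel) -> np.ndarray:
    sizes = [sbc.n_locations for sbc in model.sbcs]
    return np.concatenate([[0], np.cumsum(sizes)])


def _pattern_locations(sbc, row: FiringPattern, col: FiringPattern) -> np.ndarray:
    # reuse the memory module's probing rule so the unrolled vector indexes
    # exactly the locations training would write
    from .sbc_memory import _probe_locations

    return _probe_locations(sbc, row, col)


def unroll_bit_vector(
    model: BitBrainModel, image: np.ndarray
) -> CoincidenceBitVector:
    """All coincidence locations one image activates, globally indexed."""
    vecs = unroll_dataset(model, np.asarray(image, dtype=np.uint8)[None])
    return vecs[0]


def unroll_dataset(
    model: BitBrainModel, images: np.ndarray
) -> list[CoincidenceBitVector]:
    """Unrolled bit vectors for an image stack (firing computed batchwise)."""
    images = np.asarray(images, dtype=np.uint8)
    firing = [
        batch_firing(ad, prepare_inputs(images, ad.synapse_type))
        for ad in model.decoders
    ]
    offsets = _sbc_offsets(model)
    m = int(offsets[-1])
    out = []
    for i in range(len(images)):
        pats = [
            FiringPattern(np.flatnonzero(f[i]), ad.w)
            for ad, f in zip(model.decoders, firing)
        ]
        parts = []
        for s, (sbc, entry) in enumerate(zip(model.sbcs, model.plan)):
            locs = _pattern_locations(
                sbc, pats[entry.row_ad], pats[entry.col_ad]
            )
            parts.append(locs + offsets[s])
        bits = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        out.append(CoincidenceBitVector(bits, m))
    return out


def overlap_kernel(a: CoincidenceBitVector, b: CoincidenceBitVector) -> int:
    """|a n b| — the set-intersection (AND-popcount) kernel."""
    if a.m != b.m:
        raise ValueError(f"bit-space sizes differ: {a.m} != {b.m}")
    return int(len(np.intersect1d(a.active_bits, b.active_bits, assume_unique=True)))


def gram_matrix(
    vectors: Sequence[CoincidenceBitVector], ridge: float | None = None
) -> GramMatrix:
    """Pairwise overlap kernel over a sample.

    ``ridge=None`` picks the default ``1e-6 * trace(K) / n``; pass 0 for
    the unregularised system.
    """
    n = len(vectors)
    K = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        K[i, i] = vectors[i].cardinality
        for j in range(i + 1, n):
            K[i, j] = K[j, i] = overlap_kernel(vectors[i], vectors[j])
    if ridge is None:
        ridge = 1e-6 * float(np.trace(K)) / max(n, 1)
    return GramMatrix(K=K, ridge=float(ridge))


def lsc_fit(K: GramMatrix, labels: Sequence[int], n_classes: int) -> HatVectors:
    """Solve (K + ridge*I) H = Y for one-hot class targets.

    With ridge = 0 this is the exact hat-vector system h_i = K^-1 y_i;
    a singular K then raises :class:`SingularKernelError` advising a
    ridge term.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n = K.K.shape[0]
    if len(labels) != n:
        raise ValueError(f"{len(labels)} labels for a {n}x{n} Gram matrix")
    Y = np.zeros((n, n_classes), dtype=np.float64)
    Y[np.arange(n), labels] = 1.0
    A = K.K + K.ridge * np.eye(n)
    try:
        H = scipy.linalg.solve(A, Y, assume_a="sym")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as err:
        raise SingularKernelError(
            "Gram system is singular; refit with a positive ridge"
        ) from err
    if not np.isfinite(H).all():
        raise SingularKernelError(
            "Gram solve produced non-finite hat vectors; refit with a positive ridge"
        )
    return HatVectors(H=H, class_targets=Y)


def lsc_predict(
    k_star: np.ndarray, hat: HatVectors
) -> tuple[np.ndarray, int]:
    """Class indicators k* . h_i and the argmax class (ties: lowest index)."""
    k_star = np.asarray(k_star, dtype=np.float64)
    if k_star.shape != (hat.H.shape[0],):
        raise ValueError(
            f"k_star length {k_star.shape} != training size {hat.H.shape[0]}"
        )
    indicators = k_star @ hat.H
    return indicators, int(np.argmax(indicators))


def class_subset_report(
    model: BitBrainModel, test_images: np.ndarray
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Subset-cardinality diagnostics of a trained model.

    Returns per-class set-bit cardinalities |S{b_i}| (the diagonal), the
    pairwise class-subset intersection matrix, and a per-test-case table
    with card(o*) and the overlap of o* with each class subset — the
    overlap with the true class of a training case equals card(o*)
    exactly, because every location a training case activates was
    written.
    """
    card = np.zeros(model.n_classes, dtype=np.int64)
    for sbc in model.sbcs:
        totals, _ = occupancy(sbc)
        card += totals
    inter = pairwise_intersections(model.sbcs)

    test_images = np.asarray(test_images, dtype=np.uint8)
    firing = [
        batch_firing(ad, prepare_inputs(test_images, ad.synapse_type))
        for ad in model.decoders
    ]
    rows = []
    for i in range(len(test_images)):
        pats = [
            FiringPattern(np.flatnonzero(f[i]), ad.w)
            for ad, f in zip(model.decoders, firing)
        ]
        total = ClassCounts(np.zeros(model.n_classes, dtype=np.int64))
        card_o = 0
        for sbc, entry in zip(model.sbcs, model.plan):
            rp, cp = pats[entry.row_ad], pats[entry.col_ad]
            card_o += len(_pattern_locations(sbc, rp, cp))
            total = total + read_counts(sbc, rp, cp)
        row = {"card_o_star": card_o, "predicted": int(np.argmax(total.counts))}
        row.update(
            {f"overlap_class_{c}": int(total.counts[c]) for c in range(model.n_classes)}
        )
        rows.append(row)
    return card, inter, pd.DataFrame(rows)
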