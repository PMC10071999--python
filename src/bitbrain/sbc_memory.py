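"""Sparse binary coincidence (SBC) memories.

An SBC memory is a 2D bit store indexed by pairs of ADE indices from a
row decoder and a column decoder, with one bit per class at every
location.  Supervised learning is a single pass: every coincidence
``(j active in the row AD, k active in the column AD)`` sets the bit of
the example's class at location ``(j, k)``.  Setting an already-set bit
changes nothing, which is what makes the pass idempotent and
order-independent.  Inference probes exactly the same locations and
counts set bits per class.

Two layouts exist.  ``full`` memories pair two distinct decoders and
address every ``(j, k)``.  ``half`` memories pair a decoder with itself;
only the strict upper triangle ``j < k`` describes unique within-AD
coincidences (the diagonal is a self-coincidence and carries no pairwise
information), so only those locations are addressable — two half-size
memories fit in the storage of one full-size one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .address_decoder import FiringPattern

__all__ = [
    "SBCMemory",
    "ClassCounts",
    "NoEvidenceWarning",
    "create_sbc",
    "write_coincidences",
    "read_counts",
    "predict",
    "occupancy",
    "pairwise_intersections",
    "random_forget",
]

Layout = Literal["full", "half"]

SBC_FORMAT_VERSION = 1


class NoEvidenceWarning(UserWarning):
    """Prediction requested with zero set-bit counts for every class."""


class CorruptModelError(RuntimeError):
    """Stored SBC bits disagree with their integrity sidecar."""


@dataclass(frozen=True)
class ClassCounts:
    """Per-class set-bit counts accumulated over probed coincidences."""

    counts: np.ndarray  # (n_classes,) int64

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(self.counts + other.counts)


@dataclass
class SBCMemory:
    """One coincidence bit store; see the module docstring for semantics.

    ``bits`` is held unpacked as a (n_locations, n_classes) uint8 array of
    0/1 flags; location order is row-major ``(j, k)`` for the full layout
    and lexicographic over the strict upper triangle for the half layout.
    """

    row_ad_id: int
    col_ad_id: int
    w_row: int
    w_col: int
    n_classes: int
    layout: Layout
    bits: np.ndarray = field(repr=False)

    @property
    def n_locations(self) -> int:
        if self.layout == "half":
            return self.w_row * (self.w_row - 1) // 2
        return self.w_row * self.w_col

    def popcount(self) -> int:
        return int(self.bits.sum())


def create_sbc(
    row_ad_id: int,
    col_ad_id: int,
    w_row: int,
    w_col: int,
    n_classes: int,
    layout: Layout = "full",
) -> SBCMemory:
    """Allocate a cleared memory; half layout requires row AD == column AD."""
    if layout == "half":
        if row_ad_id != col_ad_id or w_row != w_col:
            raise ValueError("half layout requires identical row and column ADs")
        n_loc = w_row * (w_row - 1) // 2
    elif layout == "full":
        n_loc = w_row * w_col
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if n_classes < 1:
        raise ValueError("need at least one class")
    return SBCMemory(
        row_ad_id=row_ad_id,
        col_ad_id=col_ad_id,
        w_row=w_row,
        w_col=w_col,
        n_classes=n_classes,
        layout=layout,
        bits=np.zeros((n_loc, n_classes), dtype=np.uint8),
    )


def _probe_locations(
    sbc: SBCMemory, row_pattern: FiringPattern, col_pattern: FiringPattern
) -> np.ndarray:
    """Flat location indices touched by a (row, col) pattern pair.

    This single path serves both writes and reads, so the probed set is
    identical for the two operations by construction.
    """
    if row_pattern.width != sbc.w_row or col_pattern.width != sbc.w_col:
        raise ValueError("firing-pattern widths do not match this memory")
    r = row_pattern.active
    c = col_pattern.active
    if len(r) == 0 or len(c) == 0:
        return np.empty(0, dtype=np.int64)
    if sbc.layout == "full":
        return (r[:, None] * sbc.w_col + c[None, :]).ravel()
    jj, kk = np.meshgrid(r, c, indexing="ij")
    mask = jj < kk
    j, k = jj[mask], kk[mask]
    # strict upper triangle, lexicographic: offset(j) + (k - j - 1)
    w = sbc.w_row
    return j * w - j * (j + 1) // 2 + (k - j - 1)


def write_coincidences(
    sbc: SBCMemory,
    row_pattern: FiringPattern,
    col_pattern: FiringPattern,
    label: int,
) -> SBCMemory:
    """Set the class bit at every coincidence location (idempotent OR)."""
    if not 0 <= label < sbc.n_classes:
        raise ValueError(f"label {label} outside [0, {sbc.n_classes})")
    locs = _probe_locations(sbc, row_pattern, col_pattern)
    sbc.bits[locs, label] = 1
    return sbc


def read_counts(
    sbc: SBCMemory, row_pattern: FiringPattern, col_pattern: FiringPattern
) -> ClassCounts:
    """Count set bits per class over exactly the writable location set."""
    locs = _probe_locations(sbc, row_pattern, col_pattern)
    if len(locs) == 0:
        return ClassCounts(np.zeros(sbc.n_classes, dtype=np.int64))
    return ClassCounts(sbc.bits[locs].sum(axis=0, dtype=np.int64))


def predict(total_counts: ClassCounts) -> int:
    """Argmax class; ties break toward the lowest class index."""
    counts = total_counts.counts
    if len(counts) < 1:
        raise ValueError("need at least one class")
    if not counts.any():
        warnings.warn(
            "all class counts are zero; defaulting to class 0", NoEvidenceWarning
        )
    return int(np.argmax(counts))


def occupancy(sbc: SBCMemory) -> tuple[np.ndarray, np.ndarray]:
    """Per-class set-bit totals and fractions of addressable locations."""
    totals = sbc.bits.sum(axis=0, dtype=np.int64)
    return totals, totals / sbc.n_locations


def pairwise_intersections(sbcs: Sequence[SBCMemory]) -> np.ndarray:
    """Class-subset intersection matrix summed over memories.

    Entry ``(a, b)`` is the number of coincidence locations where both
    class ``a``'s and class ``b``'s bits are set; the diagonal equals the
    per-class occupancy totals.
    """
    if not sbcs:
        raise ValueError("need at least one memory")
    c = sbcs[0].n_classes
    out = np.zeros((c, c), dtype=np.int64)
    for sbc in sbcs:
        if sbc.n_classes != c:
            raise ValueError("memories disagree on the number of classes")
        b = sbc.bits.astype(np.int64)
        out += b.T @ b
    return out


def random_forget(sbc: SBCMemory, n_bits: int, seed: int) -> SBCMemory:
    """Clear exactly ``n_bits`` uniformly-chosen set bits (continuous learning).

    Pairs with ongoing supervised writes to hold occupancy at a chosen
    level while the input distribution drifts.
    """
    set_flat = np.flatnonzero(sbc.bits.ravel())
    if n_bits > len(set_flat):
        raise ValueError(f"cannot forget {n_bits} bits, only {len(set_flat)} set")
    if n_bits == 0:
        return sbc
    rng = np.random.default_rng(seed)
    drop = rng.choice(set_flat, size=n_bits, replace=False)
    sbc.bits.ravel()[drop] = 0
    return sbc


# ---------------------------------------------------------------------------
# Serialization: packed bit plane + JSON sidecar


def save_sbc(sbc: SBCMemory, directory, name: str) -> None:
    """Write one memory as packed little-endian bits plus a JSON sidecar.

    The bit at address ``((j * w_col) + k) * n_classes + l`` (half layout:
    triangle-linearised location in place of ``j * w_col + k``) maps to
    bit ``address % 8`` of byte ``address // 8``.
    """
    directory = Path(directory)
    packed = np.packbits(sbc.bits.ravel(), bitorder="little")
    (directory / f"{name}.bits").write_bytes(packed.tobytes())
    totals, _ = occupancy(sbc)
    sidecar = {
        "version": SBC_FORMAT_VERSION,
        "row_ad_id": sbc.row_ad_id,
        "col_ad_id": sbc.col_ad_id,
        "w_row": sbc.w_row,
        "w_col": sbc.w_col,
        "n_classes": sbc.n_classes,
        "layout": sbc.layout,
        "popcounts": [int(t) for t in totals],
    }
    (directory / f"{name}.json").write_text(json.dumps(sidecar, indent=1))


def load_sbc(directory, name: str) -> SBCMemory:
    """Load a memory written by :func:`save_sbc`, verifying integrity."""
    directory = Path(directory)
    sidecar = json.loads((directory / f"{name}.json").read_text())
    if sidecar.get("version") != SBC_FORMAT_VERSION:
        raise CorruptModelError(
            f"unsupported SBC format version {sidecar.get('version')!r}"
        )
    sbc = create_sbc(
        sidecar["row_ad_id"],
        sidecar["col_ad_id"],
        sidecar["w_row"],
        sidecar["w_col"],
        sidecar["n_classes"],
        sidecar["layout"],
    )
    raw = np.frombuffer((directory / f"{name}.bits").read_bytes(), dtype=np.uint8)
    n_flat = sbc.n_locations * sbc.n_classes
    bits = np.unpackbits(raw, bitorder="little", count=n_flat)
    sbc.bits = bits.reshape(sbc.n_locations, sbc.n_classes).astype(np.uint8)
    totals, _ = occupancy(sbc)
    if [int(t) for t in totals] != sidecar["popcounts"]:
        raise CorruptModelError(f"popcount mismatch loading SBC {name!r}")
    return sbc
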