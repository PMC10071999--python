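"""IDX container I/O, pixel centering and the two pixel-noise models.

The IDX format is the MNIST/EMNIST container: a big-endian magic word
(0x00000803 for a rank-3 unsigned-byte image tensor, 0x00000801 for a
rank-1 label vector), big-endian 32-bit dimension sizes, then the raw
bytes.  Reading and writing preserve pixel values exactly.

Noise is always injected on the raw 0..255 pixel scale, before centering:
Gaussian noise is clamped at the 0/255 rails, salt-and-pepper replaces a
pixel with 0 or 255 equiprobably.  ``freeze_noise`` draws exactly one
noise realisation per image, seeded from (spec seed, image index), so the
same corrupted image is reused everywhere it appears — "static" noise.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .synthetic_data import LabelledImageSet

__all__ = [
    "SignedImage",
    "NoiseSpec",
    "IdxFormatError",
    "read_idx",
    "write_idx",
    "center_pixels",
    "add_gaussian_noise",
    "add_salt_pepper",
    "freeze_noise",
]

IMAGES_MAGIC = 0x00000803
LABELS_MAGIC = 0x00000801


class IdxFormatError(ValueError):
    """A malformed IDX file (bad magic, dimension mismatch, short payload)."""


@dataclass(frozen=True)
class SignedImage:
    """A centered image: raw uint8 pixels shifted by -127 into [-127, 128]."""

    values: np.ndarray  # (rows, cols) int16

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.min(initial=0) < -127 or v.max(initial=0) > 128:
            raise ValueError("centered pixels must lie in [-127, 128]")


@dataclass(frozen=True)
class NoiseSpec:
    """Which noise model to apply and at what level.

    ``level`` is the SD in raw pixel units for ``gaussian`` and the
    replacement probability for ``salt_pepper``; it is ignored for
    ``none``.
    """

    kind: Literal["none", "gaussian", "salt_pepper"] = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind == "gaussian" and self.level < 0:
            raise ValueError("gaussian level (SD) must be >= 0")
        if self.kind == "salt_pepper" and not 0.0 <= self.level <= 1.0:
            raise ValueError("salt_pepper level (probability) must be in [0, 1]")


# ---------------------------------------------------------------------------
# IDX container


def _read_header(fh, expected_magic: int, rank: int, path) -> tuple[int, ...]:
    head = fh.read(4 * (1 + rank))
    if len(head) < 4 * (1 + rank):
        raise IdxFormatError(f"{path}: truncated IDX header")
    words = struct.unpack(f">{1 + rank}I", head)
    if words[0] != expected_magic:
        raise IdxFormatError(
            f"{path}: bad magic 0x{words[0]:08x}, expected 0x{expected_magic:08x}"
        )
    return words[1:]


def read_idx(image_path, label_path) -> LabelledImageSet:
    """Load an image/label IDX pair into a :class:`LabelledImageSet`."""
    image_path, label_path = Path(image_path), Path(label_path)
    with open(image_path, "rb") as fh:
        n, rows, cols = _read_header(fh, IMAGES_MAGIC, 3, image_path)
        payload = fh.read()
    if len(payload) != n * rows * cols:
        raise IdxFormatError(
            f"{image_path}: payload holds {len(payload)} bytes, "
            f"header promises {n * rows * cols}"
        )
    images = np.frombuffer(payload, dtype=np.uint8).reshape(n, rows, cols).copy()

    with open(label_path, "rb") as fh:
        (n_labels,) = _read_header(fh, LABELS_MAGIC, 1, label_path)
        label_payload = fh.read()
    if len(label_payload) != n_labels:
        raise IdxFormatError(
            f"{label_path}: payload holds {len(label_payload)} labels, "
            f"header promises {n_labels}"
        )
    if n_labels != n:
        raise IdxFormatError(
            f"image count {n} ({image_path}) != label count {n_labels} ({label_path})"
        )
    labels = np.frombuffer(label_payload, dtype=np.uint8).astype(np.int64)
    n_classes = int(labels.max()) + 1 if n else 0
    return LabelledImageSet(images, labels, max(n_classes, 1))


def write_idx(dataset: LabelledImageSet, image_path, label_path) -> None:
    """Write a labelled set as a standard big-endian IDX image/label pair."""
    n = len(dataset)
    rows, cols = dataset.image_shape if n else (0, 0)
    if n:
        rows, cols = dataset.images.shape[1:]
    with open(image_path, "wb") as fh:
        fh.write(struct.pack(">4I", IMAGES_MAGIC, n, rows, cols))
        fh.write(np.ascontiguousarray(dataset.images, dtype=np.uint8).tobytes())
    with open(label_path, "wb") as fh:
        fh.write(struct.pack(">2I", LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Centering and noise


def center_pixels(image: np.ndarray) -> SignedImage:
    """Shift raw 8-bit pixels to a bipolar scale: out = in - 127."""
    image = np.asarray(image)
    if image.dtype != np.uint8 and (image.min() < 0 or image.max() > 255):
        raise ValueError("raw pixels must lie in [0, 255]")
    return SignedImage(image.astype(np.int16) - 127)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-even; the noise contract rounds ties away from 0
    return np.trunc(x + np.copysign(0.5, x))


def add_gaussian_noise(image: np.ndarray, sd: float, seed: int) -> np.ndarray:
    """Add i.i.d. clamped Gaussian noise on the raw pixel scale."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    image = np.asarray(image, dtype=np.uint8)
    if sd == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image.astype(np.float64) + rng.normal(0.0, sd, size=image.shape)
    return np.clip(_round_half_away(noisy), 0, 255).astype(np.uint8)


def add_salt_pepper(image: np.ndarray, p: float, seed: int) -> np.ndarray:
    """Replace each pixel with 0 or 255 (equiprobably) with probability p."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    image = np.asarray(image, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    replace = rng.random(size=image.shape) < p
    salt = rng.random(size=image.shape) < 0.5
    out = image.copy()
    out[replace] = np.where(salt[replace], 255, 0)
    return out


def _image_noise_seed(spec_seed: int, index: int) -> int:
    # stable per-image stream: subsetting a dataset must not reshuffle noise
    return int(np.random.SeedSequence((spec_seed, index)).generate_state(1)[0])


def freeze_noise(dataset: LabelledImageSet, spec: NoiseSpec) -> LabelledImageSet:
    """Apply one fixed noise realisation per image (static noise).

    The per-image stream is derived from ``(spec.seed, image_index)``, so
    calling twice with the same spec is bit-identical and independent of
    how the dataset is batched.
    """
    if spec.kind == "none":
        return dataset
    out = np.empty_like(dataset.images)
    for i, img in enumerate(dataset.images):
        s = _image_noise_seed(spec.seed, i)
        if spec.kind == "gaussian":
            out[i] = add_gaussian_noise(img, spec.level, s)
        elif spec.kind == "salt_pepper":
            out[i] = add_salt_pepper(img, spec.level, s)
        else:  # pragma: no cover - NoiseSpec validates kind
            raise ValueError(f"unknown noise kind {spec.kind!r}")
    return LabelledImageSet(out, dataset.labels.copy(), dataset.n_classes)
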