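"""Synthetic labelled image sets with MNIST-like statistical structure.

The classifier implemented by this package leans on two properties of
handwritten-character rasters: the global "ink" mass is concentrated away
from the image borders (corner pixels carry essentially no information),
and each class is distinguished by a small number of local features.  The
generator here reproduces both properties with the simplest renderer that
has them: each class is a fixed set of filled discs ("strokes") whose
centers are sampled from the central window of the image, and each sample
of the class is the prototype redrawn with a small integer translation and
a clamped Gaussian perturbation of the stroke intensities.

Every function is deterministic given its seed, so test fixtures are
regenerated rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ClassPrototype",
    "LabelledImageSet",
    "make_prototypes",
    "make_dataset",
    "default_benchmark",
]

#: margin kept free of stroke centers on every border, in pixels
CENTER_MARGIN = 4


@dataclass(frozen=True)
class ClassPrototype:
    """One class: a set of filled discs defining its ideal, noise-free image.

    Parameters
    ----------
    class_id
        Integer label of the class.
    stroke_set
        Tuples ``(row, col, radius, intensity)`` with center coordinates in
        pixels, disc radius in pixels and peak intensity in ``[0, 255]``.
    """

    class_id: int
    stroke_set: tuple[tuple[int, int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.stroke_set) < 1:
            raise ValueError("a prototype needs at least one stroke")
        for r, c, _rad, inten in self.stroke_set:
            if not 0 <= inten <= 255:
                raise ValueError(f"stroke intensity {inten} outside [0, 255]")


@dataclass
class LabelledImageSet:
    """A stack of uint8 raster images with integer class labels."""

    images: np.ndarray  # (n, rows, cols) uint8
    labels: np.ndarray  # (n,) int64
    n_classes: int
    image_shape: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n, rows, cols) array")
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if len(self.labels) and not (
            (self.labels >= 0).all() and (self.labels < self.n_classes).all()
        ):
            raise ValueError("labels must lie in [0, n_classes)")
        self.image_shape = (int(self.images.shape[1]), int(self.images.shape[2]))

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx: np.ndarray) -> "LabelledImageSet":
        return LabelledImageSet(self.images[idx], self.labels[idx], self.n_classes)


def make_prototypes(
    n_classes: int,
    image_shape: tuple[int, int] = (28, 28),
    strokes_per_class: int = 3,
    seed: int = 0,
) -> list[ClassPrototype]:
    """Draw one disc-set prototype per class.

    Stroke centers are uniform over the central ``(rows-8) x (cols-8)``
    window so the aggregate ink distribution is non-uniform and border
    pixels stay empty, mirroring the structure of digit rasters.  Radii are
    uniform in 2..3 px and intensities in 160..255.  Identical seeds give
    identical prototypes; a collision between two classes' stroke sets is
    resampled so prototypes are pairwise distinct.
    """
    rows, cols = image_shape
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if strokes_per_class < 1:
        raise ValueError("need at least 1 stroke per class")
    if rows <= 2 * CENTER_MARGIN or cols <= 2 * CENTER_MARGIN:
        raise ValueError(f"image_shape {image_shape} too small for center window")

    rng = np.random.default_rng(seed)
    protos: list[ClassPrototype] = []
    seen: set[tuple] = set()
    for cid in range(n_classes):
        while True:
            strokes = tuple(
                (
                    int(rng.integers(CENTER_MARGIN, rows - CENTER_MARGIN)),
                    int(rng.integers(CENTER_MARGIN, cols - CENTER_MARGIN)),
                    int(rng.integers(2, 4)),
                    int(rng.integers(160, 256)),
                )
                for _ in range(strokes_per_class)
            )
            if strokes not in seen:
                seen.add(strokes)
                break
        protos.append(ClassPrototype(class_id=cid, stroke_set=strokes))
    return protos


def _render(
    strokes: Sequence[tuple[int, int, int, int]],
    image_shape: tuple[int, int],
    dr: int,
    dc: int,
    intensity_offsets: np.ndarray | None,
) -> np.ndarray:
    """Rasterise discs, translated by (dr, dc); overlaps take the max."""
    rows, cols = image_shape
    img = np.zeros((rows, cols), dtype=np.int16)
    rr, cc = np.mgrid[0:rows, 0:cols]
    for i, (r, c, rad, inten) in enumerate(strokes):
        if intensity_offsets is not None:
            inten = int(np.clip(round(inten + intensity_offsets[i]), 0, 255))
        mask = (rr - (r + dr)) ** 2 + (cc - (c + dc)) ** 2 <= rad * rad
        np.maximum(img, np.where(mask, inten, 0), out=img)
    return img.astype(np.uint8)


def make_dataset(
    prototypes: Sequence[ClassPrototype],
    class_counts: Mapping[int, int],
    jitter_px: int = 1,
    intensity_noise_sd: float = 8.0,
    seed: int = 0,
) -> LabelledImageSet:
    """Render a labelled set from prototypes.

    ``class_counts`` maps class id to the exact number of images to emit,
    which expresses class imbalance directly.  Each image is its prototype
    translated by an integer offset uniform in ``[-jitter_px, +jitter_px]``
    per axis, with each stroke's intensity perturbed by clamped
    ``N(0, intensity_noise_sd)``.
    """
    if jitter_px < 0:
        raise ValueError("jitter_px must be >= 0")
    by_id = {p.class_id: p for p in prototypes}
    unknown = set(class_counts) - set(by_id)
    if unknown:
        raise ValueError(f"class_counts refers to unknown class ids {sorted(unknown)}")

    if not prototypes:
        raise ValueError("need at least one prototype")
    n_classes = max(p.class_id for p in prototypes) + 1
    shape = _infer_shape(prototypes)

    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cid in sorted(class_counts):
        proto = by_id[cid]
        n_strokes = len(proto.stroke_set)
        for _ in range(class_counts[cid]):
            dr, dc = rng.integers(-jitter_px, jitter_px + 1, size=2)
            offsets = (
                rng.normal(0.0, intensity_noise_sd, size=n_strokes)
                if intensity_noise_sd > 0
                else np.zeros(n_strokes)
            )
            images.append(_render(proto.stroke_set, shape, int(dr), int(dc), offsets))
            labels.append(cid)
    if not images:
        images_arr = np.zeros((0, *shape), dtype=np.uint8)
    else:
        images_arr = np.stack(images)
    return LabelledImageSet(images_arr, np.array(labels, dtype=np.int64), n_classes)


def _infer_shape(prototypes: Sequence[ClassPrototype]) -> tuple[int, int]:
    # prototypes carry no shape; the default raster is 28x28 unless a stroke
    # needs more room (strokes are constrained to the center window anyway)
    extent = max(
        max(r, c) + rad + 1 for p in prototypes for (r, c, rad, _i) in p.stroke_set
    )
    side = max(28, extent)
    return (side, side)


def default_benchmark(
    n_classes: int = 10,
    n_train_per_class: int = 200,
    n_test_per_class: int = 100,
    seed: int = 0,
) -> tuple[LabelledImageSet, LabelledImageSet]:
    """The package's standard synthetic task: balanced 28x28 disc classes.

    Train and test sets come from the same prototypes (drawn at ``seed``)
    but disjoint rendering streams.
    """
    protos = make_prototypes(n_classes, (28, 28), strokes_per_class=3, seed=seed)
    train = make_dataset(
        protos, {c: n_train_per_class for c in range(n_classes)}, seed=seed + 1
    )
    test = make_dataset(
        protos, {c: n_test_per_class for c in range(n_classes)}, seed=seed + 2
    )
    return train, test
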