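"""End-to-end training, inference and evaluation.

The full pipeline is: accumulate the global ink distribution of the
(optionally noise-frozen) training set, take its square root as the
sampling target, build the address decoders, run the unsupervised phase
(threshold homeostasis + structural plasticity, labels unread), then make
a single supervised pass through the training data writing every
coincidence into the planned SBC memories.  Inference computes each AD's
firing pattern once per image, sums set-bit counts per class across all
memories, and predicts the class with the highest sum.

The default configuration uses 4 decoders with ADE widths {6, 8, 10, 12}
(2,048 elements each) feeding 6 full-size cross-AD memories plus 4
half-size within-AD memories.  A lighter 3-decoder preset with widths
{6, 10, 12} and locality radii {2, 3, 4}, pairs only, is also provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import sbc_memory
from .address_decoder import (
    AddressDecoder,
    FiringPattern,
    UnsupervisedSchedule,
    batch_firing,
    build_address_decoder,
    prepare_inputs,
    unsupervised_learn,
)
from .io_encoding import NoiseSpec, freeze_noise
from .sampling import SamplingTarget, accumulate_global_distribution, sqrt_transform
from .sbc_memory import (
    ClassCounts,
    CorruptModelError,
    SBCMemory,
    create_sbc,
    load_sbc,
    predict,
    read_counts,
    save_sbc,
    write_coincidences,
)
from .synthetic_data import LabelledImageSet

__all__ = [
    "ADSpec",
    "SBCPlanEntry",
    "BitBrainConfig",
    "BitBrainModel",
    "default_config",
    "three_ad_config",
    "expand_sbc_plan",
    "train",
    "infer",
    "evaluate",
    "noise_sweep",
    "single_shot_curve",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ADSpec(BaseModel):
    """One address decoder: width ``n`` synapses per ADE, ``w`` ADEs."""

    w: int = Field(ge=1)
    n: int = Field(ge=1)
    locality_radius: int | None = None
    synapse_type: Literal["binary", "int8"] = "binary"


class SBCPlanEntry(BaseModel):
    row_ad: int
    col_ad: int
    layout: Literal["full", "half"] = "full"

    @model_validator(mode="after")
    def _check_half(self) -> "SBCPlanEntry":
        if self.layout == "half" and self.row_ad != self.col_ad:
            raise ValueError("half layout must pair a decoder with itself")
        return self


class BitBrainConfig(BaseModel):
    """Everything needed to train and serialize a model.

    ``sbc_plan`` is either the keyword ``"all_pairs_plus_half"`` (every
    cross-AD pair full-size plus one half-size memory per AD),
    ``"all_pairs"`` (cross-AD pairs only), or an explicit list of
    entries.  Named seeds keep every random stage independently
    reproducible.
    """

    ad_specs: list[ADSpec]
    sbc_plan: Literal["all_pairs_plus_half", "all_pairs"] | list[SBCPlanEntry] = (
        "all_pairs_plus_half"
    )
    target_rate: float = 0.01
    interval_t: int = 2000
    unsupervised_presentations: int | None = None
    adaptation_step: int = 1
    plasticity: bool = True
    replacement: bool = True
    train_noise: NoiseSpec = NoiseSpec()
    seeds: dict[str, int] = Field(
        default_factory=lambda: {"sampling": 1, "unsupervised": 2}
    )

    @model_validator(mode="after")
    def _check_plan(self) -> "BitBrainConfig":
        if isinstance(self.sbc_plan, list):
            k = len(self.ad_specs)
            for e in self.sbc_plan:
                if not (0 <= e.row_ad < k and 0 <= e.col_ad < k):
                    raise ValueError(f"SBC plan references missing decoder: {e}")
        return self


def default_config(w: int = 2048) -> BitBrainConfig:
    """4 ADs, widths {6, 8, 10, 12}, radii {2, 3, 3, 4}, 6 full + 4 half SBCs."""
    widths = (6, 8, 10, 12)
    radii = (2, 3, 3, 4)
    return BitBrainConfig(
        ad_specs=[
            ADSpec(w=w, n=n, locality_radius=r) for n, r in zip(widths, radii)
        ],
    )


def three_ad_config(w: int = 2048) -> BitBrainConfig:
    """3 ADs, widths {6, 10, 12}, radii {2, 3, 4}, 3 full SBCs, no half."""
    widths = (6, 10, 12)
    radii = (2, 3, 4)
    return BitBrainConfig(
        ad_specs=[
            ADSpec(w=w, n=n, locality_radius=r) for n, r in zip(widths, radii)
        ],
        sbc_plan="all_pairs",
    )


def expand_sbc_plan(config: BitBrainConfig) -> list[SBCPlanEntry]:
    """Resolve a plan keyword into explicit (row, col, layout) entries."""
    if isinstance(config.sbc_plan, list):
        return list(config.sbc_plan)
    k = len(config.ad_specs)
    entries = [
        SBCPlanEntry(row_ad=i, col_ad=j, layout="full")
        for i, j in combinations(range(k), 2)
    ]
    if config.sbc_plan == "all_pairs_plus_half":
        entries += [
            SBCPlanEntry(row_ad=i, col_ad=i, layout="half") for i in range(k)
        ]
    return entries


@dataclass
class BitBrainModel:
    """A trained model: fitted decoders plus populated coincidence memories.

    Inference-complete — no training data is retained.
    """

    config: BitBrainConfig
    target: SamplingTarget
    decoders: list[AddressDecoder]
    sbcs: list[SBCMemory]
    plan: list[SBCPlanEntry]
    n_classes: int
    image_shape: tuple[int, int]


def _derived_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


def _firing_patterns(
    model: BitBrainModel, images: np.ndarray
) -> list[np.ndarray]:
    """Boolean (m, w) firing matrices, one per decoder."""
    out = []
    for ad in model.decoders:
        X = prepare_inputs(images, ad.synapse_type)
        out.append(batch_firing(ad, X))
    return out


def train(config: BitBrainConfig, train_set: LabelledImageSet) -> BitBrainModel:
    """Unsupervised phase, then a single supervised pass in dataset order."""
    if len(train_set) == 0:
        raise ValueError("empty training set")
    n_classes = train_set.n_classes
    noisy = freeze_noise(train_set, config.train_noise)

    mass = accumulate_global_distribution(noisy.images)
    target = sqrt_transform(mass)

    sampling_seed = config.seeds.get("sampling", 1)
    decoders = [
        build_address_decoder(
            target,
            w=spec.w,
            n=spec.n,
            synapse_type=spec.synapse_type,
            locality_radius=spec.locality_radius,
            seed=_derived_seed(sampling_seed, i),
        )
        for i, spec in enumerate(config.ad_specs)
    ]

    schedule = UnsupervisedSchedule(
        n_presentations=config.unsupervised_presentations,
        interval_t=config.interval_t,
        target_rate=config.target_rate,
        step=config.adaptation_step,
        plasticity=config.plasticity,
        replacement=config.replacement,
        seed=config.seeds.get("unsupervised", 2),
    )
    unsupervised_learn(decoders, noisy.images, target, schedule)

    plan = expand_sbc_plan(config)
    sbcs = [
        create_sbc(
            e.row_ad,
            e.col_ad,
            config.ad_specs[e.row_ad].w,
            config.ad_specs[e.col_ad].w,
            n_classes,
            e.layout,
        )
        for e in plan
    ]

    model = BitBrainModel(
        config=config,
        target=target,
        decoders=decoders,
        sbcs=sbcs,
        plan=plan,
        n_classes=n_classes,
        image_shape=(noisy.images.shape[1], noisy.images.shape[2]),
    )
    supervised_pass(model, noisy)
    return model


def supervised_pass(model: BitBrainModel, dataset: LabelledImageSet) -> BitBrainModel:
    """One pass through ``dataset`` writing every coincidence (idempotent)."""
    firing = _firing_patterns(model, dataset.images)
    patterns = [
        [FiringPattern(np.flatnonzero(f[i]), ad.w) for ad, f in zip(model.decoders, firing)]
        for i in range(len(dataset))
    ]
    for i, label in enumerate(dataset.labels):
        for sbc, entry in zip(model.sbcs, model.plan):
            write_coincidences(
                sbc,
                patterns[i][entry.row_ad],
                patterns[i][entry.col_ad],
                int(label),
            )
    return model


def infer(
    model: BitBrainModel, images: np.ndarray | LabelledImageSet
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and per-image summed class counts.

    For every image each decoder's firing pattern is computed once; the
    per-class set-bit counts are accumulated across all memories and the
    class with the highest sum wins (ties toward the lowest index).
    """
    if isinstance(images, LabelledImageSet):
        images = images.images
    images = np.asarray(images, dtype=np.uint8)
    if images.ndim == 2:
        images = images[None]
    if (images.shape[1], images.shape[2]) != model.image_shape:
        raise ValueError(
            f"image shape {images.shape[1:]} != training shape {model.image_shape}"
        )
    firing = _firing_patterns(model, images)
    m = len(images)
    counts = np.zeros((m, model.n_classes), dtype=np.int64)
    labels = np.empty(m, dtype=np.int64)
    import warnings as _warnings

    for i in range(m):
        pats = [
            FiringPattern(np.flatnonzero(f[i]), ad.w)
            for ad, f in zip(model.decoders, firing)
        ]
        total = ClassCounts(np.zeros(model.n_classes, dtype=np.int64))
        for sbc, entry in zip(model.sbcs, model.plan):
            total = total + read_counts(sbc, pats[entry.row_ad], pats[entry.col_ad])
        counts[i] = total.counts
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", sbc_memory.NoEvidenceWarning)
            labels[i] = predict(total)
    return labels, counts


def evaluate(
    model: BitBrainModel, test_set: LabelledImageSet
) -> tuple[float, np.ndarray]:
    """Accuracy and a confusion matrix with rows indexed by true class."""
    if len(test_set) == 0:
        raise ValueError("cannot evaluate on an empty test set")
    pred, _ = infer(model, test_set)
    true = test_set.labels
    c = model.n_classes
    confusion = np.zeros((c, c), dtype=np.int64)
    np.add.at(confusion, (true, pred), 1)
    accuracy = float((pred == true).mean())
    return accuracy, confusion


def noise_sweep(
    config: BitBrainConfig,
    train_set: LabelledImageSet,
    test_set: LabelledImageSet,
    train_levels: Sequence[float],
    test_levels: Sequence[float],
    noise_kind: Literal["gaussian", "salt_pepper"] = "gaussian",
    seeds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Accuracy grid over train-noise x test-noise levels.

    One model is trained per training-noise level (frozen noise) and
    evaluated at every test-noise level; rows are train levels, columns
    test levels.
    """
    seeds = seeds or {"train_noise": 11, "test_noise": 12}
    grid = np.zeros((len(train_levels), len(test_levels)))
    for i, tl in enumerate(train_levels):
        kind = noise_kind if tl > 0 else "none"
        cfg = config.model_copy(
            update={
                "train_noise": NoiseSpec(
                    kind=kind, level=tl, seed=seeds.get("train_noise", 11)
                )
            }
        )
        model = train(cfg, train_set)
        for j, sl in enumerate(test_levels):
            if sl > 0:
                noisy = freeze_noise(
                    test_set,
                    NoiseSpec(kind=noise_kind, level=sl, seed=seeds.get("test_noise", 12)),
                )
            else:
                noisy = test_set
            grid[i, j], _ = evaluate(model, noisy)
    return pd.DataFrame(grid, index=list(train_levels), columns=list(test_levels))


def single_shot_curve(
    config: BitBrainConfig,
    train_set: LabelledImageSet,
    test_set: LabelledImageSet,
    per_class_ns: Sequence[int],
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy versus training-set size, from one example per class upward.

    For each ``n`` the training set is subsampled class-stratified without
    replacement (capped at the examples a class actually has — imbalanced
    sets simply exhaust their small classes), a full model is trained and
    evaluated, and mean/SD over ``repeats`` independent subsamples are
    reported.
    """
    rows = []
    for n in per_class_ns:
        if n < 1:
            raise ValueError("per-class n must be >= 1")
        accs = []
        for r in range(repeats):
            rng = np.random.default_rng(np.random.SeedSequence((seed, n, r)))
            idx = []
            for cls in range(train_set.n_classes):
                cls_idx = np.flatnonzero(train_set.labels == cls)
                take = min(n, len(cls_idx))
                if take:
                    idx.append(rng.choice(cls_idx, size=take, replace=False))
            sub = train_set.subset(np.sort(np.concatenate(idx)))
            model = train(config, sub)
            acc, _ = evaluate(model, test_set)
            accs.append(acc)
        rows.append(
            {
                "n_per_class": n,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model bundle serialization


def save_model(model: BitBrainModel, directory) -> None:
    """Write an inference-complete bundle: config, target, decoders, SBCs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": MODEL_FORMAT_VERSION,
        "n_classes": model.n_classes,
        "image_shape": list(model.image_shape),
        "n_sbcs": len(model.sbcs),
        "config": json.loads(model.config.model_dump_json()),
        "plan": [e.model_dump() for e in model.plan],
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=1))
    np.save(directory / "target.npy", model.target.relative_mass)
    for i, ad in enumerate(model.decoders):
        np.savez(
            directory / f"decoder_{i}.npz",
            pixels=ad.pixels,
            weights=ad.weights,
            longevities=ad.longevities,
            thresholds=ad.thresholds,
            centroids=ad.centroids,
        )
    for i, sbc in enumerate(model.sbcs):
        save_sbc(sbc, directory, f"sbc_{i}")


def load_model(directory) -> BitBrainModel:
    """Load a bundle written by :func:`save_model`, verifying integrity."""
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    if meta.get("version") != MODEL_FORMAT_VERSION:
        raise CorruptModelError(
            f"unsupported model format version {meta.get('version')!r}"
        )
    config = BitBrainConfig.model_validate(meta["config"])
    image_shape = tuple(meta["image_shape"])
    target = SamplingTarget(
        relative_mass=np.load(directory / "target.npy"), image_shape=image_shape
    )
    decoders = []
    for i, spec in enumerate(config.ad_specs):
        z = np.load(directory / f"decoder_{i}.npz")
        decoders.append(
            AddressDecoder(
                pixels=z["pixels"],
                weights=z["weights"],
                longevities=z["longevities"],
                thresholds=z["thresholds"],
                centroids=z["centroids"],
                synapse_type=spec.synapse_type,
                locality_radius=spec.locality_radius,
                image_shape=image_shape,
            )
        )
    plan = [SBCPlanEntry.model_validate(e) for e in meta["plan"]]
    sbcs = [load_sbc(directory, f"sbc_{i}") for i in range(meta["n_sbcs"])]
    return BitBrainModel(
        config=config,
        target=target,
        decoders=decoders,
        sbcs=sbcs,
        plan=plan,
        n_classes=meta["n_classes"],
        image_shape=image_shape,
    )
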