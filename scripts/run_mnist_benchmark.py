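#!/usr/bin/env python
"""Reproduce the MNIST/EMNIST-scale benchmarks on user-supplied IDX files.

These runs need the real datasets (60,000 training images), which this
repository does not ship; download the IDX files yourself (uncompressed)
and point this script at them.

Examples
--------
Coincidence-memory path (3 ADs of 2,048 ADEs, 3 full-size SBCs):

    python scripts/run_mnist_benchmark.py \
        --train-images train-images-idx3-ubyte --train-labels train-labels-idx1-ubyte \
        --test-images t10k-images-idx3-ubyte --test-labels t10k-labels-idx1-ubyte

Kernel least-squares path on class-stratified subsets (the Gram solve is
cubic in the training subset size, so keep --kernel-train moderate):

    python scripts/run_mnist_benchmark.py ... --kernel-train 2000 --kernel-test 1000
"""

from __future__ import annotations

import argparse
import time

import numpy as np

from bitbrain import io_encoding, kernel_analysis as ka, pipeline as pl


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--train-images", required=True)
    parser.add_argument("--train-labels", required=True)
    parser.add_argument("--test-images", required=True)
    parser.add_argument("--test-labels", required=True)
    parser.add_argument("--preset", choices=["three-ad", "default"], default="three-ad")
    parser.add_argument("--w", type=int, default=2048)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--kernel-train", type=int, default=0,
                        help="If > 0, also run the overlap-kernel LSC path on "
                             "a stratified training subset of this size.")
    parser.add_argument("--kernel-test", type=int, default=1000)
    args = parser.parse_args()

    train = io_encoding.read_idx(args.train_images, args.train_labels)
    test = io_encoding.read_idx(args.test_images, args.test_labels)
    print(f"train {len(train)} images, test {len(test)}, {train.n_classes} classes")

    preset = pl.three_ad_config if args.preset == "three-ad" else pl.default_config
    cfg = preset(w=args.w)
    cfg.seeds.update({"sampling": args.seed, "unsupervised": args.seed + 1})

    t0 = time.perf_counter()
    model = pl.train(cfg, train)
    print(f"training took {time.perf_counter() - t0:.1f} s")
    t0 = time.perf_counter()
    acc, _ = pl.evaluate(model, test)
    print(f"inference over {len(test)} images took {time.perf_counter() - t0:.1f} s")
    print(f"coincidence-memory accuracy: {acc:.4f}")

    if args.kernel_train > 0:
        rng = np.random.default_rng(args.seed)
        idx = []
        per = args.kernel_train // train.n_classes
        for c in range(train.n_classes):
            pool = np.flatnonzero(train.labels == c)
            idx.append(rng.choice(pool, size=min(per, len(pool)), replace=False))
        sub = train.subset(np.sort(np.concatenate(idx)))
        t0 = time.perf_counter()
        vecs = ka.unroll_dataset(model, sub.images)
        G = ka.gram_matrix(vecs)
        hat = ka.lsc_fit(G, sub.labels, train.n_classes)
        print(f"kernel fit on {len(sub)} cases took {time.perf_counter() - t0:.1f} s")
        test_idx = rng.choice(len(test), size=min(args.kernel_test, len(test)),
                              replace=False)
        tvecs = ka.unroll_dataset(model, test.images[test_idx])
        correct = 0
        for tv, lab in zip(tvecs, test.labels[test_idx]):
            k_star = np.array([ka.overlap_kernel(tv, v) for v in vecs], float)
            _, cls = ka.lsc_predict(k_star, hat)
            correct += cls == lab
        print(f"kernel-LSC accuracy on {len(tvecs)} test cases: "
              f"{correct / len(tvecs):.4f}")


if __name__ == "__main__":
    main()
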