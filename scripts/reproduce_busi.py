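#!/usr/bin/env python
"""Reproduce the real-data experiment on the BUSI breast-ultrasound images.

Requires the optional 'realnets' extra (torch + torchvision), downloaded
pretrained weights, and a local copy of the public BUSI collection arranged
as benign/ malignant/ normal/ subdirectories.  Extracts ResNet-50 deep
features and runs the equilibrium-optimizer wrapper (population 10, 100
iterations, phi=0.99/gamma=0.01, stratified 0.2 holdout) over ten repeated
splits, printing mean +/- SD holdout accuracy and selected-feature counts.

This is an external reproduction aid, not part of the test suite: the
reference mean accuracy for this configuration is about 94.7 +/- 2.5 %.

Usage:
    python scripts/reproduce_busi.py --data /path/to/BUSI --repeats 10
"""

from __future__ import annotations

import argparse

import numpy as np

from budl import (
    CostConfig,
    OptimizerConfig,
    TorchvisionBackend,
    extract_features,
    load_image_dataset,
    lookup_backbone,
    run_optimizer,
    stratified_holdout,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", required=True, help="BUSI root (folder per class)")
    parser.add_argument("--backbone", default="ResNet-50")
    parser.add_argument("--repeats", type=int, default=10)
    parser.add_argument("--base-seed", type=int, default=0)
    args = parser.parse_args()

    dataset = load_image_dataset(args.data)
    print(f"loaded {len(dataset)} images in classes {dataset.classes}")
    table = extract_features(dataset, lookup_backbone(args.backbone), TorchvisionBackend())
    print(f"extracted {table.n_samples}x{table.n_features} feature table")

    accs, sizes = [], []
    for repeat in range(args.repeats):
        seed = args.base_seed + repeat
        split = stratified_holdout(table.labels, 0.2, seed)
        cfg = OptimizerConfig(algorithm="eo", population_size=10, max_iterations=100, seed=seed)
        res = run_optimizer(table, split, CostConfig(), cfg)
        accs.append(100.0 * res.best_accuracy)
        sizes.append(res.n_selected)
        print(
            f"repeat {repeat}: accuracy {accs[-1]:.2f}% with {sizes[-1]} features "
            f"({res.elapsed_seconds:.0f} s)"
        )
    accs, sizes = np.array(accs), np.array(sizes)
    print(f"accuracy: {accs.mean():.1f} ± {accs.std(ddof=1):.1f} %")
    print(f"features: {sizes.mean():.0f} ± {sizes.std(ddof=1):.0f}")


if __name__ == "__main__":
    main()
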