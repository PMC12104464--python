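"""Desk-scale experiment harness.

Canned study conditions used by the examples, the test suite and the
reproduction script: a synthetic low-contrast dataset small enough to
train on one CPU core in under a minute per run, with 10% of the
training scans labeled.  Arms differ only in the ablation switch under
study; every arm of a comparison shares the dataset, the seed and the
iteration budget, and is scored by test-set Dice of the positive head
using the best-validation checkpoint.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data import SlicePair, SplitData, split_scans
from .network import NetworkConfig
from .synthetic import FixtureSpec, generate_arrays
from .trainer import TrainConfig, TrainResult, evaluate_split, fit

#: Desk-scale study conditions: 12 scans x 4 slices at 32x32, two classes,
#: low contrast and blurred boundaries; 10% labeled; depth-3/width-8 network;
#: 300 iterations of batch 8 with 4 labeled.
DESK_FIXTURE = dict(n_scans=12, slices_per_scan=4, image_size=32, n_classes=2)
DESK_NETWORK = dict(base_width=8, depth=3)
DESK_TRAIN = dict(iterations=300, batch_size=8, labeled_per_batch=4,
                  val_interval=100)
DESK_SPLIT = dict(labeled_fraction=0.1, val_fraction=0.15, test_fraction=0.25)


def _strip(p: SlicePair) -> SlicePair:
    return SlicePair(image=p.image, label=None, scan_id=p.scan_id,
                     slice_index=p.slice_index)


def make_desk_dataset(seed: int, **fixture_overrides) -> SplitData:
    """Synthetic dataset under the desk-scale conditions, split scan-disjointly."""
    spec = FixtureSpec(seed=seed, **{**DESK_FIXTURE, **fixture_overrides})
    pairs = generate_arrays(spec)
    groups = split_scans([p.scan_id for p in pairs], seed=seed, **DESK_SPLIT)
    by = {k: set(v) for k, v in groups.items()}
    return SplitData(
        labeled=[p for p in pairs if p.scan_id in by["labeled"]],
        unlabeled=[_strip(p) for p in pairs if p.scan_id in by["unlabeled"]],
        val=[p for p in pairs if p.scan_id in by["val"]],
        test=[p for p in pairs if p.scan_id in by["test"]],
    )


def desk_config(seed: int, **overrides) -> TrainConfig:
    net = NetworkConfig(n_classes=DESK_FIXTURE["n_classes"], **DESK_NETWORK)
    return TrainConfig(seed=seed, network=net, **{**DESK_TRAIN, **overrides})


def run_arm(data: SplitData, config: TrainConfig) -> dict[str, float]:
    """Train one arm and score its best-validation checkpoint on the test split."""
    result: TrainResult = fit(config, data)
    result.net.load_state_dict(result.best_state)
    metrics = evaluate_split(result.net, data.test,
                             config.build_network_config().n_classes,
                             head=config.inference_head)
    metrics["best_val_dice"] = result.best_val_dice
    metrics["final_gamma"] = result.threshold_state.gamma
    metrics["final_con_frac"] = float(result.log[-1]["con_frac"])
    return metrics


def compare_arms(seed: int, arm_overrides: dict[str, dict]) -> dict[str, dict]:
    """Train every arm on the same dataset/seed; returns name -> test metrics."""
    data = make_desk_dataset(seed)
    out = {}
    for name, overrides in arm_overrides.items():
        out[name] = run_arm(data, desk_config(seed, **overrides))
    return out


#: The comparisons the framework's claims rest on, at desk scale.
STANDARD_ARMS: dict[str, dict] = {
    "mpdc": {},
    "supervised_only": {"unsupervised": False},
    "fixed_threshold_0.5": {"threshold": 0.5},
    "two_branch": {"branches": "pos+rev"},
}
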