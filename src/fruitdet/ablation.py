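"""Four-way ablation harness: baseline, +DPL, +SA, +DPL+SA.

DPL (double prediction layer) swaps the single 4×-output neck for the
cropped deep-to-shallow neck with 2× and 4× outputs; SA (sample
allocation) swaps the one-positive-per-fruit focal supervision for the
expanded allocation with the continuous label value loss. Each
configuration is trained per seed on the same data and evaluated on the
held-out split; improvements are reported, not asserted, because tiny
stochastic runs need not reproduce full-scale orderings on every seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np

from .evaluation import evaluate
from .heatmap import allocate_samples
from .inference import DecodeConfig, detect_image
from .model import ModelConfig
from .training import TrainConfig, build_layer_targets, train

log = logging.getLogger(__name__)

ABLATION_ROWS = (
    ("baseline", "original_single", "original", "focal"),
    ("+DPL", "cropped_double", "original", "focal"),
    ("+SA", "original_single", "expanded", "continuous"),
    ("+DPL+SA", "cropped_double", "expanded", "continuous"),
)


def _positive_counts(dataset, cfg: TrainConfig, variant: str) -> float:
    """Mean positive-sample count per image under a row's allocation."""
    factors = {1: 2, 2: 4} if variant == "cropped_double" else {2: 4}
    strategy = cfg.allocation_strategy
    total = 0
    for _, ann in dataset:
        t = build_layer_targets(ann, cfg.encoding, factors)
        for layer in factors:
            total += int(allocate_samples(t.heat[layer], strategy).positive_mask.sum())
    return total / max(1, len(dataset))


def run_ablation(
    train_dataset,
    test_dataset,
    base_config: TrainConfig,
    seeds: tuple[int, ...] = (0,),
    model_config: ModelConfig | None = None,
    decode_config: DecodeConfig | None = None,
    out_path: str | Path | None = None,
) -> dict:
    """Train and evaluate all four configurations over the given seeds."""
    decode_config = decode_config or DecodeConfig(score_threshold=0.05)
    gts = [ann for _, ann in test_dataset]
    report: dict = {"rows": []}
    for name, variant, strategy, loss_choice in ABLATION_ROWS:
        cfg0 = replace(
            base_config,
            neck_variant=variant,
            allocation_strategy=strategy,
            loss_choice=loss_choice,
        )
        row = {
            "name": name,
            "neck_variant": variant,
            "allocation_strategy": strategy,
            "loss_choice": loss_choice,
            "positive_samples_per_image": _positive_counts(train_dataset, cfg0, variant),
            "seeds": [],
        }
        for seed in seeds:
            cfg = replace(cfg0, seed=seed)
            try:
                result = train(train_dataset, cfg, model_config=model_config)
                dets = [detect_image(result.model, im, decode_config) for im, _ in test_dataset]
                res = evaluate(dets, gts)
                row["seeds"].append({"seed": seed, **res.as_dict()})
            except Exception as exc:  # partial report with the failure noted
                log.exception("ablation row %s seed %d failed", name, seed)
                row["seeds"].append({"seed": seed, "error": str(exc)})
        ok = [s for s in row["seeds"] if "ap" in s]
        for metric in ("precision", "recall", "f1", "ap"):
            vals = [s[metric] for s in ok]
            row[f"mean_{metric}"] = float(np.mean(vals)) if vals else None
            row[f"std_{metric}"] = float(np.std(vals)) if vals else None
        report["rows"].append(row)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        with open(out_path, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
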