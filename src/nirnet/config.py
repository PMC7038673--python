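"""YAML (de)serialization for generator, architecture and training configs."""

from __future__ import annotations

import numpy as np
import yaml

from .dataset import SpectralGrid
from .network import ArchitectureSpec, ConvLayerSpec, PoolSpec
from .synthetic import BandSpec, GeneratorConfig
from .training import TrainingConfig

__all__ = [
    "generator_config_to_dict",
    "generator_config_from_dict",
    "architecture_to_dict",
    "architecture_from_dict",
    "training_config_to_dict",
    "training_config_from_dict",
    "save_yaml",
    "load_yaml",
]


def _bands(bands: list[BandSpec]) -> list[dict]:
    return [
        {"center": b.center, "width": b.width, "amplitude": b.amplitude}
        for b in bands
    ]


def _unbands(items: list[dict]) -> list[BandSpec]:
    return [BandSpec(d["center"], d["width"], d["amplitude"]) for d in items]


def generator_config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "grid": {
            "wn_start": config.grid.wn_start,
            "wn_end": config.grid.wn_end,
            "n_points": config.grid.n_points,
        },
        "n_classes": config.n_classes,
        "class_proportions": [float(p) for p in config.class_proportions],
        "shared_bands": _bands(config.shared_bands),
        "class_bands": [_bands(bl) for bl in config.class_bands],
        "baseline_offset_sd": config.baseline_offset_sd,
        "baseline_slope_sd": config.baseline_slope_sd,
        "multiplicative_scatter_sd": config.multiplicative_scatter_sd,
        "noise_sd": config.noise_sd,
        "n_samples": config.n_samples,
        "seed": config.seed,
        "class_names": list(config.class_names),
        "fixed_counts": config.fixed_counts,
    }


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    return GeneratorConfig(
        grid=SpectralGrid(**d["grid"]),
        n_classes=d["n_classes"],
        class_proportions=np.array(d["class_proportions"], dtype=np.float64),
        shared_bands=_unbands(d["shared_bands"]),
        class_bands=[_unbands(bl) for bl in d["class_bands"]],
        baseline_offset_sd=d.get("baseline_offset_sd", 0.0),
        baseline_slope_sd=d.get("baseline_slope_sd", 0.0),
        multiplicative_scatter_sd=d.get("multiplicative_scatter_sd", 0.0),
        noise_sd=d.get("noise_sd", 0.0),
        n_samples=d["n_samples"],
        seed=d.get("seed", 0),
        class_names=d.get("class_names"),
        fixed_counts=d.get("fixed_counts", False),
    )


def architecture_to_dict(arch: ArchitectureSpec) -> dict:
    return {
        "conv_layers": [
            {"kernel_width": c.kernel_width, "out_channels": c.out_channels,
             "stride": c.stride}
            for c in arch.conv_layers
        ],
        "pool": {"width": arch.pool.width, "stride": arch.pool.stride},
        "fc_widths": list(arch.fc_widths),
        "activation": arch.activation,
        "leaky_slope": arch.leaky_slope,
        "dropout_p": arch.dropout_p,
        "batch_norm": arch.batch_norm,
    }


def architecture_from_dict(d: dict) -> ArchitectureSpec:
    return ArchitectureSpec(
        conv_layers=tuple(ConvLayerSpec(**c) for c in d["conv_layers"]),
        pool=PoolSpec(**d.get("pool", {})),
        fc_widths=tuple(d["fc_widths"]),
        activation=d.get("activation", "relu"),
        leaky_slope=d.get("leaky_slope", 0.01),
        dropout_p=d.get("dropout_p", 0.5),
        batch_norm=d.get("batch_norm", True),
    )


def training_config_to_dict(config: TrainingConfig) -> dict:
    d = {k: getattr(config, k) for k in (
        "batch_size", "init_lr", "decay_rate", "decay_steps", "staircase",
        "l2_lambda", "total_rounds", "eval_every", "seed", "momentum",
        "target_test_accuracy", "dtype",
    )}
    return d


def training_config_from_dict(d: dict) -> TrainingConfig:
    return TrainingConfig(**d)


def save_yaml(d: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
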