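"""Desk-scale experiment designs: layer sweep, activation comparison,
initialization ablation, and baseline comparison.

Each experiment returns an :class:`ExperimentReport` whose rows are a
DataFrame (the CSV contract) and whose metadata records the seed and a
config hash, enough to re-run the experiment bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import pandas as pd

from . import baselines as bl
from .config import training_config_to_dict, save_yaml
from .dataset import SpectralDataset
from .network import default_architecture, predict_labels
from .training import TrainingConfig, TrainingLog, train

__all__ = [
    "SweepSpec",
    "ExperimentReport",
    "run_layer_sweep",
    "run_activation_comparison",
    "run_init_ablation",
    "run_baseline_comparison",
]

INIT_PAIRING = {
    "relu": "msra",
    "leaky_relu": "msra",
    "sigmoid": "xavier",
    "tanh": "xavier",
}


@dataclass(frozen=True)
class SweepSpec:
    conv_layer_counts: tuple[int, ...] = (3, 4, 5, 6)
    fc_layer_counts: tuple[int, ...] = (3, 4)
    rounds_per_cell: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.conv_layer_counts or not self.fc_layer_counts:
            raise ValueError("sweep grid must be non-empty")
        if any(c < 1 for c in self.conv_layer_counts + self.fc_layer_counts):
            raise ValueError("layer counts must be positive")


@dataclass
class ExperimentReport:
    name: str
    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    logs: dict[str, TrainingLog] = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """CSV rows plus a YAML config snapshot sufficient to re-run."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / f"{self.name}.csv", index=False)
        save_yaml(self.metadata, out / f"{self.name}_config.yaml")
        for tag, log in self.logs.items():
            log.to_csv(out / f"{self.name}_{tag}_log.csv")


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _final(log: TrainingLog) -> dict:
    row = log.rows[-1] if log.rows else {}
    return {
        "train_accuracy": row.get("train_accuracy"),
        "test_accuracy": row.get("test_accuracy"),
        "loss": row.get("train_loss"),
    }


def run_layer_sweep(
    train_ds: SpectralDataset,
    test_ds: SpectralDataset,
    spec: SweepSpec,
    training: TrainingConfig | None = None,
) -> ExperimentReport:
    """Train every conv-count x fc-count cell ("6C-3F" tags) with a shared
    seed and budget; rows sorted by final test accuracy, best first."""
    rows = []
    logs = {}
    for n_conv in spec.conv_layer_counts:
        for n_fc in spec.fc_layer_counts:
            tag = f"{n_conv}C-{n_fc}F"
            arch = default_architecture(
                n_classes=train_ds.n_classes, n_conv_layers=n_conv, n_fc_layers=n_fc
            )
            config = training or TrainingConfig(
                total_rounds=spec.rounds_per_cell,
                eval_every=max(spec.rounds_per_cell // 4, 1),
                seed=spec.seed,
            )
            config = TrainingConfig(**{**training_config_to_dict(config),
                                       "seed": spec.seed,
                                       "total_rounds": spec.rounds_per_cell})
            params, log = train(train_ds, test_ds, arch, config)
            logs[tag] = log
            rows.append({"architecture": tag, **_final(log)})
    frame = pd.DataFrame(rows).sort_values(
        "test_accuracy", ascending=False, kind="stable"
    ).reset_index(drop=True)
    meta = {
        "seed": spec.seed,
        "rounds_per_cell": spec.rounds_per_cell,
        "conv_layer_counts": list(spec.conv_layer_counts),
        "fc_layer_counts": list(spec.fc_layer_counts),
    }
    meta["config_hash"] = _config_hash(meta)
    return ExperimentReport("layer_sweep", frame, meta, logs)


def run_activation_comparison(
    train_ds: SpectralDataset,
    test_ds: SpectralDataset,
    activations: list[str],
    budget: int = 2000,
    seed: int = 0,
) -> ExperimentReport:
    """One run per activation, pairing each with its standard initializer
    (MSRA for ReLU/leaky-ReLU, Xavier for sigmoid/tanh)."""
    if not activations:
        raise ValueError("activations list must be non-empty")
    rows = []
    logs = {}
    for act in activations:
        if act not in INIT_PAIRING:
            raise ValueError(f"unknown activation {act!r}")
        init = INIT_PAIRING[act]
        arch = default_architecture(n_classes=train_ds.n_classes, activation=act)
        config = TrainingConfig(
            total_rounds=budget, eval_every=max(budget // 4, 1), seed=seed
        )
        params, log = train(train_ds, test_ds, arch, config, init_method=init)
        logs[act] = log
        rows.append({"activation": act, "init_method": init, **_final(log)})
    meta = {"seed": seed, "budget": budget, "activations": list(activations),
            "init_pairing": {a: INIT_PAIRING[a] for a in activations}}
    meta["config_hash"] = _config_hash(meta)
    return ExperimentReport("activation_comparison", pd.DataFrame(rows), meta, logs)


def run_init_ablation(
    train_ds: SpectralDataset,
    test_ds: SpectralDataset,
    budget: int = 2000,
    seed: int = 0,
    init_methods: tuple[str, str] = ("normal", "msra"),
) -> ExperimentReport:
    """Two matched-seed arms differing only in weight initialization
    (naive sd-0.01 Gaussian vs MSRA); logs keep full curves for plotting."""
    rows = []
    logs = {}
    arch = default_architecture(n_classes=train_ds.n_classes)
    for i, init in enumerate(init_methods):
        config = TrainingConfig(
            total_rounds=budget, eval_every=max(budget // 10, 1), seed=seed
        )
        params, log = train(train_ds, test_ds, arch, config, init_method=init)
        logs[init if init not in logs else f"{init}_{i}"] = log
        rows.append({"init_method": init, **_final(log)})
    meta = {"seed": seed, "budget": budget, "init_methods": list(init_methods)}
    meta["config_hash"] = _config_hash(meta)
    return ExperimentReport("init_ablation", pd.DataFrame(rows), meta, logs)


def run_baseline_comparison(
    train_ds: SpectralDataset,
    test_ds: SpectralDataset,
    models: list[str] = ("svm", "ga_svm", "ann", "cnn"),
    cnn_rounds: int = 2000,
    seed: int = 0,
    ga_config: bl.GAConfig | None = None,
) -> ExperimentReport:
    """Accuracy table over the model family (the Table-5-shaped design)."""
    rows = []
    for kind in models:
        if kind == "cnn":
            arch = default_architecture(n_classes=train_ds.n_classes)
            config = TrainingConfig(
                total_rounds=cnn_rounds, eval_every=max(cnn_rounds // 4, 1),
                seed=seed,
            )
            params, log = train(train_ds, test_ds, arch, config)
            pred = predict_labels(params, test_ds.spectra)
        elif kind == "svm":
            model = bl.fit_svm(train_ds)
            pred = bl.predict(model, test_ds.spectra)
        elif kind == "ga_svm":
            model = bl.fit_ga_svm(train_ds, ga_config or bl.GAConfig(seed=seed))
            pred = bl.predict(model, test_ds.spectra)
        elif kind == "ann":
            model = bl.fit_ann(train_ds, seed=seed)
            pred = bl.predict(model, test_ds.spectra)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        acc = float((pred == test_ds.labels).mean())
        rows.append({"model": kind, "test_accuracy": acc})
    meta = {"seed": seed, "models": list(models), "cnn_rounds": cnn_rounds,
            "n_train": train_ds.n_samples, "n_test": test_ds.n_samples}
    meta["config_hash"] = _config_hash(meta)
    return ExperimentReport("baseline_comparison", pd.DataFrame(rows), meta)
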