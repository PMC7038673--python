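"""Spectral dataset container, CSV I/O, label encoding and train/test splitting.

A dataset is a dense matrix of absorbance spectra sampled on a common
equally spaced wavenumber grid, with one integer class label per spectrum.
Class ids are 1-based externally (region 1..C); that convention is part of
the public contract of every function in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "SpectralDataset",
    "SplitSpec",
    "read_csv",
    "write_csv",
    "split_dataset",
    "one_hot_encode",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Equally spaced wavenumber axis in cm^-1 (inclusive endpoints)."""

    wn_start: float
    wn_end: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.wn_end > self.wn_start:
            raise ValueError(
                f"wn_end ({self.wn_end}) must exceed wn_start ({self.wn_start})"
            )
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points}")

    @property
    def spacing(self) -> float:
        return (self.wn_end - self.wn_start) / (self.n_points - 1)

    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wn_start, self.wn_end, self.n_points)


@dataclass
class SpectralDataset:
    """Absorbance spectra (n_samples x n_points) with 1-based integer labels."""

    spectra: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    grid: SpectralGrid

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        if self.spectra.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.spectra.shape[0]} spectra but {self.labels.shape[0]} labels"
            )
        if self.spectra.shape[1] != self.grid.n_points:
            raise ValueError(
                f"spectra have {self.spectra.shape[1]} points, grid has "
                f"{self.grid.n_points}"
            )
        C = len(self.class_names)
        if self.labels.size and (self.labels.min() < 1 or self.labels.max() > C):
            bad = self.labels[(self.labels < 1) | (self.labels > C)][0]
            raise ValueError(f"label {bad} outside [1, {C}]")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_points(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices: np.ndarray) -> "SpectralDataset":
        indices = np.asarray(indices)
        return SpectralDataset(
            self.spectra[indices], self.labels[indices], list(self.class_names), self.grid
        )


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: fraction of samples assigned to training."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def read_csv(path, class_names: list[str] | None = None) -> SpectralDataset:
    """Read a dataset from CSV: first column ``label``, remaining headers are
    wavenumbers as decimal strings.

    If *class_names* is given it declares C and labels are checked against it;
    otherwise C is taken as the maximum label and names are auto-generated.
    """
    frame = pd.read_csv(path)
    if frame.shape[1] < 2 or frame.columns[0] != "label":
        raise ValueError(f"{path}: first column must be 'label'")
    try:
        wn = np.array([float(c) for c in frame.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header: {exc}") from None
    body = frame.iloc[:, 1:]
    nonnum = body.columns[body.dtypes == object]
    if len(nonnum):
        raise ValueError(f"{path}: non-numeric absorbance in column {nonnum[0]}")
    spectra = body.to_numpy(dtype=np.float64)
    labels = frame["label"].to_numpy()
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"{path}: labels must be integers")
    if class_names is None:
        C = int(labels.max()) if labels.size else 1
        class_names = [f"class_{i}" for i in range(1, C + 1)]
    grid = SpectralGrid(float(wn[0]), float(wn[-1]), len(wn))
    return SpectralDataset(spectra, labels, class_names, grid)


def write_csv(dataset: SpectralDataset, path) -> None:
    """Write a dataset to the CSV dialect read by :func:`read_csv`.

    Absorbances are written with 17 significant digits so a round trip
    preserves them to well below 1e-12.
    """
    wn = dataset.grid.wavenumbers()
    frame = pd.DataFrame(dataset.spectra, columns=[repr(float(w)) for w in wn])
    frame.insert(0, "label", dataset.labels)
    frame.to_csv(path, index=False, float_format="%.17g")


def split_dataset(
    dataset: SpectralDataset, spec: SplitSpec
) -> tuple[SpectralDataset, SpectralDataset]:
    """Randomly partition into (train, test) with |train| = round(f * n).

    Stratified mode applies the same rounding per class, so class
    proportions carry over to both halves up to integer rounding.
    """
    n = dataset.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(spec.seed)
    if spec.stratified:
        train_idx: list[np.ndarray] = []
        test_idx: list[np.ndarray] = []
        for c in range(1, dataset.n_classes + 1):
            members = np.flatnonzero(dataset.labels == c)
            perm = rng.permutation(members)
            k = _round_half_up(spec.train_fraction * len(members))
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
        train = np.sort(np.concatenate(train_idx))
        test = np.sort(np.concatenate(test_idx))
    else:
        perm = rng.permutation(n)
        k = _round_half_up(spec.train_fraction * n)
        train, test = np.sort(perm[:k]), np.sort(perm[k:])
    if len(train) == 0 or len(test) == 0:
        raise ValueError(
            f"train_fraction {spec.train_fraction} leaves an empty partition at n={n}"
        )
    return dataset.subset(train), dataset.subset(test)


def one_hot_encode(labels: np.ndarray, C: int) -> np.ndarray:
    """One-hot matrix (n x C) from 1-based labels."""
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 1 or labels.max() > C):
        bad = labels[(labels < 1) | (labels > C)][0]
        raise ValueError(f"label {bad} outside [1, {C}]")
    out = np.zeros((labels.shape[0], C), dtype=np.float64)
    if labels.size:
        out[np.arange(labels.shape[0]), labels - 1] = 1.0
    return out
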