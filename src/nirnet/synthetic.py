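"""Synthetic NIR spectrum generator.

Emulates the statistical structure of diffuse-reflectance NIR absorbance
data from plant material: a handful of broad, heavily overlapping Gaussian
absorption bands shared by all samples, smaller class-specific bands that
carry the region signal, per-spectrum multiplicative scatter, an additive
linear baseline, and white measurement noise.  The default configuration
mirrors an 8-region tobacco study: 1609 points over 3800-10,000 cm^-1 and
a strongly imbalanced class distribution.

The generative model for a sample of class c on grid wavenumbers w is

    a(w) = [ sum_shared g(w) + sum_{class c} g(w) ] * (1 + m)
           + b0 + b1 * (w - w_mid) + eps(w)

with g a Gaussian band, m ~ N(0, scatter_sd^2), b0 ~ N(0, offset_sd^2),
b1 ~ N(0, slope_sd^2) and eps i.i.d. N(0, noise_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset, SpectralGrid

__all__ = [
    "BandSpec",
    "GeneratorConfig",
    "default_tobacco_like_config",
    "generate_dataset",
    "TOBACCO_REGION_NAMES",
    "TOBACCO_REGION_COUNTS",
]

# 8-region class structure of the motivating tobacco study
TOBACCO_REGION_NAMES = [
    "West", "Northwest", "Northeast", "Southeast",
    "North", "South", "Middle", "Southwest",
]
TOBACCO_REGION_COUNTS = [557, 7668, 1422, 326, 2897, 132, 164, 204]


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band: center/width in cm^-1, amplitude in AU."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(
            -0.5 * ((wavenumbers - self.center) / self.width) ** 2
        )


@dataclass
class GeneratorConfig:
    grid: SpectralGrid
    n_classes: int
    class_proportions: np.ndarray
    shared_bands: list[BandSpec]
    class_bands: list[list[BandSpec]]
    baseline_offset_sd: float = 0.0
    baseline_slope_sd: float = 0.0
    multiplicative_scatter_sd: float = 0.0
    noise_sd: float = 0.0
    n_samples: int = 0
    seed: int = 0
    class_names: list[str] | None = None
    # fixed_counts=True apportions exact per-class counts (largest remainder)
    # instead of sampling labels i.i.d. from class_proportions.
    fixed_counts: bool = False

    def __post_init__(self) -> None:
        self.class_proportions = np.asarray(self.class_proportions, dtype=np.float64)
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.class_proportions.shape != (self.n_classes,):
            raise ValueError("class_proportions length must equal n_classes")
        if abs(self.class_proportions.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions sum to {self.class_proportions.sum()!r}, not 1"
            )
        if np.any(self.class_proportions < 0):
            raise ValueError("class_proportions must be nonnegative")
        if len(self.class_bands) != self.n_classes:
            raise ValueError(
                f"{len(self.class_bands)} class band lists for {self.n_classes} classes"
            )
        for sd_name in (
            "baseline_offset_sd", "baseline_slope_sd",
            "multiplicative_scatter_sd", "noise_sd",
        ):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.grid.wn_start, self.grid.wn_end
        for band in self.shared_bands + [b for bl in self.class_bands for b in bl]:
            if not lo <= band.center <= hi:
                raise ValueError(f"band center {band.center} outside grid [{lo}, {hi}]")
        if self.class_names is None:
            self.class_names = [f"class_{i}" for i in range(1, self.n_classes + 1)]
        if len(self.class_names) != self.n_classes:
            raise ValueError("class_names length must equal n_classes")


def default_tobacco_like_config(n_samples: int, seed: int) -> GeneratorConfig:
    """Config emulating the 8-region tobacco data: 1609-point grid over
    3800-10,000 cm^-1, Table-1-proportioned imbalanced classes, broad shared
    CH/OH bands and two smaller distinct marker bands per region.
    """
    if n_samples < 8:
        raise ValueError(f"n_samples must be >= 8 (one per class), got {n_samples}")
    counts = np.array(TOBACCO_REGION_COUNTS, dtype=np.float64)
    shared = [
        BandSpec(4300.0, 150.0, 0.45),   # C-H combination
        BandSpec(5180.0, 120.0, 0.60),   # O-H / water combination
        BandSpec(6900.0, 200.0, 0.35),   # O-H first overtone
        BandSpec(8400.0, 250.0, 0.20),   # C-H second overtone
    ]
    class_bands = [
        [
            BandSpec(4600.0 + 340.0 * c, 60.0, 0.15),
            BandSpec(7300.0 + 160.0 * c, 90.0, 0.10),
        ]
        for c in range(8)
    ]
    return GeneratorConfig(
        grid=SpectralGrid(3800.0, 10000.0, 1609),
        n_classes=8,
        class_proportions=counts / counts.sum(),
        shared_bands=shared,
        class_bands=class_bands,
        baseline_offset_sd=0.05,
        baseline_slope_sd=1.5e-5,
        multiplicative_scatter_sd=0.05,
        noise_sd=0.005,
        n_samples=n_samples,
        seed=seed,
        class_names=list(TOBACCO_REGION_NAMES),
    )


def _apportion(proportions: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n into integer class counts."""
    quota = proportions * n
    counts = np.floor(quota).astype(np.int64)
    remainder = n - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_dataset(config: GeneratorConfig) -> SpectralDataset:
    """Draw a labeled synthetic dataset; bit-identical for equal configs."""
    rng = np.random.default_rng(config.seed)
    wn = config.grid.wavenumbers()
    n, p = config.n_samples, config.grid.n_points

    shared = np.zeros(p)
    for band in config.shared_bands:
        shared += band.profile(wn)
    class_profiles = np.empty((config.n_classes, p))
    for c in range(config.n_classes):
        class_profiles[c] = shared
        for band in config.class_bands[c]:
            class_profiles[c] += band.profile(wn)

    if config.fixed_counts:
        counts = _apportion(config.class_proportions, n)
        labels = np.repeat(np.arange(1, config.n_classes + 1), counts)
        labels = rng.permutation(labels)
    else:
        labels = rng.choice(
            np.arange(1, config.n_classes + 1), size=n, p=config.class_proportions
        )

    scatter = rng.normal(0.0, config.multiplicative_scatter_sd, size=n)
    offsets = rng.normal(0.0, config.baseline_offset_sd, size=n)
    slopes = rng.normal(0.0, config.baseline_slope_sd, size=n)
    noise = rng.normal(0.0, config.noise_sd, size=(n, p))

    centred_wn = wn - 0.5 * (config.grid.wn_start + config.grid.wn_end)
    spectra = (
        class_profiles[labels - 1] * (1.0 + scatter)[:, None]
        + offsets[:, None]
        + slopes[:, None] * centred_wn[None, :]
        + noise
    )
    return SpectralDataset(spectra, labels, list(config.class_names), config.grid)
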