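"""Comparison models: RBF-kernel SVM, GA-tuned SVM, and a shallow ANN.

All three share the fit/predict contract of the CNN so one evaluation path
scores every model.  The GA-SVM evolves (log2 cost, log2 gamma, a subset
mask over the leading principal components) by a generational genetic
algorithm whose fitness is cross-validated accuracy; PCA is fitted on the
training folds only.  The ANN is a single-hidden-layer sigmoid network
trained with the same SGD machinery as the CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import SpectralDataset
from .network import ArchitectureSpec, NetworkParameters, predict_labels
from .training import TrainingConfig, train

__all__ = [
    "GAConfig",
    "BaselineModel",
    "fit_svm",
    "fit_ga_svm",
    "fit_ann",
    "predict",
]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 12
    generations: int = 8
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    log2_cost_range: tuple[float, float] = (-5.0, 15.0)
    log2_gamma_range: tuple[float, float] = (-15.0, 3.0)
    n_components: int = 50
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("GA rates must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class BaselineModel:
    kind: str
    _sk: object | None = None
    _pca: object | None = None
    _mask: np.ndarray | None = None
    _net: NetworkParameters | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self._sk is not None or self._net is not None


def _check_multiclass(dataset: SpectralDataset) -> None:
    if len(np.unique(dataset.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")


def fit_svm(
    train_ds: SpectralDataset,
    cost: float = 10.0,
    kernel_width: float | None = None,
) -> BaselineModel:
    """Multiclass RBF-kernel SVM.  ``kernel_width`` is the RBF sigma
    (gamma = 1 / (2 sigma^2)); None uses the median-heuristic-style
    'scale' default."""
    _check_multiclass(train_ds)
    gamma = "scale" if kernel_width is None else 1.0 / (2.0 * kernel_width**2)
    clf = SVC(C=cost, kernel="rbf", gamma=gamma)
    clf.fit(train_ds.spectra, train_ds.labels)
    return BaselineModel(
        kind="svm", _sk=clf, metadata={"cost": cost, "gamma": gamma}
    )


def _cv_fitness(X, y, log2_cost, log2_gamma, mask, cv_folds, seed):
    """k-fold CV accuracy of PCA -> mask -> SVC; PCA fit on train folds only."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    n_comp = len(mask)
    accs = []
    for tr, va in skf.split(X, y):
        pca = PCA(n_components=n_comp, random_state=seed)
        Z_tr = pca.fit_transform(X[tr])[:, mask]
        Z_va = pca.transform(X[va])[:, mask]
        clf = SVC(C=2.0**log2_cost, kernel="rbf", gamma=2.0**log2_gamma)
        clf.fit(Z_tr, y[tr])
        accs.append(float((clf.predict(Z_va) == y[va]).mean()))
    return float(np.mean(accs))


def fit_ga_svm(train_ds: SpectralDataset, ga: GAConfig = GAConfig()) -> BaselineModel:
    """Genetic-algorithm-tuned SVM over (cost, gamma, PC subset).

    Generational GA with tournament selection (size 2), single-point
    crossover on the mask, Gaussian perturbation of the log hyperparameters,
    bit-flip mutation, and elitism of 1 — so the best fitness never
    decreases across generations.
    """
    _check_multiclass(train_ds)
    X, y = train_ds.spectra, train_ds.labels
    counts = np.bincount(y)[1:]
    if ga.cv_folds > counts[counts > 0].min():
        raise ValueError(
            f"cv_folds={ga.cv_folds} exceeds the smallest class count "
            f"({int(counts[counts > 0].min())})"
        )
    n_comp = int(min(ga.n_components, X.shape[1], X.shape[0] - 1))
    rng = np.random.default_rng(ga.seed)

    def random_individual():
        lc = rng.uniform(*ga.log2_cost_range)
        lg = rng.uniform(*ga.log2_gamma_range)
        mask = rng.random(n_comp) < 0.5
        if not mask.any():
            mask[rng.integers(n_comp)] = True
        return [lc, lg, mask]

    def evaluate(ind):
        return _cv_fitness(X, y, ind[0], ind[1], ind[2], ga.cv_folds, ga.seed)

    pop = [random_individual() for _ in range(ga.population_size)]
    fitness = [evaluate(ind) for ind in pop]
    history = [max(fitness)]

    for _ in range(ga.generations - 1):
        elite = int(np.argmax(fitness))
        new_pop = [[pop[elite][0], pop[elite][1], pop[elite][2].copy()]]
        while len(new_pop) < ga.population_size:
            def tournament():
                i, j = rng.integers(ga.population_size, size=2)
                return pop[i] if fitness[i] >= fitness[j] else pop[j]

            a, b = tournament(), tournament()
            child = [a[0], a[1], a[2].copy()]
            if rng.random() < ga.crossover_rate:
                point = rng.integers(1, n_comp) if n_comp > 1 else 0
                child[2] = np.concatenate([a[2][:point], b[2][point:]])
                child[0] = 0.5 * (a[0] + b[0])
                child[1] = 0.5 * (a[1] + b[1])
            if rng.random() < ga.mutation_rate:
                child[0] = float(
                    np.clip(child[0] + rng.normal(0, 1.0), *ga.log2_cost_range)
                )
            if rng.random() < ga.mutation_rate:
                child[1] = float(
                    np.clip(child[1] + rng.normal(0, 1.0), *ga.log2_gamma_range)
                )
            flip = rng.random(n_comp) < ga.mutation_rate
            child[2] = child[2] ^ flip
            if not child[2].any():
                child[2][rng.integers(n_comp)] = True
            new_pop.append(child)
        pop = new_pop
        fitness = [evaluate(ind) for ind in pop]
        history.append(max(max(fitness), history[-1]))

    best = pop[int(np.argmax(fitness))]
    pca = PCA(n_components=n_comp, random_state=ga.seed)
    Z = pca.fit_transform(X)[:, best[2]]
    clf = SVC(C=2.0 ** best[0], kernel="rbf", gamma=2.0 ** best[1])
    clf.fit(Z, y)
    return BaselineModel(
        kind="ga_svm",
        _sk=clf,
        _pca=pca,
        _mask=best[2],
        metadata={
            "log2_cost": best[0],
            "log2_gamma": best[1],
            "n_components_used": int(best[2].sum()),
            "fitness_history": history,
        },
    )


def fit_ann(
    train_ds: SpectralDataset,
    hidden_width: int = 64,
    epochs: int = 20,
    lr: float = 0.01,
    seed: int = 0,
) -> BaselineModel:
    """Three-layer shallow network: input -> sigmoid hidden -> softmax output,
    trained with the same SGD loop as the CNN (Xavier init, no dropout/BN)."""
    if hidden_width < 1:
        raise ValueError("hidden_width must be >= 1")
    _check_multiclass(train_ds)
    C = train_ds.n_classes
    arch = ArchitectureSpec(
        conv_layers=(),
        fc_widths=(hidden_width, C),
        activation="sigmoid",
        dropout_p=0.0,
        batch_norm=False,
    )
    batch = 16
    rounds = epochs * max(train_ds.n_samples // batch, 1)
    config = TrainingConfig(
        batch_size=batch,
        init_lr=lr,
        l2_lambda=0.0,
        total_rounds=rounds,
        eval_every=max(rounds, 1),
        seed=seed,
    )
    params, log = train(train_ds, None, arch, config)
    return BaselineModel(
        kind="ann",
        _net=params,
        metadata={"hidden_width": hidden_width, "epochs": epochs, "lr": lr},
    )


def predict(model: BaselineModel, spectra: np.ndarray) -> np.ndarray:
    """1-based predicted labels for each spectrum."""
    if not model.fitted:
        raise RuntimeError("model must be fitted before predict")
    spectra = np.asarray(spectra, dtype=np.float64)
    if model.kind == "ann":
        return predict_labels(model._net, spectra)
    if model._pca is not None:
        Z = model._pca.transform(spectra)[:, model._mask]
        return model._sk.predict(Z)
    return model._sk.predict(spectra)
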