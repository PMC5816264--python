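"""GA-tuned soft-margin RBF-kernel classification of feature tables.

The classifier is a standard C-SVM with radial basis kernel (one-vs-one
multiclass, as is conventional for the (c, g) parameter pairing), with
features z-scored per dimension on the training split. The penalty ``c`` and
kernel width ``g`` are searched in log2 space by a seeded genetic algorithm
whose fitness is stratified k-fold cross-validated accuracy on the training
table; elitism makes the best-so-far trace non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import feature_columns


@dataclass(frozen=True)
class SVMParams:
    c: float
    g: float

    def __post_init__(self):
        if self.c <= 0 or self.g <= 0:
            raise ValueError("c and g must be strictly positive")


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    max_generation: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.1
    mutation_sd: float = 1.0
    c_range: tuple[float, float] = (-5.0, 15.0)   # log2 bounds
    g_range: tuple[float, float] = (-15.0, 3.0)   # log2 bounds
    cv_folds: int = 5
    elite: int = 1
    stagnation_patience: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_generation < 1:
            raise ValueError("max_generation must be >= 1")
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.c_range[0] >= self.c_range[1] or self.g_range[0] >= self.g_range[1]:
            raise ValueError("search ranges must be ordered (lo < hi)")


@dataclass
class Model:
    """A fitted classifier plus its label set and training accuracy."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    params: SVMParams
    train_accuracy: float


@dataclass
class Evaluation:
    per_class_recall: dict[str, float]
    overall_accuracy: float
    confusion: pd.DataFrame


def _xy(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cols = feature_columns(features)
    if not cols:
        raise ValueError("feature table has no f.. columns")
    if "gesture" not in features.columns:
        raise ValueError("feature table lacks a 'gesture' label column")
    X = features[cols].to_numpy(dtype=float)
    y = features["gesture"].to_numpy()
    return X, y


def _make_pipeline(params: SVMParams) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(C=params.c, gamma=params.g, kernel="rbf")),
    ])


def cv_fitness(params: SVMParams, features: pd.DataFrame,
               folds: int = 5, seed: int = 0) -> float:
    """Mean held-out accuracy over seeded stratified folds."""
    X, y = _xy(features)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 classes for cross-validation")
    for lab, cnt in zip(labels, counts):
        if cnt < folds:
            raise ValueError(
                f"class '{lab}' has {cnt} samples, fewer than {folds} folds")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = cross_val_score(_make_pipeline(params), X, y, cv=cv,
                             scoring="accuracy")
    return float(scores.mean())


def ga_optimize(features: pd.DataFrame,
                ga: GAConfig = GAConfig()) -> tuple[SVMParams, list[float]]:
    """Genetic search over (log2 c, log2 g) maximizing CV accuracy.

    Binary-tournament selection, uniform crossover, per-gene Gaussian
    mutation in log2 space, elitism of ``ga.elite``; stops early when the
    best fitness has not improved for ``stagnation_patience`` generations.
    Returns the best-ever parameters and the per-generation best-so-far
    fitness trace (non-decreasing by elitism).
    """
    rng = np.random.default_rng(np.random.SeedSequence(ga.seed))
    lo = np.array([ga.c_range[0], ga.g_range[0]])
    hi = np.array([ga.c_range[1], ga.g_range[1]])
    pop = rng.uniform(lo, hi, size=(ga.population_size, 2))
    cache: dict[tuple[float, float], float] = {}

    def fitness(genes: np.ndarray) -> float:
        key = (round(float(genes[0]), 9), round(float(genes[1]), 9))
        if key not in cache:
            params = SVMParams(c=2.0 ** key[0], g=2.0 ** key[1])
            cache[key] = cv_fitness(params, features, folds=ga.cv_folds,
                                    seed=ga.seed)
        return cache[key]

    fits = np.array([fitness(ind) for ind in pop])
    best_idx = int(np.argmax(fits))
    best_genes, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace = [best_fit]
    stagnant = 0

    for _ in range(1, ga.max_generation):
        order = np.argsort(-fits)
        new_pop = [pop[i].copy() for i in order[:ga.elite]]
        while len(new_pop) < ga.population_size:
            # binary tournaments
            a, b = rng.integers(0, ga.population_size, 2)
            p1 = pop[a] if fits[a] >= fits[b] else pop[b]
            a, b = rng.integers(0, ga.population_size, 2)
            p2 = pop[a] if fits[a] >= fits[b] else pop[b]
            child = p1.copy()
            if rng.random() < ga.crossover_rate:
                mask = rng.random(2) < 0.5
                child[mask] = p2[mask]
            mutate = rng.random(2) < ga.mutation_rate
            child[mutate] += rng.normal(0.0, ga.mutation_sd, 2)[mutate]
            new_pop.append(np.clip(child, lo, hi))
        pop = np.asarray(new_pop)
        fits = np.array([fitness(ind) for ind in pop])
        gen_best = int(np.argmax(fits))
        if float(fits[gen_best]) > best_fit:
            best_fit = float(fits[gen_best])
            best_genes = pop[gen_best].copy()
            stagnant = 0
        else:
            stagnant += 1
        trace.append(best_fit)
        if stagnant >= ga.stagnation_patience:
            break
    return SVMParams(c=2.0 ** float(best_genes[0]),
                     g=2.0 ** float(best_genes[1])), trace


def train(params: SVMParams, features: pd.DataFrame) -> Model:
    """Fit the scaled RBF-SVM on a labeled feature table."""
    X, y = _xy(features)
    if X.shape[0] == 0:
        raise ValueError("empty training table")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("degenerate training table: all feature rows identical")
    pipe = _make_pipeline(params)
    pipe.fit(X, y)
    acc = float(np.mean(pipe.predict(X) == y))
    classes = tuple(str(c) for c in pipe.named_steps["svm"].classes_)
    return Model(pipeline=pipe, classes=classes, params=params,
                 train_accuracy=acc)


def evaluate(model: Model, test: pd.DataFrame) -> Evaluation:
    """Per-class recall, overall accuracy, and confusion matrix on test data."""
    X, y = _xy(test)
    if X.shape[0] == 0:
        raise ValueError("empty test table")
    unseen = set(map(str, np.unique(y))) - set(model.classes)
    if unseen:
        raise ValueError(f"test set contains unseen class labels: {sorted(unseen)}")
    pred = model.pipeline.predict(X)
    labels = list(model.classes)
    cm = confusion_matrix(y, pred, labels=labels)
    recall = {}
    for i, lab in enumerate(labels):
        n = cm[i].sum()
        if n > 0:
            recall[lab] = float(cm[i, i] / n)
    overall = float(np.trace(cm) / cm.sum())
    confusion = pd.DataFrame(cm, index=labels, columns=labels)
    return Evaluation(per_class_recall=recall, overall_accuracy=overall,
                      confusion=confusion)
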