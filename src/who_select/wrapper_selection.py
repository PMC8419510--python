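"""Wrapper feature selection: continuous herd positions -> binary masks ->
cross-validated classifier fitness.

The minimized fitness is the standard wrapper blend

    error_weight * CV-misclassification-error
      + (1 - error_weight) * (selected count / n_features)

so that among equally accurate subsets the smaller one wins.  Fold
assignment is stratified and derived deterministically from the fitness
seed, making every fitness value reproducible bit-for-bit.

The k-NN route is evaluated with a precomputed per-feature squared-distance
stack: the distance matrix of any feature subset is a sum of per-feature
slices, which keeps a single fitness evaluation in the sub-millisecond
range for the problem sizes used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import metrics as _metrics
from .who_core import BoundsSpec, OptimizeResult, RandomSource, WHOConfig, optimize

__all__ = [
    "FeatureMatrix",
    "LabelVector",
    "SelectionMask",
    "FitnessConfig",
    "SelectionResult",
    "SubsetFitnessEvaluator",
    "binarize",
    "subset_fitness",
    "select_features",
    "baseline_search",
    "repeated_runs",
    "who_evaluation_budget",
]

# above this many matrix cells in the stack, fall back to on-the-fly distances
_STACK_CELL_LIMIT = 80_000_000


@dataclass
class FeatureMatrix:
    values: np.ndarray
    feature_names: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        n, d = self.values.shape
        if n < 4 or d < 2:
            raise ValueError("need n_samples >= 4 and n_features >= 2")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal n_features")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values: np.ndarray) -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        names = [f"f{i}" for i in range(values.shape[1])]
        return cls(values, names)


@dataclass
class LabelVector:
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if self.labels.ndim != 1:
            raise ValueError("labels must be 1-D")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class SelectionMask:
    selected: tuple  # length n_features, entries 0/1

    def __post_init__(self) -> None:
        sel = tuple(int(v) for v in self.selected)
        if not set(sel) <= {0, 1}:
            raise ValueError("mask entries must be 0/1")
        if sum(sel) < 1:
            raise ValueError("mask must select at least one feature")
        object.__setattr__(self, "selected", sel)

    @property
    def count(self) -> int:
        return sum(self.selected)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.selected))

    @classmethod
    def from_indices(cls, indices: Sequence[int], n_features: int) -> "SelectionMask":
        sel = np.zeros(n_features, dtype=int)
        sel[list(indices)] = 1
        return cls(tuple(sel))


@dataclass(frozen=True)
class FitnessConfig:
    error_weight: float = 0.99
    classifier: str = "knn"
    knn_k: int = 5
    cv_folds: int = 5
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_weight <= 1.0:
            raise ValueError("error_weight must be in [0, 1]")
        if self.classifier not in ("knn", "linear-svm"):
            raise ValueError("classifier must be 'knn' or 'linear-svm'")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError("knn_k must be a positive odd integer")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "error_weight": self.error_weight,
            "classifier": self.classifier,
            "knn_k": self.knn_k,
            "cv_folds": self.cv_folds,
            "threshold": self.threshold,
            "seed": self.seed,
        }


@dataclass
class SelectionResult:
    mask: SelectionMask
    fitness: float
    trace: List[float]
    config: dict
    evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "mask": list(self.mask.selected),
            "selected_indices": [int(i) for i in self.mask.indices],
            "count": self.mask.count,
            "fitness": float(self.fitness),
            "trace": [float(v) for v in self.trace],
            "config": self.config,
            "evaluations": int(self.evaluations),
        }


def binarize(position: np.ndarray, threshold: float) -> SelectionMask:
    """Threshold a continuous position into a mask; an all-zero result is
    repaired by selecting the single largest component."""
    position = np.asarray(position, dtype=float)
    sel = (position > threshold).astype(int)
    if sel.sum() == 0:
        sel[int(np.argmax(position))] = 1
    return SelectionMask(tuple(sel))


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold codes; every fold contains both
    classes, else a contract error."""
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_folds:
            raise ValueError(
                f"class {cls} has {idx.size} samples; cannot stratify into "
                f"{n_folds} folds with both classes in every fold"
            )
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


class SubsetFitnessEvaluator:
    """Caches everything mask-independent (fold codes and the per-feature
    squared-distance stack) so repeated mask evaluations are cheap."""

    def __init__(self, matrix: FeatureMatrix, labels: LabelVector, fc: FitnessConfig):
        self.matrix = matrix
        self.labels = labels
        self.fc = fc
        self.X = matrix.values
        self.y = labels.labels
        self.folds = _stratified_folds(self.y, fc.cv_folds, fc.seed)
        n, d = self.X.shape
        self._stack = None
        if fc.classifier == "knn" and d * n * n <= _STACK_CELL_LIMIT:
            diff = self.X[:, None, :] - self.X[None, :, :]  # (n, n, d)
            self._stack = np.ascontiguousarray(np.moveaxis(diff**2, 2, 0))

    def _subset_sq_distances(self, indices: np.ndarray) -> np.ndarray:
        if self._stack is not None:
            return self._stack[indices].sum(axis=0)
        Xs = self.X[:, indices]
        sq = np.sum(Xs**2, axis=1)
        return sq[:, None] + sq[None, :] - 2.0 * (Xs @ Xs.T)

    def _knn_error(self, indices: np.ndarray) -> float:
        D = self._subset_sq_distances(indices)
        wrong = 0
        for f in range(self.fc.cv_folds):
            test = np.flatnonzero(self.folds == f)
            train = np.flatnonzero(self.folds != f)
            k = min(self.fc.knn_k, train.size)
            d = D[np.ix_(test, train)]
            if k < train.size:
                nn = np.argpartition(d, k - 1, axis=1)[:, :k]
            else:
                nn = np.tile(np.arange(train.size), (test.size, 1))
            votes = self.y[train][nn].sum(axis=1)
            pred = (2 * votes >= k).astype(int)  # ties go to the positive class
            wrong += int(np.sum(pred != self.y[test]))
        return wrong / self.y.size

    def _svm_error(self, indices: np.ndarray) -> float:
        from sklearn.svm import LinearSVC

        wrong = 0
        for f in range(self.fc.cv_folds):
            test = self.folds == f
            train = ~test
            clf = LinearSVC(random_state=self.fc.seed, max_iter=5000)
            clf.fit(self.X[np.ix_(train, indices)], self.y[train])
            pred = clf.predict(self.X[np.ix_(test, indices)])
            wrong += int(np.sum(pred != self.y[test]))
        return wrong / self.y.size

    def cv_error(self, mask: SelectionMask) -> float:
        indices = mask.indices
        if self.fc.classifier == "knn":
            return self._knn_error(indices)
        return self._svm_error(indices)

    def cv_predictions(self, mask: SelectionMask) -> np.ndarray:
        """Out-of-fold predictions for every sample (k-NN only path reused
        for report generation; SVM handled fold-by-fold)."""
        indices = mask.indices
        pred = np.empty(self.y.size, dtype=int)
        if self.fc.classifier == "knn":
            D = self._subset_sq_distances(indices)
            for f in range(self.fc.cv_folds):
                test = np.flatnonzero(self.folds == f)
                train = np.flatnonzero(self.folds != f)
                k = min(self.fc.knn_k, train.size)
                d = D[np.ix_(test, train)]
                if k < train.size:
                    nn = np.argpartition(d, k - 1, axis=1)[:, :k]
                else:
                    nn = np.tile(np.arange(train.size), (test.size, 1))
                votes = self.y[train][nn].sum(axis=1)
                pred[test] = (2 * votes >= k).astype(int)
        else:
            from sklearn.svm import LinearSVC

            for f in range(self.fc.cv_folds):
                test = self.folds == f
                train = ~test
                clf = LinearSVC(random_state=self.fc.seed, max_iter=5000)
                clf.fit(self.X[np.ix_(train, indices)], self.y[train])
                pred[test] = clf.predict(self.X[np.ix_(test, indices)])
        return pred

    def fitness(self, mask: SelectionMask) -> float:
        w = self.fc.error_weight
        size_term = mask.count / self.matrix.n_features
        return w * self.cv_error(mask) + (1.0 - w) * size_term


def subset_fitness(
    mask: SelectionMask,
    matrix: FeatureMatrix,
    labels: LabelVector,
    fc: FitnessConfig,
) -> float:
    """One-shot fitness of a mask (builds a fresh evaluator; use
    :class:`SubsetFitnessEvaluator` directly for repeated queries)."""
    return SubsetFitnessEvaluator(matrix, labels, fc).fitness(mask)


def select_features(
    matrix: FeatureMatrix,
    labels: LabelVector,
    who_config: Optional[WHOConfig] = None,
    fc: Optional[FitnessConfig] = None,
) -> SelectionResult:
    """Run the herd optimizer over [0, 1]^n_features with the masked
    CV-fitness objective and return the best mask found."""
    if who_config is None:
        who_config = WHOConfig()
    if fc is None:
        fc = FitnessConfig(seed=who_config.seed)
    evaluator = SubsetFitnessEvaluator(matrix, labels, fc)
    bounds = BoundsSpec.cube(0.0, 1.0, matrix.n_features)

    def objective(position: np.ndarray) -> float:
        return evaluator.fitness(binarize(position, fc.threshold))

    result = optimize(objective, bounds, who_config)
    mask = binarize(result.best_position, fc.threshold)
    return SelectionResult(
        mask=mask,
        fitness=result.best_fitness,
        trace=list(result.trace),
        config={"who": _who_config_dict(who_config), "fitness": fc.to_dict()},
        evaluations=result.evaluations,
    )


def _who_config_dict(cfg: WHOConfig) -> dict:
    return {
        "population_size": cfg.population_size,
        "iterations": cfg.iterations,
        "milling_steps": cfg.milling_steps,
        "learning_rate": cfg.learning_rate,
        "alpha1": cfg.alpha1,
        "beta1": cfg.beta1,
        "alpha2": cfg.alpha2,
        "beta2": cfg.beta2,
        "crowding_threshold": cfg.crowding_threshold,
        "pressure_lower_bound": cfg.pressure_lower_bound,
        "social_memory_radius": cfg.social_memory_radius,
        "use_social_memory": cfg.use_social_memory,
        "seed": cfg.seed,
    }


def who_evaluation_budget(who_config: WHOConfig) -> int:
    """Approximate number of fitness evaluations one herd run spends:
    population * iterations * (milling probes + up to 3 per-candidate
    moves)."""
    return who_config.population_size * who_config.iterations * (
        who_config.milling_steps + 3
    )


def _random_mask(rng: np.random.Generator, n_features: int) -> SelectionMask:
    sel = (rng.random(n_features) < 0.5).astype(int)
    if sel.sum() == 0:
        sel[int(rng.integers(n_features))] = 1
    return SelectionMask(tuple(sel))


def baseline_search(
    matrix: FeatureMatrix,
    labels: LabelVector,
    method: str,
    budget: int,
    fc: Optional[FitnessConfig] = None,
    start_mask: Optional[SelectionMask] = None,
    search_seed: Optional[int] = None,
) -> SelectionResult:
    """Budget-matched baselines: ``random`` keeps the best of ``budget``
    uniform masks; ``hillclimb`` does best-improvement single-bit flips
    (restarting from a fresh random mask at local optima) until the budget
    is exhausted.

    ``search_seed`` decouples the search randomness from the CV fold seed
    so paired comparisons can share folds while varying the search.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if fc is None:
        fc = FitnessConfig()
    evaluator = SubsetFitnessEvaluator(matrix, labels, fc)
    rng = np.random.default_rng(fc.seed if search_seed is None else search_seed)
    d = matrix.n_features
    trace: List[float] = []
    best_mask: Optional[SelectionMask] = None
    best_fit = np.inf
    used = 0

    def evaluate(mask: SelectionMask) -> float:
        nonlocal used, best_mask, best_fit
        value = evaluator.fitness(mask)
        used += 1
        if value < best_fit:
            best_fit = value
            best_mask = mask
        trace.append(best_fit)
        return value

    if method == "random":
        while used < budget:
            evaluate(_random_mask(rng, d))
    elif method == "hillclimb":
        current = start_mask if start_mask is not None else _random_mask(rng, d)
        current_fit = evaluate(current)
        while used < budget:
            best_flip = None
            best_flip_fit = current_fit
            for j in range(d):
                if used >= budget:
                    break
                sel = list(current.selected)
                sel[j] = 1 - sel[j]
                if sum(sel) == 0:
                    continue
                candidate = SelectionMask(tuple(sel))
                value = evaluate(candidate)
                if value < best_flip_fit:
                    best_flip_fit = value
                    best_flip = candidate
            if best_flip is None:
                if used >= budget:
                    break
                current = _random_mask(rng, d)  # local optimum: restart
                current_fit = evaluate(current)
            else:
                current, current_fit = best_flip, best_flip_fit
    else:
        raise ValueError(f"unknown baseline method {method!r}")

    return SelectionResult(
        mask=best_mask,
        fitness=float(best_fit),
        trace=trace,
        config={"method": method, "budget": budget, "fitness": fc.to_dict()},
        evaluations=used,
    )


def repeated_runs(
    matrix: FeatureMatrix,
    labels: LabelVector,
    who_config: Optional[WHOConfig] = None,
    fc: Optional[FitnessConfig] = None,
    n_runs: int = 35,
) -> Tuple[_metrics.RunStats, List[SelectionResult]]:
    """Independent repeated selection runs with seeds base, base+1, ...

    Both the herd seed and the CV fold seed advance together so each run is
    fully independent yet reproducible.  Fitness values are aggregated into
    RunStats; the per-run results are returned for inspection.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if who_config is None:
        who_config = WHOConfig()
    if fc is None:
        fc = FitnessConfig(seed=who_config.seed)
    results: List[SelectionResult] = []
    for r in range(n_runs):
        cfg_r = replace(who_config, seed=who_config.seed + r)
        fc_r = replace(fc, seed=fc.seed + r)
        results.append(select_features(matrix, labels, cfg_r, fc_r))
    stats = _metrics.run_statistics([res.fitness for res in results])
    return stats, results
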