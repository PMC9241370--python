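"""Three-stage wrapper feature selection.

Stage 1 screens each feature alone with a random forest and keeps features
whose out-of-bag (OOB) misclassification error is at or below a threshold
(default 40%).  Stage 2 runs a stagnation-terminated single-state genetic
search many times: each iteration toggles one uniformly chosen feature in or
out, keeps the toggle only when the cross-validated fitness strictly
improves, and stops after a fixed run of non-improving iterations.  Stage 3
applies backward elimination to the five best stage-2 subsets and returns
the overall best.

Fitness is the mean Matthews correlation coefficient over repeated
stratified 5-fold cross-validation of a random forest.  One seed fixes the
CV partition and the forest RNG for every subset, so any two subsets are
compared on identical resampling noise (common random numbers); evaluations
are cached by subset, making re-visits free and reported values exactly
reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .dataset import LabeledDataset
from .metrics import ConfusionCounts, compute_metrics
from .records import SaasError

logger = logging.getLogger(__name__)

#: forest size used for fitness / screening models; the paper-scale profile
#: raises this to the R randomForest default of 500 trees
DEFAULT_FITNESS_TREES = 30

EMPTY_SUBSET_FITNESS = -1.0

Subset = FrozenSet[str]


class FitnessEvaluator:
    """Cached subset-fitness oracle: mean MCC of a random forest under
    repeated stratified 5-fold cross-validation."""

    def __init__(self, dataset: LabeledDataset, k: int = 5, repeats: int = 2,
                 seed: int = 0, n_trees: int = DEFAULT_FITNESS_TREES) -> None:
        self.dataset = dataset
        self.k = k
        self.repeats = repeats
        self.seed = seed
        self.n_trees = n_trees
        self._X = dataset.features.to_numpy(dtype=float)
        self._y = dataset.labels
        self._col = {name: i for i, name in enumerate(dataset.feature_names)}
        self._cache: Dict[Subset, float] = {}
        cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats,
                                     random_state=seed)
        self._folds = list(cv.split(self._X, self._y))

    @property
    def n_evaluations(self) -> int:
        return len(self._cache)

    def __call__(self, subset: Sequence[str]) -> float:
        key = frozenset(subset)
        if key in self._cache:
            return self._cache[key]
        if not key:
            self._cache[key] = EMPTY_SUBSET_FITNESS
            return EMPTY_SUBSET_FITNESS
        cols = sorted(self._col[name] for name in key)
        X = self._X[:, cols]
        mccs = []
        for train, test in self._folds:
            rf = RandomForestClassifier(n_estimators=self.n_trees,
                                        random_state=self.seed, n_jobs=1)
            rf.fit(X[train], self._y[train])
            pred = rf.predict(X[test])
            counts = ConfusionCounts.from_predictions(self._y[test], pred)
            mccs.append(compute_metrics(counts)["MCC"])
        fitness = float(np.mean(mccs))
        self._cache[key] = fitness
        return fitness


@dataclass
class GaRun:
    subset: Subset
    fitness: float
    seed: int
    n_iterations: int


@dataclass
class SelectionResult:
    """Surviving feature sets per pipeline stage, with fitness traces."""

    stage1_retained: List[str]
    oob_errors: Dict[str, float]
    ga_runs: List[GaRun]
    top5: List[GaRun]
    final: List[str]
    final_fitness: float
    config: Dict[str, object] = field(default_factory=dict)


def oob_filter(dataset: LabeledDataset, threshold: float = 0.40,
               seed: int = 0, n_trees: int = 100,
               min_samples_leaf: Optional[int] = None,
               ) -> Tuple[List[str], Dict[str, float]]:
    """Per-feature single-feature forest screen.

    Returns the retained feature list (OOB error <= threshold) and every
    feature's OOB error.  An empty retained set is allowed (warned).

    A forest grown to unit leaves on a single continuous feature
    degenerates to bagged nearest-neighbour voting, whose OOB error
    overstates the feature's information; the screen therefore regularizes
    the leaves (default: 1% of the sample size) so the error tracks the
    feature's one-dimensional Bayes error.
    """
    if not (0.0 < threshold <= 1.0):
        raise SaasError("OOB threshold must be in (0, 1]")
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels
    if min_samples_leaf is None:
        min_samples_leaf = max(1, round(0.01 * len(y)))
    errors: Dict[str, float] = {}
    for i, name in enumerate(dataset.feature_names):
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                    min_samples_leaf=min_samples_leaf,
                                    random_state=seed, n_jobs=1)
        rf.fit(X[:, [i]], y)
        errors[name] = 1.0 - float(rf.oob_score_)
    retained = [n for n in dataset.feature_names if errors[n] <= threshold]
    if not retained:
        logger.warning("OOB filter retained no features at threshold %.2f",
                       threshold)
    return retained, errors


def ga_search(dataset: LabeledDataset, pool: Sequence[str],
              evaluator: FitnessEvaluator, stagnation: int = 500,
              seed: int = 0) -> GaRun:
    """Single-state stochastic toggle search over subsets of ``pool``.

    Starts from a random subset (inclusion probability 0.5); each iteration
    toggles one uniformly chosen feature and keeps the toggle only when
    fitness strictly improves; terminates after ``stagnation`` consecutive
    non-improving iterations.
    """
    pool = sorted(pool)
    if not pool:
        raise SaasError("GA feature pool is empty")
    if stagnation < 1:
        raise SaasError("stagnation must be >= 1")
    rng = np.random.default_rng(seed)
    current = frozenset(f for f in pool if rng.random() < 0.5)
    current_fit = evaluator(current)
    stagnant = 0
    iterations = 0
    while stagnant < stagnation:
        iterations += 1
        feat = pool[rng.integers(len(pool))]
        candidate = current - {feat} if feat in current else current | {feat}
        cand_fit = evaluator(candidate)
        if cand_fit > current_fit:
            current, current_fit = candidate, cand_fit
            stagnant = 0
        else:
            stagnant += 1
    return GaRun(subset=current, fitness=current_fit, seed=seed,
                 n_iterations=iterations)


def _run_sort_key(run: GaRun) -> Tuple[float, int, Tuple[str, ...]]:
    return (-run.fitness, len(run.subset), tuple(sorted(run.subset)))


def run_ga_restarts(dataset: LabeledDataset, pool: Sequence[str],
                    evaluator: FitnessEvaluator, n_restarts: int = 500,
                    stagnation: int = 500, seed: int = 0,
                    ) -> Tuple[List[GaRun], List[GaRun]]:
    """Repeat the GA with distinct seeds; return (all runs, best five).

    Ranking is by fitness, ties broken by smaller subset then lexical order.
    """
    if n_restarts < 5:
        raise SaasError("need at least 5 restarts to pick a top five")
    runs = [ga_search(dataset, pool, evaluator, stagnation=stagnation,
                      seed=seed + 1000 * (j + 1))
            for j in range(n_restarts)]
    return runs, sorted(runs, key=_run_sort_key)[:5]


def backward_elimination(dataset: LabeledDataset, top5: Sequence[GaRun],
                         evaluator: FitnessEvaluator,
                         ) -> Tuple[List[str], float]:
    """Backward elimination on each top subset; best resulting subset wins.

    From each subset, repeatedly remove the single feature whose removal
    yields the highest fitness, accepting only strict improvements; a
    singleton is returned unchanged (the empty subset is never evaluated).
    """
    if not top5:
        raise SaasError("no subsets to refine")
    results: List[GaRun] = []
    for run in top5:
        current, current_fit = run.subset, run.fitness
        while len(current) > 1:
            best_removal: Optional[Subset] = None
            best_fit = current_fit
            for feat in sorted(current):
                cand = current - {feat}
                fit = evaluator(cand)
                if fit > best_fit:
                    best_fit, best_removal = fit, cand
            if best_removal is None:
                break
            current, current_fit = best_removal, best_fit
        results.append(GaRun(subset=current, fitness=current_fit,
                             seed=run.seed, n_iterations=run.n_iterations))
    best = sorted(results, key=_run_sort_key)[0]
    return sorted(best.subset), best.fitness


def select_features(dataset: LabeledDataset, oob_threshold: float = 0.40,
                    n_restarts: int = 500, stagnation: int = 500,
                    cv_repeats: int = 2, seed: int = 0,
                    n_trees: int = DEFAULT_FITNESS_TREES,
                    ) -> SelectionResult:
    """The full three-stage pipeline on a labelled feature table."""
    retained, errors = oob_filter(dataset, threshold=oob_threshold, seed=seed)
    if not retained:
        return SelectionResult(stage1_retained=[], oob_errors=errors,
                               ga_runs=[], top5=[], final=[],
                               final_fitness=EMPTY_SUBSET_FITNESS)
    evaluator = FitnessEvaluator(dataset, repeats=cv_repeats, seed=seed,
                                 n_trees=n_trees)
    runs, top5 = run_ga_restarts(dataset, retained, evaluator,
                                 n_restarts=n_restarts,
                                 stagnation=stagnation, seed=seed)
    final, final_fitness = backward_elimination(dataset, top5, evaluator)
    return SelectionResult(
        stage1_retained=retained, oob_errors=errors, ga_runs=runs,
        top5=top5, final=final, final_fitness=final_fitness,
        config={"oob_threshold": oob_threshold, "n_restarts": n_restarts,
                "stagnation": stagnation, "cv_repeats": cv_repeats,
                "seed": seed, "n_trees": n_trees,
                "n_fitness_evaluations": evaluator.n_evaluations})
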