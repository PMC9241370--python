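"""Model building and evaluation for substitution-effect prediction.

Four base learners — random forest, gradient-boosted trees (XGBoost), SVM
and a single-hidden-layer feed-forward network — are tuned by repeated
stratified 5-fold cross-validation on mean MCC, refit on the full training
set, and combined into all 11 stacking ensembles (every subset of two or
more base learners) with a logistic-regression meta-learner fitted on
out-of-fold base probabilities.  Prediction scores are probabilities in
[0, 1]; a record is called functional when its score is >= 0.5.

The public surface is a statsmodels-style pair:
:class:`SubstitutionEffectModel` wraps the training data and learner
specifications; its :meth:`~SubstitutionEffectModel.fit` returns a
:class:`SubstitutionEffectResults` carrying the fitted bundle, per-model
cross-validation fitness, evaluation tables and a text ``summary()``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .dataset import LabeledDataset, StandardizationParams, apply_standardizer
from .metrics import METRIC_ORDER, ConfusionCounts, compute_metrics, full_report
from .records import FUNCTIONAL, NEUTRAL, SaasError

ALGORITHMS = ("random_forest", "gradient_boosted_trees", "svm", "ffnn_1hidden")

DEFAULT_THRESHOLD = 0.5

#: compact default grids; the paper-scale profile widens every axis
DEFAULT_GRIDS: Dict[str, List[Dict[str, object]]] = {
    "random_forest": [
        {"ntree": 100, "mtry": "sqrt", "nodesize": 1},
        {"ntree": 100, "mtry": "sqrt", "nodesize": 5},
    ],
    "gradient_boosted_trees": [
        {"nrounds": 100, "max_depth": 3, "eta": 0.3},
        {"nrounds": 100, "max_depth": 6, "eta": 0.3},
    ],
    "svm": [
        {"kernel": "rbf", "gamma": "scale", "cost": 1.0},
        {"kernel": "rbf", "gamma": "scale", "cost": 10.0},
    ],
    "ffnn_1hidden": [
        {"activation": "logistic", "hidden": 16, "learning_rate": 1e-3},
        {"activation": "relu", "hidden": 16, "learning_rate": 1e-3},
    ],
}

PAPER_GRIDS: Dict[str, List[Dict[str, object]]] = {
    "random_forest": [
        {"ntree": nt, "mtry": mt, "nodesize": ns}
        for nt in (500, 1000) for mt in ("sqrt", 0.3) for ns in (1, 5, 10)
    ],
    "gradient_boosted_trees": [
        {"nrounds": nr, "max_depth": md, "min_child_weight": mc,
         "gamma": g, "subsample": ss, "colsample_bytree": cs,
         "alpha": a, "lambda": l, "eta": e}
        for nr in (100, 500) for md in (3, 6, 9) for mc in (1,)
        for g in (0.0,) for ss in (0.8, 1.0) for cs in (0.8, 1.0)
        for a in (0.0,) for l in (1.0,) for e in (0.05, 0.3)
    ],
    "svm": [
        {"kernel": k, "gamma": g, "cost": c}
        for k in ("rbf", "linear") for g in ("scale", 0.1) for c in (0.1, 1.0, 10.0)
    ],
    "ffnn_1hidden": [
        {"activation": a, "hidden": h, "learning_rate": lr}
        for a in ("logistic", "relu") for h in (8, 16, 64)
        for lr in (1e-3, 1e-2)
    ],
}


@dataclass(frozen=True)
class LearnerSpec:
    """One base-learner family plus its hyperparameter grid."""

    algorithm: str
    grid: Tuple[Mapping[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise SaasError(f"unknown algorithm {self.algorithm!r}")
        if not self.grid:
            object.__setattr__(
                self, "grid", tuple(DEFAULT_GRIDS[self.algorithm]))


def default_specs() -> List[LearnerSpec]:
    return [LearnerSpec(a) for a in ALGORITHMS]


def build_estimator(algorithm: str, params: Mapping[str, object], seed: int = 0):
    """Instantiate a scikit-learn / xgboost estimator from a named
    hyperparameter point (field-style names: ntree, mtry, cost, ...)."""
    p = dict(params)
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(p.get("ntree", 100)),
            max_features=p.get("mtry", "sqrt"),
            min_samples_leaf=int(p.get("nodesize", 1)),
            random_state=seed, n_jobs=1)
    if algorithm == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=int(p.get("nrounds", 100)),
            max_depth=int(p.get("max_depth", 6)),
            min_child_weight=p.get("min_child_weight", 1),
            gamma=p.get("gamma", 0.0),
            subsample=p.get("subsample", 1.0),
            colsample_bytree=p.get("colsample_bytree", 1.0),
            reg_alpha=p.get("alpha", 0.0),
            reg_lambda=p.get("lambda", 1.0),
            learning_rate=p.get("eta", 0.3),
            random_state=seed, n_jobs=1, eval_metric="logloss")
    if algorithm == "svm":
        return SVC(kernel=str(p.get("kernel", "rbf")),
                   gamma=p.get("gamma", "scale"),
                   C=float(p.get("cost", 1.0)),
                   probability=True, random_state=seed)
    if algorithm == "ffnn_1hidden":
        return MLPClassifier(
            hidden_layer_sizes=(int(p.get("hidden", 16)),),
            activation=str(p.get("activation", "relu")),
            learning_rate_init=float(p.get("learning_rate", 1e-3)),
            max_iter=500, random_state=seed)
    raise SaasError(f"unknown algorithm {algorithm!r}")


@dataclass(frozen=True)
class CvConfig:
    k: int = 5
    repeats: int = 2  # paper-scale profile: 10
    seed: int = 0


def _cv_mean_mcc(estimator_factory, X: np.ndarray, y: np.ndarray,
                 cv_config: CvConfig) -> float:
    cv = RepeatedStratifiedKFold(n_splits=cv_config.k,
                                 n_repeats=cv_config.repeats,
                                 random_state=cv_config.seed)
    mccs = []
    for train, test in cv.split(X, y):
        est = estimator_factory()
        est.fit(X[train], y[train])
        pred = est.predict(X[test])
        mccs.append(compute_metrics(
            ConfusionCounts.from_predictions(y[test], pred))["MCC"])
    return float(np.mean(mccs))


def tune_hyperparameters(spec: LearnerSpec, dataset: LabeledDataset,
                         cv_config: CvConfig = CvConfig(), seed: int = 0,
                         ) -> Tuple[Dict[str, object], float]:
    """Grid point maximizing mean MCC across all fold-models; ties resolved
    to the first point in deterministic grid order."""
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < cv_config.k:
        raise SaasError(
            f"need at least k={cv_config.k} records per class, have {counts}")
    best: Optional[Tuple[Dict[str, object], float]] = None
    for point in spec.grid:
        score = _cv_mean_mcc(
            lambda: build_estimator(spec.algorithm, point, seed=seed),
            X, y, cv_config)
        if best is None or score > best[1]:
            best = (dict(point), score)
    assert best is not None
    return best


def stacking_subsets(algorithms: Sequence[str]) -> List[Tuple[str, ...]]:
    """All combinations of two or more base learners (11 for four)."""
    out: List[Tuple[str, ...]] = []
    for r in range(2, len(algorithms) + 1):
        out.extend(itertools.combinations(algorithms, r))
    return out


def _ensemble_name(subset: Sequence[str]) -> str:
    return "stack[" + "+".join(subset) + "]"


@dataclass
class ModelBundle:
    """Everything needed to score new substitutions.

    Fitted base learners, logistic-regression stacking meta-models keyed by
    ensemble name, optional standardization parameters, the selected feature
    names and the decision threshold.
    """

    feature_names: List[str]
    base_models: Dict[str, object]
    tuned_params: Dict[str, Dict[str, object]]
    meta_models: Dict[str, object] = field(default_factory=dict)
    standardizer: Optional[StandardizationParams] = None
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    @property
    def model_names(self) -> List[str]:
        return list(self.base_models) + list(self.meta_models)

    def _base_scores(self, X: np.ndarray) -> Dict[str, np.ndarray]:
        return {name: model.predict_proba(X)[:, 1]
                for name, model in self.base_models.items()}

    def score(self, features: pd.DataFrame,
              model: Optional[str] = None) -> np.ndarray:
        """Probability-of-functional scores from one model (default: the
        all-learner stack when present, else the single base learner)."""
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise SaasError(f"feature vector lacks selected features: {missing}")
        X = features[self.feature_names].to_numpy(dtype=float)
        if model is None:
            model = (max(self.meta_models, key=lambda n: n.count("+"))
                     if self.meta_models else next(iter(self.base_models)))
        if model in self.base_models:
            return self.base_models[model].predict_proba(X)[:, 1]
        if model in self.meta_models:
            members = model[len("stack["):-1].split("+")
            base = np.column_stack([
                self.base_models[m].predict_proba(X)[:, 1] for m in members])
            return self.meta_models[model].predict_proba(base)[:, 1]
        raise SaasError(f"unknown model {model!r}; have {self.model_names}")

    def predict(self, features: pd.DataFrame, model: Optional[str] = None,
                ) -> Tuple[np.ndarray, List[str]]:
        """Scores plus class calls (functional iff score >= threshold)."""
        scores = self.score(features, model)
        classes = [FUNCTIONAL if s >= self.threshold else NEUTRAL
                   for s in scores]
        return scores, classes

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "feature_names": self.feature_names,
            "tuned_params": self.tuned_params,
            "threshold": self.threshold,
            "seed": self.seed,
            "base_models": list(self.base_models),
            "meta_models": list(self.meta_models),
        }
        if self.standardizer is not None:
            meta["standardizer"] = {
                "means": self.standardizer.means.to_dict(),
                "sds": self.standardizer.sds.to_dict(),
                "medians": self.standardizer.medians.to_dict(),
            }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))
        joblib.dump({"base": self.base_models, "meta": self.meta_models},
                    d / "models.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        d = Path(directory)
        meta = json.loads((d / "bundle.json").read_text())
        blobs = joblib.load(d / "models.joblib")
        std = None
        if "standardizer" in meta:
            s = meta["standardizer"]
            std = StandardizationParams(means=pd.Series(s["means"]),
                                        sds=pd.Series(s["sds"]),
                                        medians=pd.Series(s["medians"]))
        return cls(feature_names=meta["feature_names"],
                   base_models=blobs["base"], tuned_params=meta["tuned_params"],
                   meta_models=blobs["meta"], standardizer=std,
                   threshold=meta["threshold"], seed=meta["seed"])


class SubstitutionEffectModel:
    """Functional-vs-neutral substitution classifier (training view).

    Parameters
    ----------
    dataset : LabeledDataset
        Standardized training (benchmark) features and binary labels.
    specs : sequence of LearnerSpec, optional
        Base learners; defaults to all four families.
    threshold : float
        Decision threshold on the probability score (default 0.5).
    """

    def __init__(self, dataset: LabeledDataset,
                 specs: Optional[Sequence[LearnerSpec]] = None,
                 threshold: float = DEFAULT_THRESHOLD) -> None:
        self.dataset = dataset
        self.specs = list(specs) if specs is not None else default_specs()
        if len(self.specs) > 4:
            raise SaasError("at most four base learners are supported")
        self.threshold = threshold

    @classmethod
    def from_dataframe(cls, features: pd.DataFrame,
                       labels: Sequence[int], **kwargs
                       ) -> "SubstitutionEffectModel":
        return cls(LabeledDataset(features=features,
                                  labels=np.asarray(labels)), **kwargs)

    def fit(self, cv_config: CvConfig = CvConfig(), seed: int = 0,
            stacking: bool = True,
            standardizer: Optional[StandardizationParams] = None,
            ) -> "SubstitutionEffectResults":
        """Tune, refit and (optionally) stack every configured learner."""
        X = self.dataset.features.to_numpy(dtype=float)
        y = self.dataset.labels
        tuned: Dict[str, Dict[str, object]] = {}
        cv_fitness: Dict[str, float] = {}
        base_models: Dict[str, object] = {}
        for spec in self.specs:
            params, fitness = tune_hyperparameters(spec, self.dataset,
                                                   cv_config, seed=seed)
            tuned[spec.algorithm] = params
            cv_fitness[spec.algorithm] = fitness
            est = build_estimator(spec.algorithm, params, seed=seed)
            est.fit(X, y)
            base_models[spec.algorithm] = est

        meta_models: Dict[str, object] = {}
        if stacking and len(base_models) >= 2:
            oof = self._out_of_fold_scores(tuned, cv_config, seed)
            for subset in stacking_subsets(list(base_models)):
                Z = np.column_stack([oof[a] for a in subset])
                # unregularized meta-learner (plain logistic regression)
                lr = LogisticRegression(C=np.inf, max_iter=1000)
                lr.fit(Z, y)
                meta_models[_ensemble_name(subset)] = lr

        bundle = ModelBundle(feature_names=self.dataset.feature_names,
                             base_models=base_models, tuned_params=tuned,
                             meta_models=meta_models,
                             standardizer=standardizer,
                             threshold=self.threshold, seed=seed)
        return SubstitutionEffectResults(model=self, bundle=bundle,
                                         cv_fitness=cv_fitness)

    def _out_of_fold_scores(self, tuned: Mapping[str, Mapping[str, object]],
                            cv_config: CvConfig, seed: int,
                            ) -> Dict[str, np.ndarray]:
        """Leakage-free base-learner probabilities for meta-learning."""
        X = self.dataset.features.to_numpy(dtype=float)
        y = self.dataset.labels
        cv = StratifiedKFold(n_splits=cv_config.k, shuffle=True,
                             random_state=seed)
        oof = {a: np.zeros(len(y)) for a in tuned}
        for train, test in cv.split(X, y):
            for algorithm, params in tuned.items():
                est = build_estimator(algorithm, params, seed=seed)
                est.fit(X[train], y[train])
                oof[algorithm][test] = est.predict_proba(X[test])[:, 1]
        return oof


@dataclass
class SubstitutionEffectResults:
    """Fitted substitution-effect classifier suite.

    Carries the serializable :class:`ModelBundle`, the per-learner tuning
    fitness (mean CV MCC), and evaluation helpers.
    """

    model: SubstitutionEffectModel
    bundle: ModelBundle
    cv_fitness: Dict[str, float]

    def predict(self, features: pd.DataFrame, model: Optional[str] = None):
        return self.bundle.predict(features, model)

    def evaluate(self, dataset: LabeledDataset,
                 models: Optional[Sequence[str]] = None) -> pd.DataFrame:
        """Six-metric table (MCC, ACC, SEN, SPE, PRE, AUC), one row per
        model, mirroring the standard report layout."""
        names = list(models) if models else self.bundle.model_names
        rows = {}
        for name in names:
            scores = self.bundle.score(dataset.features, name)
            rows[name] = full_report(dataset.labels, scores,
                                     self.bundle.threshold)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=list(METRIC_ORDER))

    def summary(self, eval_dataset: Optional[LabeledDataset] = None) -> str:
        lines = ["Substitution-effect classifier suite",
                 "=" * 44,
                 f"training records : {len(self.model.dataset)}",
                 f"features         : {len(self.bundle.feature_names)}",
                 f"threshold        : {self.bundle.threshold}",
                 "",
                 "Base learners (mean CV MCC during tuning):"]
        for algorithm, fitness in self.cv_fitness.items():
            params = json.dumps(self.bundle.tuned_params[algorithm])
            lines.append(f"  {algorithm:<24s} {fitness:6.3f}  {params}")
        lines.append(f"Stacking ensembles: {len(self.bundle.meta_models)}")
        if eval_dataset is not None:
            lines.append("")
            lines.append("Evaluation (rows = models):")
            lines.append(self.evaluate(eval_dataset).round(3).to_string())
        return "\n".join(lines)
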