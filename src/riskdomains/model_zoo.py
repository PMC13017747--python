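"""The classifier suite: 12 base learners, the age+gender benchmark, and a
Super Learner stacking ensemble.

All models consume a :class:`~riskdomains.data_model.CohortTable` and return
death probabilities. Non-tree models receive median imputation and
standardization fitted on the training rows only; the gradient-boosting
models (LightGBM, XGBoost) consume missing values natively and skip both.
Models without native probabilities (SVM, SGD with hinge loss) are
sigmoid-calibrated (Platt scaling) on the training data.

Every stochastic component is driven by the integer seed in the
:class:`ModelSpec`; a fixed (spec, data) pair reproduces identical
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

import lightgbm as lgb
import xgboost as xgb

from .data_model import CohortTable, SplitSpec, split_cohort
from .metrics import MetricReport, aggregate_report, compute_all_metrics

__all__ = [
    "BASE_MODEL_NAMES",
    "MODEL_NAMES",
    "ModelSpec",
    "FittedModel",
    "default_base_specs",
    "fit_model",
    "predict_proba",
    "fit_benchmark",
    "fit_super_learner",
    "evaluate_suite",
]

BASE_MODEL_NAMES = (
    "sgd",
    "knn",
    "logistic",
    "decision_tree",
    "svm",
    "gaussian_nb",
    "adaboost",
    "bagging",
    "random_forest",
    "extra_trees",
    "lightgbm",
    "xgboost",
)
MODEL_NAMES = BASE_MODEL_NAMES + ("benchmark", "super_learner")

#: models that consume NaN natively and skip imputation/standardization
_NATIVE_MISSING = {"lightgbm", "xgboost"}


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier with hyperparameter overrides and a seed."""

    name: str
    hyperparams: Mapping = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        object.__setattr__(self, "hyperparams", dict(self.hyperparams))


@dataclass
class FittedModel:
    """A fitted estimator plus everything needed to predict on new cohorts."""

    spec: ModelSpec
    feature_names: list[str]
    handle: object  # fitted sklearn pipeline/estimator or _SuperLearner
    train_prevalence: float

    def predict(self, table: CohortTable) -> np.ndarray:
        return predict_proba(self, table)


def default_base_specs(seed: int = 0) -> list[ModelSpec]:
    """One spec per base learner, library defaults (k=25 for KNN)."""
    return [ModelSpec(name=n, seed=seed) for n in BASE_MODEL_NAMES]


def _build_estimator(name: str, hp: Mapping, seed: int):
    hp = dict(hp)
    hp.pop("max_train_n", None)
    if name == "sgd":
        base = SGDClassifier(random_state=seed, **hp)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 25), **hp)
    if name == "logistic":
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if name == "svm":
        base = SVC(random_state=seed, **hp)
        return CalibratedClassifierCV(base, method="sigmoid", cv=3)
    if name == "gaussian_nb":
        return GaussianNB(**hp)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if name == "bagging":
        return BaggingClassifier(random_state=seed, **hp)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)
    if name == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if name == "lightgbm":
        return lgb.LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1, **hp)
    if name == "xgboost":
        return xgb.XGBClassifier(random_state=seed, eval_metric="logloss", n_jobs=1, **hp)
    raise ValueError(f"unknown model {name!r}")


def _design(table: CohortTable, feature_names: Sequence[str]) -> np.ndarray:
    missing = [c for c in feature_names if c not in table.features.columns]
    if missing:
        raise KeyError(f"cohort lacks feature columns {missing}")
    return table.features[list(feature_names)].to_numpy(dtype=float)


def fit_model(
    spec: ModelSpec,
    train: CohortTable,
    feature_subset: Sequence[str] | None = None,
) -> FittedModel:
    """Fit one classifier on the training cohort.

    ``feature_subset`` restricts the design matrix (used by the coalition
    analysis); default is all feature columns. Imputation/scaling statistics
    are fitted on the training rows only.
    """
    if spec.name == "benchmark":
        return fit_benchmark(train, seed=spec.seed)
    if spec.name == "super_learner":
        hp = dict(spec.hyperparams)
        base_specs = hp.pop("base_specs", None) or default_base_specs(spec.seed)
        return fit_super_learner(
            base_specs,
            train,
            k_folds=hp.pop("k_folds", 5),
            seed=spec.seed,
            feature_subset=feature_subset,
        )
    features = list(feature_subset) if feature_subset is not None else train.feature_names
    if not features:
        raise ValueError("feature_subset must be non-empty")
    y = train.outcome.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort has a single outcome class")
    work = train
    if spec.name == "svm":
        # cost control: cap the SVM training subsample (stratified, seeded)
        cap = int(spec.hyperparams.get("max_train_n", 10000))
        if train.n > cap:
            rng = np.random.default_rng(spec.seed)
            pos = np.flatnonzero(y == 1)
            neg = np.flatnonzero(y == 0)
            k_pos = max(1, int(round(cap * len(pos) / train.n)))
            take = np.concatenate(
                [
                    rng.choice(pos, size=k_pos, replace=False),
                    rng.choice(neg, size=cap - k_pos, replace=False),
                ]
            )
            work = train.take(np.sort(take))
            y = work.outcome.to_numpy()
    X = _design(work, features)
    est = _build_estimator(spec.name, spec.hyperparams, spec.seed)
    if spec.name in _NATIVE_MISSING:
        pipeline = est
    else:
        pipeline = Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("scale", StandardScaler()),
                ("clf", est),
            ]
        )
    pipeline.fit(X, y)
    return FittedModel(
        spec=spec,
        feature_names=features,
        handle=pipeline,
        train_prevalence=float(work.outcome.mean()),
    )


def predict_proba(model: FittedModel, table: CohortTable) -> np.ndarray:
    """Death probability per row; columns aligned by name."""
    X = _design(table, model.feature_names)
    if isinstance(model.handle, _SuperLearner):
        return model.handle.predict_proba(table)
    with warnings.catch_warnings():
        # fitting on a plain array, predicting on a plain array: the sklearn
        # feature-name consistency warning is spurious here
        warnings.filterwarnings("ignore", message="X does not have valid feature names")
        proba = model.handle.predict_proba(X)
    return np.clip(proba[:, 1], 0.0, 1.0)


def fit_benchmark(train: CohortTable, seed: int = 0) -> FittedModel:
    """The demographic benchmark: logistic regression on age and gender only."""
    for col, kind in ((train.age_col, "age"), (train.gender_col, "gender")):
        if col not in train.features.columns:
            raise KeyError(f"benchmark requires the {kind} column {col!r}")
    fitted = fit_model(
        ModelSpec(name="logistic", seed=seed),
        train,
        feature_subset=[train.age_col, train.gender_col],
    )
    return FittedModel(
        spec=ModelSpec(name="benchmark", seed=seed),
        feature_names=fitted.feature_names,
        handle=fitted.handle,
        train_prevalence=fitted.train_prevalence,
    )


# ---------------------------------------------------------------------------
# Super Learner


@dataclass
class _SuperLearner:
    bases: list[FittedModel]
    weights: np.ndarray

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        Z = np.column_stack([predict_proba(m, table) for m in self.bases])
        return Z @ self.weights


def _logloss_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative weights summing to 1 minimizing log-loss of Z @ w."""
    m = Z.shape[1]
    if m == 1:
        return np.ones(1)
    yf = y.astype(float)

    def nll(w: np.ndarray) -> float:
        p = np.clip(Z @ w, 1e-12, 1.0 - 1e-12)
        return -float(np.mean(yf * np.log(p) + (1.0 - yf) * np.log(1.0 - p)))

    res = minimize(
        nll,
        x0=np.full(m, 1.0 / m),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * m,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def fit_super_learner(
    base_specs: Sequence[ModelSpec],
    train: CohortTable,
    k_folds: int = 5,
    seed: int = 0,
    feature_subset: Sequence[str] | None = None,
) -> FittedModel:
    """Classical stacking: out-of-fold base predictions feed a convex,
    log-loss-minimizing meta-combination; bases are refit on the full
    training set for deployment."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if not base_specs:
        raise ValueError("need at least one base spec")
    y = train.outcome.to_numpy()
    if np.bincount(y, minlength=2).min() < k_folds:
        raise ValueError("too few minority-class rows to stratify the folds")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    Z = np.zeros((train.n, len(base_specs)))
    for tr_idx, val_idx in skf.split(np.zeros(train.n), y):
        sub = train.take(tr_idx)
        val = train.take(val_idx)
        for j, bs in enumerate(base_specs):
            fitted = fit_model(bs, sub, feature_subset)
            Z[val_idx, j] = predict_proba(fitted, val)
    weights = _logloss_weights(Z, y)
    bases = [fit_model(bs, train, feature_subset) for bs in base_specs]
    features = list(feature_subset) if feature_subset is not None else train.feature_names
    return FittedModel(
        spec=ModelSpec(name="super_learner", hyperparams={"k_folds": k_folds}, seed=seed),
        feature_names=features,
        handle=_SuperLearner(bases=bases, weights=weights),
        train_prevalence=float(train.outcome.mean()),
    )


# ---------------------------------------------------------------------------
# Seed-replicated evaluation


def evaluate_suite(
    specs: Sequence[ModelSpec],
    cohort: CohortTable,
    split_spec: SplitSpec,
    seeds: Sequence[int],
    include_benchmark: bool = True,
) -> MetricReport:
    """For each seed: split 7:3, fit every model, score all five metrics on
    the test rows; aggregate to mean +- SE per (model, metric).

    IMV is anchored at the prevalence-constant predictor on the test set;
    the test prevalence itself is carried as the IP row.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    all_specs = list(specs)
    if include_benchmark and not any(s.name == "benchmark" for s in all_specs):
        all_specs.append(ModelSpec(name="benchmark"))
    per_seed: dict[tuple[str, str], list[float]] = {}
    ip: list[float] = []
    for seed in seeds:
        train, test = split_cohort(cohort, replace(split_spec, seed=seed))
        y_test = test.outcome.to_numpy()
        ip.append(float(y_test.mean()))
        for spec in all_specs:
            fitted = fit_model(replace(spec, seed=seed), train)
            p = predict_proba(fitted, test)
            for metric, value in compute_all_metrics(y_test, p).items():
                per_seed.setdefault((spec.name, metric), []).append(value)
    return aggregate_report(per_seed, in_sample_prevalence=ip)
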