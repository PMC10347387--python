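"""Factorial model building: data partition, dataset variants, grid search.

The benchmark crosses four imputation methods, four variable-screening
methods, an optional same-day-FBG inclusion flag, and six learning
algorithms on a shared stratified 8:2 split.  Sixteen training datasets per
FBG flag (imputer x selector, numbered in alphabetical order of both
factors) feed every algorithm, giving 96 models per flag and 192 overall
when both flags run.

Leakage is prevented by construction: imputers are fit on the training
partition only and applied frozen to the test partition, selection sees
only the imputed training data, and hyperparameters are chosen by
stratified cross-validated AUC inside the training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from xgboost import XGBClassifier

from .cohort import CohortTable
from .evaluation import CostModel, evaluate_scores
from .feature_selection import METHODS as SELECTORS
from .feature_selection import select
from .imputation import METHODS as IMPUTERS
from .imputation import get_imputer

__all__ = [
    "SplitIndices",
    "DatasetVariant",
    "ModelSpec",
    "TrainedModel",
    "ModelGridRecord",
    "ExperimentConfig",
    "partition_data",
    "enumerate_datasets",
    "train_model",
    "run_factorial",
    "default_grids",
    "fast_grids",
]

ALGORITHMS = ("CB", "LGBM", "LR", "MLP", "RF", "XGB")


@dataclass(frozen=True)
class SplitIndices:
    train: tuple[int, ...]
    test: tuple[int, ...]
    ratio: float
    seed: int | None


@dataclass
class DatasetVariant:
    """One imputer x selector (x FBG flag) training dataset plus its test set."""

    number: int
    imputer: str
    selector: str
    include_fbg: bool
    variable_count: int
    train_count: int
    selected: tuple[str, ...]
    X_train: pd.DataFrame
    y_train: np.ndarray
    X_test: pd.DataFrame
    y_test: np.ndarray
    kinds: dict[str, str]
    error: str | None = None


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")


@dataclass
class TrainedModel:
    spec: ModelSpec
    best_params: dict
    estimator: object
    dataset_number: int
    seed: int | None
    cv_auc: float


@dataclass
class ModelGridRecord:
    """One row of the factorial: pipeline factors plus test-set metrics."""

    record_id: int
    dataset_number: int
    imputer: str
    selector: str
    algorithm: str
    include_fbg: bool
    n_samples: int
    n_variables: int
    metrics: dict[str, float] | None
    best_params: dict | None
    seed: int | None
    error: str | None = None


def partition_data(
    table: CohortTable, ratio: float = 0.8, seed: int | None = 0
) -> SplitIndices:
    """Stratified random split; |train| = floor(ratio * n) exactly and the
    training prevalence matches the cohort's within one patient."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = table.n
    if n < 2:
        raise ValueError("need at least 2 rows to partition")
    labels = table.labels
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(ratio * n))

    class_idx = [np.flatnonzero(labels == c) for c in (0, 1)]
    quotas = [len(idx) * ratio for idx in class_idx]
    floors = [int(np.floor(q)) for q in quotas]
    remainder = n_train - sum(floors)
    # distribute leftover slots by largest fractional part (ties: class 0)
    order = np.argsort([-(q - f) for q, f in zip(quotas, floors)], kind="stable")
    for c in order[:remainder]:
        floors[c] += 1
    train: list[int] = []
    for idx, take in zip(class_idx, floors):
        perm = rng.permutation(idx)
        train.extend(perm[:take].tolist())
    train_set = set(train)
    test = [i for i in range(n) if i not in train_set]
    return SplitIndices(
        train=tuple(sorted(train)), test=tuple(test), ratio=ratio, seed=seed
    )


def _drop_fbg(table: CohortTable) -> CohortTable:
    out = table.copy()
    if "X55" in out.frame.columns:
        out.frame = out.frame.drop(columns=["X55"])
        out.kinds.pop("X55", None)
    return out


def _subset(table: CohortTable, rows) -> CohortTable:
    return CohortTable(
        table.frame.iloc[list(rows)].copy(), dict(table.kinds), table.outcome
    )


def enumerate_datasets(
    table: CohortTable,
    split: SplitIndices,
    imputers=IMPUTERS,
    selectors=SELECTORS,
    include_fbg_flags=(True,),
    seed: int | None = 0,
    impute_params: dict | None = None,
    select_params: dict | None = None,
) -> list[DatasetVariant]:
    """Materialize every imputer x selector (x FBG flag) dataset variant.

    Stage failures are recorded on the variant (``error``) and the grid
    continues.  Numbering restarts at 1 within each FBG flag, following
    alphabetical imputer-then-selector order.
    """
    impute_params = impute_params or {}
    select_params = select_params or {}
    variants: list[DatasetVariant] = []
    for flag in include_fbg_flags:
        base = table if flag else _drop_fbg(table)
        train_tab = _subset(base, split.train)
        test_tab = _subset(base, split.test)
        number = 0
        for imp in sorted(imputers):
            try:
                imputer = get_imputer(imp, impute_params.get(imp))
                imputer.fit(train_tab)
                imp_train = imputer.transform(train_tab)
                imp_test = imputer.transform(test_tab)
            except Exception as exc:  # recorded, not fatal
                for sel in sorted(selectors):
                    number += 1
                    variants.append(
                        _failed_variant(number, imp, sel, flag, str(exc))
                    )
                continue
            for sel in sorted(selectors):
                number += 1
                try:
                    sel_seed = None if seed is None else seed + number
                    result = select(
                        imp_train, sel, select_params.get(sel), seed=sel_seed
                    )
                    chosen = list(result.selected)
                    if not chosen:
                        raise ValueError("selection returned no variables")
                    variants.append(
                        DatasetVariant(
                            number=number,
                            imputer=imp,
                            selector=sel,
                            include_fbg=flag,
                            variable_count=len(chosen),
                            train_count=imp_train.n,
                            selected=tuple(chosen),
                            X_train=imp_train.frame[chosen].astype(float),
                            y_train=imp_train.labels,
                            X_test=imp_test.frame[chosen].astype(float),
                            y_test=imp_test.labels,
                            kinds={v: imp_train.kinds[v] for v in chosen},
                        )
                    )
                except Exception as exc:
                    variants.append(
                        _failed_variant(number, imp, sel, flag, str(exc))
                    )
    return variants


def _failed_variant(number, imp, sel, flag, message) -> DatasetVariant:
    empty = pd.DataFrame()
    return DatasetVariant(
        number=number,
        imputer=imp,
        selector=sel,
        include_fbg=flag,
        variable_count=0,
        train_count=0,
        selected=(),
        X_train=empty,
        y_train=np.array([]),
        X_test=empty,
        y_test=np.array([]),
        kinds={},
        error=message,
    )


def manifest(variants: list[DatasetVariant]) -> pd.DataFrame:
    """Dataset bookkeeping table: number, methods, variable/train counts."""
    return pd.DataFrame(
        {
            "number": [v.number for v in variants],
            "include_fbg": [v.include_fbg for v in variants],
            "imputer": [v.imputer for v in variants],
            "selector": [v.selector for v in variants],
            "n_variables": [v.variable_count for v in variants],
            "n_train": [v.train_count for v in variants],
            "error": [v.error for v in variants],
        }
    )


def _preprocessor(kinds: dict[str, str]) -> ColumnTransformer:
    cont = [v for v, k in kinds.items() if k == "continuous"]
    cat = [v for v, k in kinds.items() if k == "categorical"]
    return ColumnTransformer(
        [
            ("cont", StandardScaler(), cont),
            ("cat", OneHotEncoder(handle_unknown="ignore"), cat),
        ]
    )


def build_estimator(algorithm: str, kinds: dict[str, str], seed: int | None):
    """Base estimator for one algorithm in the shared variable space.

    Tree ensembles consume raw codes; linear and neural models get scaling
    plus one-hot encoding.  The CB slot is histogram gradient boosting with
    native categorical splits.
    """
    cat_cols = [v for v, k in kinds.items() if k == "categorical"]
    if algorithm == "RF":
        return RandomForestClassifier(random_state=seed)
    if algorithm == "LR":
        return Pipeline(
            [
                ("pre", _preprocessor(kinds)),
                ("clf", LogisticRegression(max_iter=2000)),
            ]
        )
    if algorithm == "MLP":
        return Pipeline(
            [
                ("pre", _preprocessor(kinds)),
                ("clf", MLPClassifier(random_state=seed, max_iter=300)),
            ]
        )
    if algorithm == "XGB":
        return XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0
        )
    if algorithm == "LGBM":
        return LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1, subsample_freq=1
        )
    if algorithm == "CB":
        return HistGradientBoostingClassifier(
            random_state=seed,
            categorical_features=[c for c in cat_cols],
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def default_grids() -> dict[str, dict]:
    """Hyperparameter grids anchored on the benchmark's winning values."""
    return {
        "LGBM": {"clf__max_depth": [1, 3, 5], "clf__subsample": [0.1, 0.5, 1.0]},
        "CB": {"clf__max_iter": [50, 67, 100, 200]},
        "RF": {"clf__n_estimators": [100, 147, 200]},
        "XGB": {
            "clf__gamma": [0, 0.1],
            "clf__max_depth": [3, 5],
            "clf__subsample": [0.7, 1.0],
        },
        "MLP": {
            "clf__clf__activation": ["relu", "tanh"],
            "clf__clf__hidden_layer_sizes": [(100, 50, 1)],
            "clf__clf__solver": ["sgd", "adam"],
        },
        "LR": {"clf__clf__C": [0.01, 0.1, 1, 10]},
    }


def fast_grids() -> dict[str, dict]:
    """Reduced grids for desk-scale factorial runs."""
    return {
        "LGBM": {"clf__max_depth": [1, 5], "clf__subsample": [1.0]},
        "CB": {"clf__max_iter": [50, 100]},
        "RF": {"clf__n_estimators": [100]},
        "XGB": {"clf__max_depth": [3, 5]},
        "MLP": {
            "clf__clf__hidden_layer_sizes": [(32,)],
            "clf__clf__solver": ["adam"],
            "clf__clf__max_iter": [200],
        },
        "LR": {"clf__clf__C": [0.1, 1.0]},
    }


def train_model(
    dataset: DatasetVariant,
    spec: ModelSpec,
    folds: int = 5,
    seed: int | None = 0,
) -> TrainedModel:
    """Exhaustive grid search by stratified k-fold AUC, refit on all of train."""
    if dataset.error:
        raise ValueError(f"dataset {dataset.number} failed: {dataset.error}")
    y = dataset.y_train
    if len(np.unique(y)) < 2:
        raise ValueError("training partition has a single class")
    base = build_estimator(spec.algorithm, dataset.kinds, seed)
    # uniform "clf__" prefix so one grid vocabulary covers bare estimators
    # and preprocessing pipelines alike
    estimator = Pipeline([("clf", base)])
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        estimator, spec.grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(dataset.X_train, y)
    return TrainedModel(
        spec=spec,
        best_params=dict(search.best_params_),
        estimator=search.best_estimator_,
        dataset_number=dataset.number,
        seed=seed,
        cv_auc=float(search.best_score_),
    )


@dataclass
class ExperimentConfig:
    """Full factorial settings (ratio, seed, methods, grids, costs)."""

    ratio: float = 0.8
    seed: int = 0
    imputers: tuple[str, ...] = IMPUTERS
    selectors: tuple[str, ...] = SELECTORS
    algorithms: tuple[str, ...] = ALGORITHMS
    include_fbg_flags: tuple[bool, ...] = (True, False)
    folds: int = 5
    grids: dict = field(default_factory=default_grids)
    impute_params: dict = field(default_factory=dict)
    select_params: dict = field(default_factory=dict)
    costs: CostModel = field(default_factory=CostModel)
    threshold: float = 0.5


def run_factorial(
    table: CohortTable, config: ExperimentConfig
) -> tuple[list[ModelGridRecord], pd.DataFrame]:
    """Train and evaluate every flag x imputer x selector x algorithm cell.

    Returns the model records plus the dataset manifest.  Per-cell failures
    are recorded in the record's ``error`` field, never raised.
    """
    if not config.algorithms:
        warnings.warn("empty algorithm list; no models trained", stacklevel=2)
    split = partition_data(table, config.ratio, config.seed)
    variants = enumerate_datasets(
        table,
        split,
        imputers=config.imputers,
        selectors=config.selectors,
        include_fbg_flags=config.include_fbg_flags,
        seed=config.seed,
        impute_params=config.impute_params,
        select_params=config.select_params,
    )
    records: list[ModelGridRecord] = []
    rid = 0
    for variant in variants:
        for algo in config.algorithms:
            rid += 1
            common = dict(
                record_id=rid,
                dataset_number=variant.number,
                imputer=variant.imputer,
                selector=variant.selector,
                algorithm=algo,
                include_fbg=variant.include_fbg,
                n_samples=variant.train_count,
                n_variables=variant.variable_count,
                seed=config.seed,
            )
            if variant.error:
                records.append(
                    ModelGridRecord(
                        metrics=None, best_params=None, error=variant.error, **common
                    )
                )
                continue
            try:
                model = train_model(
                    variant,
                    ModelSpec(algo, config.grids[algo]),
                    folds=config.folds,
                    seed=config.seed,
                )
                scores = model.estimator.predict_proba(variant.X_test)[:, 1]
                report = evaluate_scores(
                    scores, variant.y_test, config.costs, config.threshold
                )
                metrics = {
                    "MB": report.benefit.mb,
                    "AUC": report.auc,
                    "AUPRC": report.auprc,
                    "accuracy": report.accuracy,
                    "precision": report.precision,
                    "recall": report.recall,
                }
                records.append(
                    ModelGridRecord(
                        metrics=metrics,
                        best_params=model.best_params,
                        error=None,
                        **common,
                    )
                )
            except Exception as exc:
                records.append(
                    ModelGridRecord(
                        metrics=None, best_params=None, error=str(exc), **common
                    )
                )
    return records, manifest(variants)


def records_frame(records: list[ModelGridRecord]) -> pd.DataFrame:
    """Long-format results table (one row per trained configuration)."""
    rows = []
    for r in records:
        row = {
            "record_id": r.record_id,
            "dataset_number": r.dataset_number,
            "include_fbg": r.include_fbg,
            "imputer": r.imputer,
            "selector": r.selector,
            "algorithm": r.algorithm,
            "n_samples": r.n_samples,
            "n_variables": r.n_variables,
            "error": r.error,
        }
        if r.metrics:
            row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)
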