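"""Post-hoc analysis of the factorial: ranking, meta-regression, learning
curves.

Model configurations are ranked by Model Benefit (ties broken by AUC, then
record id).  A multi-linear meta-regression relates each performance metric
to the pipeline factors (training-sample count, variable count, imputing
method, screening method); method factors are integer-coded by default
(SI=1, RF=2, KNN=3, OD=4; BOR=1, EN=2, LA=3, RD=4), with one-hot coding as
an option.

The learning-curve procedure re-trains the chosen model on stratified
subsamples of the training partition (10% to 100% in 10% steps, repeated),
evaluating AUC on the fixed test partition, to judge whether the sample
size saturates performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CohortTable
from .evaluation import roc_auc
from .grid import ModelGridRecord, ModelSpec, build_estimator, partition_data

__all__ = [
    "MetaRegressionResult",
    "LearningCurveResult",
    "FlattenPoint",
    "rank_models",
    "meta_regression",
    "sample_size_curve",
    "flatten_point",
]

IMPUTER_CODES = {"SI": 1, "RF": 2, "KNN": 3, "OD": 4}
SELECTOR_CODES = {"BOR": 1, "EN": 2, "LA": 3, "RD": 4}


def rank_models(
    records: list[ModelGridRecord], key: str = "MB", top: int | None = None
) -> list[ModelGridRecord]:
    """Records in descending order of ``key`` (ties: AUC, then record id)."""
    scored = [r for r in records if r.metrics is not None]
    if scored and key not in scored[0].metrics:
        raise KeyError(f"unknown metric {key!r}")
    ordered = sorted(
        scored,
        key=lambda r: (-r.metrics[key], -r.metrics.get("AUC", 0.0), r.record_id),
    )
    return ordered if top is None else ordered[:top]


@dataclass
class MetaRegressionResult:
    """Per-metric OLS fits: one (coefficient, p-value) row per factor."""

    table: pd.DataFrame  # columns: metric, factor, coefficient, p_value
    diagnostics: dict[str, dict]  # metric -> {r_squared, n}

    def coefficient(self, metric: str, factor: str) -> float:
        rows = self.table[
            (self.table.metric == metric) & (self.table.factor == factor)
        ]
        return float(rows.coefficient.iloc[0])

    def p_value(self, metric: str, factor: str) -> float:
        rows = self.table[
            (self.table.metric == metric) & (self.table.factor == factor)
        ]
        return float(rows.p_value.iloc[0])


def _design(
    records: list[ModelGridRecord], factors, coding: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    for r in records:
        if r.metrics is None:
            continue
        row = {
            "n_samples": r.n_samples,
            "n_variables": r.n_variables,
            "imputer": r.imputer,
            "selector": r.selector,
            "algorithm": r.algorithm,
        }
        row.update(r.metrics)
        rows.append(row)
    frame = pd.DataFrame(rows)
    design = pd.DataFrame(index=frame.index)
    for factor in factors:
        if factor in ("n_samples", "n_variables"):
            design[factor] = frame[factor].astype(float)
        elif factor == "imputer":
            if coding == "ordinal":
                design[factor] = frame[factor].map(IMPUTER_CODES).astype(float)
            else:
                design = design.join(pd.get_dummies(
                    frame[factor], prefix="imputer", drop_first=True, dtype=float
                ))
        elif factor == "selector":
            if coding == "ordinal":
                design[factor] = frame[factor].map(SELECTOR_CODES).astype(float)
            else:
                design = design.join(pd.get_dummies(
                    frame[factor], prefix="selector", drop_first=True, dtype=float
                ))
        else:
            design[factor] = frame[factor].astype(float)
    return frame, design


def meta_regression(
    records: list[ModelGridRecord],
    metrics=("MB", "AUC", "accuracy", "precision", "recall"),
    factors=("n_samples", "n_variables", "imputer", "selector"),
    coding: str = "ordinal",
) -> MetaRegressionResult:
    """OLS of each metric on the pipeline factors across grid records."""
    usable = [r for r in records if r.metrics is not None]
    if len(usable) < 2:
        raise ValueError("meta-regression needs at least two scored records")
    if len(usable) < 10:
        warnings.warn(
            f"only {len(usable)} records; coefficients will be unstable",
            stacklevel=2,
        )
    frame, design = _design(usable, factors, coding)
    # drop constant (non-varying) factor columns
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping non-varying factor(s): {constant}", stacklevel=2)
        design = design.drop(columns=constant)
    X = sm.add_constant(design, has_constant="add")
    rows, diagnostics = [], {}
    for metric in metrics:
        fit = sm.OLS(frame[metric].astype(float), X).fit()
        for factor in design.columns:
            rows.append(
                {
                    "metric": metric,
                    "factor": factor,
                    "coefficient": float(fit.params[factor]),
                    "std_err": float(fit.bse[factor]),
                    "p_value": float(fit.pvalues[factor]),
                }
            )
        diagnostics[metric] = {"r_squared": float(fit.rsquared), "n": int(fit.nobs)}
    return MetaRegressionResult(table=pd.DataFrame(rows), diagnostics=diagnostics)


@dataclass
class LearningCurveResult:
    fractions: tuple[float, ...]
    auc_matrix: np.ndarray  # repeats x fractions
    summary: pd.DataFrame  # fraction, mean_auc, sd_auc


@dataclass(frozen=True)
class CurveConfig:
    fractions: tuple[float, ...] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))
    repeats: int = 10
    ratio: float = 0.8
    seed: int | None = 0
    with_replacement: bool = False


def _stratified_subsample(y, fraction, rng, with_replacement):
    take_idx: list[int] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        k = max(1, int(np.floor(fraction * len(idx))))
        if with_replacement:
            take_idx.extend(rng.choice(idx, size=k, replace=True).tolist())
        else:
            take_idx.extend(rng.permutation(idx)[:k].tolist())
    return np.array(sorted(take_idx))


def sample_size_curve(
    table: CohortTable,
    best_spec: ModelSpec,
    config: CurveConfig = CurveConfig(),
) -> LearningCurveResult:
    """AUC versus training fraction for the chosen model configuration.

    ``table`` must be complete (imputed, post-selection).  ``best_spec``'s
    grid must pin every hyperparameter to a single value.  Subsampling is
    stratified by outcome, redrawn per repeat; the test partition and model
    seed stay fixed, so the full-sample point is deterministic.
    """
    for name, values in best_spec.grid.items():
        if isinstance(values, (list, tuple)) and len(values) != 1:
            raise ValueError(f"hyperparameter {name} is not pinned: {values}")
    params = {
        k: (v[0] if isinstance(v, (list, tuple)) else v)
        for k, v in best_spec.grid.items()
    }
    split = partition_data(table, config.ratio, config.seed)
    X = table.frame[table.candidate_columns].astype(float)
    y = table.labels
    X_train, y_train = X.iloc[list(split.train)], y[list(split.train)]
    X_test, y_test = X.iloc[list(split.test)], y[list(split.test)]

    auc = np.empty((config.repeats, len(config.fractions)))
    for rep in range(config.repeats):
        rng = np.random.default_rng(
            None if config.seed is None else [config.seed, rep]
        )
        for fi, fraction in enumerate(config.fractions):
            for attempt in range(5):
                idx = _stratified_subsample(
                    y_train, fraction, rng, config.with_replacement
                )
                if len(np.unique(y_train[idx])) == 2:
                    break
                warnings.warn(
                    f"single-class subsample at fraction {fraction}; redrawing",
                    stacklevel=2,
                )
            est = build_estimator(best_spec.algorithm, table.kinds, config.seed)
            inner = est
            prefix = {}
            for k, v in params.items():
                prefix[k.removeprefix("clf__")] = v
            inner.set_params(**prefix)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                inner.fit(X_train.iloc[idx], y_train[idx])
            scores = inner.predict_proba(X_test)[:, 1]
            auc[rep, fi] = roc_auc(scores, y_test)
    summary = pd.DataFrame(
        {
            "fraction": config.fractions,
            "mean_auc": auc.mean(axis=0),
            "sd_auc": auc.std(axis=0, ddof=1) if config.repeats > 1 else 0.0,
        }
    )
    return LearningCurveResult(
        fractions=tuple(config.fractions), auc_matrix=auc, summary=summary
    )


@dataclass(frozen=True)
class FlattenPoint:
    fraction: float
    flattened: bool


def flatten_point(
    result: LearningCurveResult, tolerance: float = 0.005
) -> FlattenPoint:
    """Smallest fraction after which every mean-AUC increment is < tolerance.

    Purely descriptive; a curve still rising at the last step returns 1.0
    with ``flattened=False``.
    """
    means = result.summary["mean_auc"].to_numpy()
    fractions = result.fractions
    increments = np.diff(means)
    flat_from = len(increments)  # index into fractions
    for i in range(len(increments), 0, -1):
        if increments[i - 1] >= tolerance:
            break
        flat_from = i - 1
    if flat_from == len(increments):
        return FlattenPoint(fraction=float(fractions[-1]), flattened=False)
    return FlattenPoint(fraction=float(fractions[flat_from]), flattened=True)
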