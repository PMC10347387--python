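"""Variable screening: LASSO (LA), ridge (RD), ElasticNet (EN), Boruta (BOR).

LA/EN select variables with nonzero coefficients in a penalized logistic
fit whose penalty strength (and mixing weight, for EN) is chosen by
stratified 5-fold cross-validated AUC.  Ridge never zeroes coefficients, so
RD selects variables whose standardized-coefficient magnitude exceeds the
mean magnitude (a configurable quantile threshold).  BOR is the shadow-
feature all-relevant procedure: each iteration shuffles copies of the
features, fits a random forest on real plus shadow features, scores a "hit"
when a real feature out-ranks the best shadow, and decides features by
binomial tests against chance at level alpha.

Penalized fits run on standardized features (z-scored continuous, one-hot
categorical); a variable is selected if any of its indicator columns is.
Boruta runs on the raw mixed-type matrix, which forests handle natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .cohort import CohortTable

__all__ = ["SelectionResult", "select"]

METHODS = ("LA", "RD", "EN", "BOR")


@dataclass
class SelectionResult:
    method: str
    selected: tuple[str, ...]
    scores: dict[str, float]
    settings: dict = field(default_factory=dict)


def _encode_standardized(table: CohortTable) -> tuple[np.ndarray, list[str]]:
    """Z-scored continuous + one-hot categorical; returns (X, var-per-col)."""
    blocks, owners = [], []
    for var in table.candidate_columns:
        col = table.frame[var].to_numpy(dtype=float)
        if table.kinds[var] == "continuous":
            sd = col.std(ddof=0)
            blocks.append(((col - col.mean()) / (sd if sd > 0 else 1.0))[:, None])
            owners.append(var)
        else:
            levels = np.unique(col)
            for lv in levels:
                blocks.append((col == lv).astype(float)[:, None])
                owners.append(var)
    return np.hstack(blocks), owners


def _validate(table: CohortTable) -> tuple[np.ndarray, np.ndarray]:
    if len(table.candidate_columns) < 2:
        raise ValueError("need at least two candidate variables")
    X = table.frame[table.candidate_columns].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite or missing values; impute before selection")
    y = table.labels
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; selection requires both classes")
    return X, y


def _aggregate(owners: list[str], coefs: np.ndarray) -> dict[str, float]:
    """Per-variable score: L2 norm of the coefficients it owns."""
    scores: dict[str, float] = {}
    for var, c in zip(owners, coefs):
        scores[var] = scores.get(var, 0.0) + float(c) ** 2
    return {v: float(np.sqrt(s)) for v, s in scores.items()}


def _penalized(table, y, method, params, seed):
    X, owners = _encode_standardized(table)
    cv = StratifiedKFold(
        n_splits=params.get("folds", 5), shuffle=True, random_state=seed
    )
    Cs = params.get("Cs", np.logspace(-3, 2, 10))
    common = dict(
        Cs=Cs, cv=cv, scoring="roc_auc", solver="saga",
        max_iter=params.get("max_iter", 2000), tol=params.get("tol", 1e-3),
        random_state=seed, n_jobs=None,
    )
    if method == "LA":
        model = LogisticRegressionCV(penalty="l1", **common)
    elif method == "EN":
        model = LogisticRegressionCV(
            penalty="elasticnet",
            l1_ratios=params.get("l1_ratios", [0.1, 0.5, 0.9]),
            **common,
        )
    else:  # RD
        common.update(solver="lbfgs")
        model = LogisticRegressionCV(penalty="l2", **common)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        model.fit(X, y)
    scores = _aggregate(owners, model.coef_.ravel())
    settings = {"C": float(model.C_[0])}
    if method == "EN":
        settings["l1_ratio"] = float(model.l1_ratio_[0])
    if method in ("LA", "EN"):
        selected = [v for v in table.candidate_columns if scores[v] > 1e-8]
    else:
        threshold_q = params.get("threshold_quantile")
        values = np.array([scores[v] for v in table.candidate_columns])
        cut = (
            float(np.quantile(values, threshold_q))
            if threshold_q is not None
            else float(values.mean())
        )
        selected = [v for v in table.candidate_columns if scores[v] > cut]
        if not selected and np.allclose(values, values[0]):
            selected = list(table.candidate_columns)  # degenerate tie: keep all
        settings["threshold"] = cut
    return selected, scores, settings


def _boruta(table, y, params, seed):
    n_estimators = params.get("n_estimators", 500)
    max_iter = params.get("max_iter", 100)
    alpha = params.get("alpha", 0.05)
    min_iter = params.get("min_iter", 5)
    rng = np.random.default_rng(seed)
    cols = list(table.candidate_columns)
    X = table.frame[cols].to_numpy(dtype=float)
    n, p = X.shape

    hits = np.zeros(p, dtype=int)
    decided = np.zeros(p, dtype=int)  # 0 undecided, 1 confirmed, -1 rejected
    imp_history: list[np.ndarray] = []
    shadow_max_history: list[float] = []

    for it in range(1, max_iter + 1):
        if not (decided == 0).any():
            break
        shadows = X.copy()
        for j in range(p):
            rng.shuffle(shadows[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            max_features="sqrt",
            random_state=int(rng.integers(2**31 - 1)),
        )
        forest.fit(np.hstack([X, shadows]), y)
        imp = forest.feature_importances_
        real, shadow = imp[:p], imp[p:]
        smax = float(shadow.max())
        imp_history.append(real)
        shadow_max_history.append(smax)
        hits += (real > smax).astype(int)

        # Bonferroni across features guards the sequential testing; no
        # confirmations before a minimum number of shadow comparisons.
        corrected = alpha / p
        undecided = np.flatnonzero(decided == 0)
        for j in undecided:
            if it >= min_iter and stats.binom.sf(hits[j] - 1, it, 0.5) < corrected:
                decided[j] = 1
            elif stats.binom.cdf(hits[j], it, 0.5) < corrected:
                decided[j] = -1

    # Tentative features: compare median importance to median shadow max.
    history = np.vstack(imp_history)
    med_smax = float(np.median(shadow_max_history))
    for j in np.flatnonzero(decided == 0):
        decided[j] = 1 if float(np.median(history[:, j])) > med_smax else -1

    scores = {v: float(history[:, j].mean()) for j, v in enumerate(cols)}
    selected = [v for j, v in enumerate(cols) if decided[j] == 1]
    settings = {
        "n_estimators": n_estimators,
        "iterations": len(imp_history),
        "alpha": alpha,
    }
    return selected, scores, settings


def select(
    table: CohortTable,
    method: str,
    params: dict | None = None,
    seed: int | None = 0,
) -> SelectionResult:
    """Screen candidate variables of a complete table by one of LA/RD/EN/BOR."""
    if method not in METHODS:
        raise ValueError(f"unknown selection method {method!r}; choose from {METHODS}")
    params = params or {}
    _, y = _validate(table)
    if method == "BOR":
        selected, scores, settings = _boruta(table, y, params, seed)
    else:
        selected, scores, settings = _penalized(table, y, method, params, seed)
    return SelectionResult(
        method=method,
        selected=tuple(sorted(selected, key=table.candidate_columns.index)),
        scores=scores,
        settings=settings,
    )
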