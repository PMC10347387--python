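"""Additive per-feature attributions (Shapley values) for fitted models.

Attributions explain one prediction as a sum of per-feature contributions
relative to a baseline (the mean prediction over a background sample),
using interventional Shapley values: the payoff of a feature coalition S is
the mean model output with features in S taken from the explained sample
and the rest from the background.

Two estimators are provided, both of which satisfy local accuracy exactly
(baseline + sum of attributions = model output, to floating point):

* exact subset enumeration for small feature counts (2^p coalitions);
* permutation sampling otherwise -- each sampled feature ordering yields
  marginal contributions that telescope to the full prediction, so the
  average over orderings preserves additivity.

Models without a probability output fall back to permutation importance,
flagged as such (those importances are not additive attributions).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance

__all__ = ["AttributionSummary", "shapley_attributions", "attribution_summary"]


@dataclass
class AttributionSummary:
    """Per-sample additive attributions and a global importance ranking."""

    method: str  # "exact-shapley" | "sampling-shapley" | "permutation-importance"
    base_value: float
    attributions: pd.DataFrame | None  # rows = explained samples, cols = features
    ranking: tuple[tuple[str, float], ...]  # (feature, mean |attribution|), desc


def _payoff_matrix(predict_fn, x_row, background, subsets):
    """v(S) for every subset: mean prediction mixing x_row into background."""
    b = len(background)
    values = np.empty(len(subsets))
    for si, subset in enumerate(subsets):
        mixed = background.copy()
        for j in subset:
            mixed[:, j] = x_row[j]
        values[si] = float(np.mean(predict_fn(mixed)))
        del mixed
    return values


def _exact_row(predict_fn, x_row, background, p):
    subsets = []
    for mask in range(2**p):
        subsets.append(tuple(j for j in range(p) if mask >> j & 1))
    v = _payoff_matrix(predict_fn, x_row, background, subsets)
    index = {s: i for i, s in enumerate(subsets)}
    phi = np.zeros(p)
    for s in subsets:
        if len(s) == p:
            continue
        w = 1.0 / (p * comb(p - 1, len(s)))  # |S|!(p-|S|-1)!/p!
        for j in range(p):
            if j in s:
                continue
            s_with = tuple(sorted(s + (j,)))
            phi[j] += w * (v[index[s_with]] - v[index[s]])
    return phi


def _sampling_row(predict_fn, x_row, background, p, rng, n_permutations):
    phi = np.zeros(p)
    for _ in range(n_permutations):
        order = rng.permutation(p)
        mixed = background.copy()
        prev = float(np.mean(predict_fn(mixed)))
        for j in order:
            mixed[:, j] = x_row[j]
            cur = float(np.mean(predict_fn(mixed)))
            phi[j] += cur - prev
            prev = cur
    return phi / n_permutations


def shapley_attributions(
    predict_fn,
    X_background: np.ndarray,
    X_explain: np.ndarray,
    seed: int | None = 0,
    exact_limit: int = 10,
    n_permutations: int = 32,
) -> tuple[str, float, np.ndarray]:
    """Interventional Shapley values of ``predict_fn`` for each explained row.

    Returns (estimator name, base value, attribution matrix).  Exact subset
    enumeration is used when the feature count is at most ``exact_limit``.
    """
    X_background = np.asarray(X_background, dtype=float)
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    p = X_explain.shape[1]
    rng = np.random.default_rng(seed)
    base = float(np.mean(predict_fn(X_background)))
    phi = np.empty((len(X_explain), p))
    exact = p <= exact_limit
    for i, row in enumerate(X_explain):
        if exact:
            phi[i] = _exact_row(predict_fn, row, X_background, p)
        else:
            phi[i] = _sampling_row(
                predict_fn, row, X_background, p, rng, n_permutations
            )
    return ("exact-shapley" if exact else "sampling-shapley", base, phi)


def attribution_summary(
    model,
    data: pd.DataFrame,
    labels=None,
    background_size: int = 64,
    explain_size: int = 64,
    seed: int | None = 0,
    **kwargs,
) -> AttributionSummary:
    """Rank features of a fitted classifier by mean |Shapley attribution|.

    ``data`` is the evaluation table in the model's input space.  Models
    without ``predict_proba`` fall back to permutation importance (requires
    ``labels``), flagged in ``method``.
    """
    rng = np.random.default_rng(seed)
    features = list(data.columns)

    if not hasattr(model, "predict_proba"):
        if labels is None:
            raise ValueError("permutation-importance fallback requires labels")
        result = permutation_importance(
            model, data, labels, n_repeats=10, random_state=seed
        )
        order = np.argsort(result.importances_mean)[::-1]
        ranking = tuple(
            (features[j], float(result.importances_mean[j])) for j in order
        )
        return AttributionSummary(
            method="permutation-importance",
            base_value=float("nan"),
            attributions=None,
            ranking=ranking,
        )

    def predict_fn(X: np.ndarray) -> np.ndarray:
        frame = pd.DataFrame(X, columns=features)
        return model.predict_proba(frame)[:, 1]

    X = data.to_numpy(dtype=float)
    bg_idx = rng.choice(len(X), size=min(background_size, len(X)), replace=False)
    ex_idx = rng.choice(len(X), size=min(explain_size, len(X)), replace=False)
    method, base, phi = shapley_attributions(
        predict_fn, X[bg_idx], X[ex_idx], seed=seed, **kwargs
    )
    attributions = pd.DataFrame(phi, index=ex_idx, columns=features)
    mean_abs = attributions.abs().mean(axis=0)
    ranking = tuple(
        (str(v), float(mean_abs[v]))
        for v in mean_abs.sort_values(ascending=False).index
    )
    return AttributionSummary(
        method=method, base_value=base, attributions=attributions, ranking=ranking
    )
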