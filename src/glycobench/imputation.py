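"""Missing-data handling: SI, KNN, RF imputation and optimal deletion (OD).

All four methods turn an incomplete table into a complete one:

* SI  -- simple imputing: continuous cells get the column mean; categorical
  cells get the median of the observed integer codes (nearest-rank, so the
  fill is always an observed code).
* KNN -- each missing cell is predicted from the k nearest neighbors among
  rows observed in that column, with distances computed on standardized
  continuous plus one-hot categorical features (NaN-aware Euclidean).
* RF  -- iterative random-forest imputation: per incomplete column, a
  forest predicts the missing entries from the other columns, initialized
  by SI and swept until the filled values stabilize.
* OD  -- optimal deletion: instead of filling, delete rows and/or columns
  to retain a maximal complete submatrix (objective: retained cell count).

Imputers follow fit/transform semantics so they can be fit on a training
partition and applied frozen to a test partition (no leakage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics.pairwise import nan_euclidean_distances

from .cohort import CohortTable

__all__ = [
    "ImputationResult",
    "DeletionPlan",
    "impute",
    "get_imputer",
    "optimal_deletion",
    "brute_force_deletion",
    "SimpleImputer",
    "KNNImputer",
    "ForestImputer",
    "DeletionImputer",
]

METHODS = ("SI", "KNN", "RF", "OD")


@dataclass
class DeletionPlan:
    """Rows/columns deleted by OD so the retained submatrix is complete."""

    rows_removed: tuple[int, ...]
    cols_removed: tuple[str, ...]
    retained_rows: int
    retained_cols: int

    @property
    def objective_value(self) -> int:
        return self.retained_rows * self.retained_cols


@dataclass
class ImputationResult:
    table: CohortTable
    method: str
    cells_filled: int
    plan: DeletionPlan | None = None


def _check_outcome_complete(table: CohortTable) -> None:
    if table.outcome in table.frame and table.frame[table.outcome].isna().any():
        raise ValueError("outcome column contains missing values")


def _fully_missing_columns(table: CohortTable) -> list[str]:
    return [v for v in table.candidate_columns if table.frame[v].isna().all()]


class _FittedImputer:
    """Fit-on-train / transform-anywhere base."""

    method: str

    def fit(self, table: CohortTable) -> "_FittedImputer":
        raise NotImplementedError

    def transform(self, table: CohortTable) -> CohortTable:
        raise NotImplementedError

    def _validate_fit(self, table: CohortTable) -> None:
        _check_outcome_complete(table)
        bad = _fully_missing_columns(table)
        if bad and self.method != "OD":
            raise ValueError(
                f"column(s) {bad} are fully missing; remove them with "
                "pre-screening before imputation"
            )


class SimpleImputer(_FittedImputer):
    method = "SI"

    def fit(self, table: CohortTable) -> "SimpleImputer":
        self._validate_fit(table)
        self.fill_: dict[str, float] = {}
        for var in table.candidate_columns:
            observed = table.frame[var].dropna()
            if table.kinds[var] == "continuous":
                self.fill_[var] = float(observed.mean())
            else:
                codes = observed.to_numpy(dtype=float)
                self.fill_[var] = float(np.percentile(codes, 50, method="nearest"))
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        out = table.copy()
        for var, value in self.fill_.items():
            if var not in out.frame:
                continue
            col = out.frame[var]
            if col.dtype == "Int64":
                out.frame[var] = col.fillna(int(value))
            else:
                out.frame[var] = col.fillna(value)
        return out


def _encode_for_distance(
    frame: pd.DataFrame, kinds: dict[str, str], stats: dict
) -> np.ndarray:
    """Standardized continuous + one-hot categorical, NaN kept for missing."""
    blocks = []
    for var in stats["order"]:
        col = frame[var].to_numpy(dtype=float, na_value=np.nan)
        if kinds[var] == "continuous":
            mu, sd = stats["scale"][var]
            blocks.append(((col - mu) / sd)[:, None])
        else:
            levels = stats["levels"][var]
            block = np.zeros((len(col), len(levels)))
            block[np.isnan(col)] = np.nan
            for j, lv in enumerate(levels):
                block[col == lv, j] = 1.0
            blocks.append(block)
    return np.hstack(blocks)


class KNNImputer(_FittedImputer):
    method = "KNN"

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, table: CohortTable) -> "KNNImputer":
        self._validate_fit(table)
        self.train_ = table.copy()
        order = list(table.candidate_columns)
        scale, levels = {}, {}
        for var in order:
            observed = table.frame[var].dropna().to_numpy(dtype=float)
            if table.kinds[var] == "continuous":
                sd = float(np.std(observed, ddof=1)) if len(observed) > 1 else 1.0
                scale[var] = (float(np.mean(observed)), sd if sd > 0 else 1.0)
            else:
                levels[var] = sorted(set(observed))
        self.stats_ = {"order": order, "scale": scale, "levels": levels}
        self.train_encoded_ = _encode_for_distance(
            table.frame, table.kinds, self.stats_
        )
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        out = table.copy()
        incomplete = out.frame[out.candidate_columns].isna().any(axis=1)
        if not incomplete.any():
            return out
        query = _encode_for_distance(
            out.frame.loc[incomplete], out.kinds, self.stats_
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = nan_euclidean_distances(query, self.train_encoded_)
        rows = np.flatnonzero(incomplete.to_numpy())
        pos = out.frame.index[rows]
        for qi, row_label in zip(range(len(rows)), pos):
            for var in out.candidate_columns:
                if not pd.isna(out.frame.at[row_label, var]):
                    continue
                donors = self.train_.frame[var].notna().to_numpy()
                d = np.where(donors, dist[qi], np.inf)
                # stable order: distance, then train row position
                k = min(self.k, int(donors.sum()))
                nearest = np.lexsort((np.arange(len(d)), d))[:k]
                values = self.train_.frame[var].iloc[nearest].to_numpy(dtype=float)
                if out.kinds[var] == "continuous":
                    out.frame.at[row_label, var] = float(values.mean())
                else:
                    codes, counts = np.unique(values, return_counts=True)
                    out.frame.at[row_label, var] = int(codes[np.argmax(counts)])
        return out


class ForestImputer(_FittedImputer):
    """Iterative per-column random-forest imputation, SI-initialized."""

    method = "RF"

    def __init__(
        self,
        n_estimators: int = 100,
        max_sweeps: int = 10,
        tol: float = 1e-3,
        seed: int | None = 0,
    ):
        self.n_estimators = n_estimators
        self.max_sweeps = max_sweeps
        self.tol = tol
        self.seed = seed

    def fit(self, table: CohortTable) -> "ForestImputer":
        self._validate_fit(table)
        self.si_ = SimpleImputer().fit(table)
        cols = table.candidate_columns
        missing_counts = table.frame[cols].isna().sum()
        self.targets_ = [
            v for v in sorted(cols, key=lambda v: (missing_counts[v], cols.index(v)))
            if missing_counts[v] > 0
        ]
        self.models_: dict[str, object] = {}
        if not self.targets_:
            return self
        filled = self.si_.transform(table)
        X = filled.frame[cols].astype(float)
        scale = X.std(ddof=0).replace(0.0, 1.0)
        prev = X.copy()
        for sweep in range(self.max_sweeps):
            for var in self.targets_:
                observed = table.frame[var].notna().to_numpy()
                others = [c for c in cols if c != var]
                if table.kinds[var] == "continuous":
                    model = RandomForestRegressor(
                        n_estimators=self.n_estimators, random_state=self.seed
                    )
                else:
                    model = RandomForestClassifier(
                        n_estimators=self.n_estimators, random_state=self.seed
                    )
                model.fit(X.loc[observed, others], X.loc[observed, var])
                X.loc[~observed, var] = model.predict(X.loc[~observed, others])
                self.models_[var] = model
            change = float(((X - prev).abs() / scale).to_numpy().max())
            prev = X.copy()
            if change < self.tol:
                break
        self._finalize = X  # unused beyond debugging
        return self

    def _apply_models(self, table: CohortTable, sweeps: int = 2) -> CohortTable:
        out = self.si_.transform(table)
        cols = [c for c in out.candidate_columns]
        X = out.frame[cols].astype(float)
        for _ in range(sweeps):
            for var in self.targets_:
                if var not in X:
                    continue
                missing = table.frame[var].isna().to_numpy()
                if not missing.any():
                    continue
                others = [c for c in cols if c != var]
                X.loc[missing, var] = self.models_[var].predict(X.loc[missing, others])
        for var in cols:
            if out.frame[var].dtype == "Int64":
                out.frame[var] = pd.array(
                    np.rint(X[var].to_numpy()).astype(int), dtype="Int64"
                )
            else:
                out.frame[var] = X[var].to_numpy()
        return out

    def transform(self, table: CohortTable) -> CohortTable:
        if not self.targets_:
            return self.si_.transform(table)
        return self._apply_models(table)


class DeletionImputer(_FittedImputer):
    """OD: drop the training plan's columns; drop incomplete rows."""

    method = "OD"

    def fit(self, table: CohortTable) -> "DeletionImputer":
        _check_outcome_complete(table)
        self.plan_ = optimal_deletion(table)
        return self

    def transform(self, table: CohortTable) -> CohortTable:
        out = table.copy()
        drop_cols = [c for c in self.plan_.cols_removed if c in out.frame.columns]
        out.frame = out.frame.drop(columns=drop_cols)
        out.kinds = {v: k for v, k in out.kinds.items() if v not in drop_cols}
        keep = out.frame[out.candidate_columns].notna().all(axis=1)
        out.frame = out.frame.loc[keep]
        return out


_IMPUTERS = {
    "SI": SimpleImputer,
    "KNN": KNNImputer,
    "RF": ForestImputer,
    "OD": DeletionImputer,
}


def get_imputer(method: str, params: dict | None = None) -> _FittedImputer:
    if method not in _IMPUTERS:
        raise ValueError(f"unknown imputation method {method!r}; choose from {METHODS}")
    return _IMPUTERS[method](**(params or {}))


def impute(
    table: CohortTable, method: str, params: dict | None = None
) -> ImputationResult:
    """Fit an imputer on ``table`` and return the completed table."""
    imputer = get_imputer(method, params)
    imputer.fit(table)
    out = imputer.transform(table)
    if method == "OD":
        plan = imputer.plan_
        filled = 0
    else:
        plan = None
        filled = int(table.frame[table.candidate_columns].isna().sum().sum())
    assert out.is_complete()
    return ImputationResult(table=out, method=method, cells_filled=filled, plan=plan)


# --- optimal deletion ------------------------------------------------------


def _mask_matrix(table: CohortTable) -> tuple[np.ndarray, list[str]]:
    cols = table.candidate_columns
    return table.frame[cols].isna().to_numpy(), cols


def _exact_deletion(
    miss: np.ndarray, cols: list[str], index
) -> tuple[np.ndarray, np.ndarray] | None:
    """Exact maximum-retained-cells plan over incomplete-column subsets.

    Complete columns are always worth keeping, so only subsets of the
    incomplete columns need enumeration; for each kept subset S the optimal
    row set is exactly the rows with no missing cell inside S.  Row counts
    per subset come from a subset-sum sweep over row missingness bitmasks.
    """
    n_rows, n_cols = miss.shape
    incomplete = np.flatnonzero(miss.any(axis=0))
    k = len(incomplete)
    full = (1 << k) - 1
    # bitmask of each row's missing cells over the incomplete columns
    patterns = (miss[:, incomplete] << np.arange(k)).sum(axis=1).astype(np.int64)
    counts = np.bincount(patterns, minlength=1 << k).astype(np.int64)
    # g[M] = number of rows whose pattern is a subset of M
    g = counts.copy()
    for j in range(k):
        m = g.reshape([2] * k)  # dimension j corresponds to bit k-1-j
        idx = k - 1 - j
        sl_hi = [slice(None)] * k
        sl_lo = [slice(None)] * k
        sl_hi[idx], sl_lo[idx] = 1, 0
        m[tuple(sl_hi)] += m[tuple(sl_lo)]
        g = m.reshape(-1)
    subsets = np.arange(1 << k, dtype=np.int64)
    popcount = np.array([bin(s).count("1") for s in subsets])
    rows_ok = g[full ^ subsets]
    cells = rows_ok * (n_cols - k + popcount)
    best = int(np.lexsort((-(rows_ok), -cells))[0])
    kept_bits = best
    kept_incomplete = {
        int(incomplete[j]) for j in range(k) if kept_bits >> j & 1
    }
    col_keep = np.array(
        [j not in set(incomplete) or j in kept_incomplete for j in range(n_cols)]
    )
    row_keep = (patterns & kept_bits) == 0
    return row_keep, col_keep


def optimal_deletion(table: CohortTable, exact_limit: int = 16) -> DeletionPlan:
    """Delete rows/columns to retain a maximal complete submatrix.

    The objective is the retained cell count (rows x columns).  When at
    most ``exact_limit`` columns carry missing cells the plan is provably
    optimal (enumeration over incomplete-column subsets); beyond that a
    greedy heuristic runs -- repeatedly delete the row or column with the
    largest missing count (ties toward column deletion, then lowest index),
    then restore any deleted rows/columns that are complete with respect to
    the retained set.
    """
    if table.n == 0:
        raise ValueError("cannot apply optimal deletion to an empty table")
    miss, cols = _mask_matrix(table)
    n_rows, n_cols = miss.shape
    if miss.size and miss.all():
        warnings.warn("every cell is missing; deleting all rows", stacklevel=2)
    n_incomplete = int(miss.any(axis=0).sum())
    if n_incomplete <= exact_limit:
        row_keep, col_keep = _exact_deletion(miss, cols, table.frame.index)
        return DeletionPlan(
            rows_removed=tuple(
                int(table.frame.index[i]) for i in np.flatnonzero(~row_keep)
            ),
            cols_removed=tuple(cols[j] for j in np.flatnonzero(~col_keep)),
            retained_rows=int(row_keep.sum()),
            retained_cols=int(col_keep.sum()),
        )
    row_active = np.ones(n_rows, dtype=bool)
    col_active = np.ones(n_cols, dtype=bool)

    while True:
        sub = miss[np.ix_(row_active, col_active)]
        if sub.size == 0 or not sub.any():
            break
        row_counts = miss[:, col_active].sum(axis=1) * row_active
        col_counts = miss[row_active].sum(axis=0) * col_active
        best_col = int(np.argmax(col_counts))
        best_row = int(np.argmax(row_counts))
        if col_counts[best_col] >= row_counts[best_row]:
            col_active[best_col] = False
        else:
            row_active[best_row] = False

    # Restoration pass: anything deleted that is complete w.r.t. the
    # currently retained set comes back; iterate to a fixed point.
    changed = True
    while changed:
        changed = False
        for i in np.flatnonzero(~row_active):
            if not miss[i, col_active].any():
                row_active[i] = True
                changed = True
        for j in np.flatnonzero(~col_active):
            if not miss[row_active, j].any():
                col_active[j] = True
                changed = True

    row_ids = tuple(
        int(table.frame.index[i]) for i in np.flatnonzero(~row_active)
    )
    return DeletionPlan(
        rows_removed=row_ids,
        cols_removed=tuple(cols[j] for j in np.flatnonzero(~col_active)),
        retained_rows=int(row_active.sum()),
        retained_cols=int(col_active.sum()),
    )


def brute_force_deletion(table: CohortTable, max_dim: int = 12) -> DeletionPlan:
    """Exhaustive optimum over column subsets (test oracle for OD).

    For any column subset kept, the optimal row set is exactly the rows
    complete on those columns, so enumerating column subsets is exhaustive
    over all complete-submatrix deletion plans.
    """
    miss, cols = _mask_matrix(table)
    n_rows, n_cols = miss.shape
    if n_rows > max_dim or n_cols > max_dim:
        raise ValueError(
            f"table {n_rows}x{n_cols} exceeds the brute-force cap of {max_dim}"
        )
    best = (-1, -1, ())  # (cells, n_kept_cols, kept cols)
    for size in range(n_cols, -1, -1):
        for kept in combinations(range(n_cols), size):
            kept_arr = np.array(kept, dtype=int)
            complete_rows = (
                ~miss[:, kept_arr].any(axis=1) if size else np.ones(n_rows, bool)
            )
            cells = int(complete_rows.sum()) * size
            if (cells, size) > best[:2]:
                best = (cells, size, kept)
    _, size, kept = best
    kept_set = set(kept)
    kept_arr = np.array(sorted(kept_set), dtype=int)
    complete_rows = (
        ~miss[:, kept_arr].any(axis=1) if size else np.zeros(n_rows, bool)
    )
    return DeletionPlan(
        rows_removed=tuple(
            int(table.frame.index[i]) for i in np.flatnonzero(~complete_rows)
        ),
        cols_removed=tuple(c for j, c in enumerate(cols) if j not in kept_set),
        retained_rows=int(complete_rows.sum()),
        retained_cols=size,
    )
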