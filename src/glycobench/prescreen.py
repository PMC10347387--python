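"""Outcome derivation and variable pre-screening.

The binary target is poor glycemic control: HbA1c strictly above 7.0% is
positive (a value of exactly 7.0 is negative, matching the grouping of the
controlled arm as HbA1c <= 7.0).

Pre-screening removes uninformative columns by three rules, applied in
order, with every removal statistic computed on the original table:

1. missing fraction above ``max_missing_fraction`` (default 0.90);
2. a single value occupying more than ``max_single_value_fraction`` of the
   observed entries (default 0.90);
3. coefficient of variation sd/|mean| below ``min_cv`` (default 0.1),
   continuous columns only -- a CV on integer level codes is meaningless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable

__all__ = [
    "OutcomeRule",
    "PrescreenConfig",
    "PrescreenReport",
    "derive_outcome",
    "apply_prescreen",
]


@dataclass(frozen=True)
class OutcomeRule:
    threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold}")


@dataclass(frozen=True)
class PrescreenConfig:
    max_missing_fraction: float = 0.90
    max_single_value_fraction: float = 0.90
    min_cv: float = 0.1

    def __post_init__(self) -> None:
        for name in ("max_missing_fraction", "max_single_value_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {value}")
        if self.min_cv < 0:
            raise ValueError(f"min_cv must be >= 0, got {self.min_cv}")


@dataclass(frozen=True)
class PrescreenReport:
    """Which columns were removed, by which rule, at what statistic."""

    removed: tuple[tuple[str, str, float], ...]
    kept: tuple[str, ...]

    @property
    def removed_ids(self) -> list[str]:
        return [var for var, _, _ in self.removed]


def derive_outcome(hba1c_value: float, rule: OutcomeRule = OutcomeRule()) -> int:
    """Dichotomize an HbA1c percentage: 1 if above the threshold, else 0."""
    if hba1c_value is None or (
        isinstance(hba1c_value, float) and math.isnan(hba1c_value)
    ):
        raise ValueError("HbA1c value is missing; the outcome must be observed")
    if hba1c_value < 0:
        raise ValueError(f"HbA1c value must be >= 0, got {hba1c_value}")
    return int(hba1c_value > rule.threshold)


def apply_prescreen(
    table: CohortTable, config: PrescreenConfig = PrescreenConfig()
) -> tuple[CohortTable, PrescreenReport]:
    """Remove uninformative candidate columns; report every removal.

    Rules fire in order and each removed column is attributed to the first
    rule that fires for it; all statistics are computed on the input table
    (no cascade recomputation), so the operation is idempotent.
    """
    if table.n == 0:
        raise ValueError("cannot pre-screen an empty table")

    removed: list[tuple[str, str, float]] = []
    decided: set[str] = set()

    # Rule 1: missingness.  A column with zero observed entries is a
    # missing-fraction-1.0 removal.
    for var in table.candidate_columns:
        frac = float(table.frame[var].isna().mean())
        if frac > config.max_missing_fraction:
            removed.append((var, "missing_fraction", frac))
            decided.add(var)

    # Rule 2: single-value dominance among observed cells.
    for var in table.candidate_columns:
        if var in decided:
            continue
        observed = table.frame[var].dropna()
        if len(observed) == 0:
            continue  # already caught by rule 1 unless threshold is 1.0
        top = float(observed.value_counts(sort=True).iloc[0]) / len(observed)
        if top > config.max_single_value_fraction:
            removed.append((var, "single_value_fraction", top))
            decided.add(var)

    # Rule 3: coefficient of variation, continuous columns only.
    for var in table.candidate_columns:
        if var in decided or table.kinds[var] != "continuous":
            continue
        observed = table.frame[var].dropna().to_numpy(dtype=float)
        if len(observed) < 2:
            continue
        mean = float(np.mean(observed))
        sd = float(np.std(observed, ddof=1))
        if mean == 0.0:
            warnings.warn(
                f"{var}: zero mean, coefficient of variation undefined; kept",
                stacklevel=2,
            )
            continue
        cv = sd / abs(mean)
        if cv < config.min_cv:
            removed.append((var, "coefficient_of_variation", cv))
            decided.add(var)

    kept = [v for v in table.candidate_columns if v not in decided]
    report = PrescreenReport(removed=tuple(removed), kept=tuple(kept))

    keep_cols = [c for c in table.frame.columns if c not in decided]
    screened = CohortTable(
        table.frame[keep_cols].copy(),
        {v: k for v, k in table.kinds.items() if v in kept},
        table.outcome,
    )
    return screened, report
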