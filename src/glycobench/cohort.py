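"""Synthetic patient cohort generation.

Draws patient-level tables whose marginal structure mirrors the study
population: the outcome label is Bernoulli with the configured prevalence
(default 52.3% poorly controlled), and every candidate variable is drawn
from its class-conditional marginal distribution in the catalog.  Variables
are sampled independently given the outcome class; the catalog provides
marginals only, so no inter-variable correlation is modeled.

Missingness is injected separately (missing completely at random, per-
variable rates), emulating routinely incomplete fields such as the same-day
fasting blood glucose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog, load_variable_catalog, sample_continuous

__all__ = ["CohortConfig", "CohortTable", "sample_cohort", "inject_missingness"]

#: Default MCAR rates: same-day FBG and waistline are the routinely
#: incomplete measurements; everything else is interview data.
DEFAULT_MISSING_RATES = {"X55": 0.05, "X4": 0.05}

_MISSING_STREAM = 104729  # offsets the missingness RNG from the sampling RNG


@dataclass(frozen=True)
class CohortConfig:
    """Settings for one synthetic cohort draw."""

    n: int
    prevalence: float = 0.523
    seed: int | None = None
    missing_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    include_fbg: bool = True
    include_value: bool = False  # also emit a continuous HbA1c display value

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be >= 0, got {self.n}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")
        for var, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {var} outside [0, 1]: {rate}")


@dataclass
class CohortTable:
    """A patient-level table: candidate variables plus the binary outcome.

    Missing cells are NA in ``frame`` (the mask is implicit).  ``kinds``
    maps variable id to "continuous"/"categorical"; categorical columns
    hold integer level codes in catalog order.
    """

    frame: pd.DataFrame
    kinds: dict[str, str]
    outcome: str = "hba1c_label"

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def candidate_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c in self.kinds]

    @property
    def labels(self) -> np.ndarray:
        return self.frame[self.outcome].to_numpy(dtype=int)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the cell is observed."""
        return self.frame[self.candidate_columns].notna()

    def copy(self) -> "CohortTable":
        return CohortTable(self.frame.copy(), dict(self.kinds), self.outcome)

    def is_complete(self) -> bool:
        return bool(self.frame[self.candidate_columns].notna().all().all())

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path, catalog: Catalog | None = None) -> "CohortTable":
        catalog = catalog or load_variable_catalog()
        frame = pd.read_csv(path)
        kinds = {v: k for v, k in catalog.kinds().items() if v in frame.columns}
        for var, kind in kinds.items():
            if kind == "categorical":
                frame[var] = frame[var].astype("Int64")
        return cls(frame, kinds, catalog.outcome.name)


def sample_cohort(catalog: Catalog, config: CohortConfig) -> CohortTable:
    """Draw a complete cohort (no missingness) from the catalog marginals.

    Fully reproducible: identical (catalog, config) give identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    labels = (rng.random(n) < config.prevalence).astype(np.int8)
    pos = labels == 1

    columns: dict[str, object] = {}
    kinds: dict[str, str] = {}
    for spec in catalog:
        if spec.id == "X55" and not config.include_fbg:
            continue
        kinds[spec.id] = spec.kind
        if spec.kind == "continuous":
            col = np.empty(n, dtype=float)
            for positive, idx in ((False, ~pos), (True, pos)):
                params = spec.params_for(positive)
                col[idx] = sample_continuous(params, int(idx.sum()), rng)
            columns[spec.id] = col
        else:
            col = np.zeros(n, dtype=np.int64)
            n_levels = len(spec.levels)
            for positive, idx in ((False, ~pos), (True, pos)):
                freqs = np.asarray(spec.params_for(positive).frequencies)
                col[idx] = rng.choice(n_levels, size=int(idx.sum()), p=freqs)
            columns[spec.id] = pd.array(col, dtype="Int64")

    frame = pd.DataFrame(columns, index=range(n))
    if config.include_value and catalog.outcome.value_params:
        values = np.empty(n, dtype=float)
        for cls, idx in (("negative", ~pos), ("positive", pos)):
            params = catalog.outcome.value_params[cls]
            values[idx] = sample_continuous(params, int(idx.sum()), rng)
        frame["hba1c_value"] = values
    frame[catalog.outcome.name] = labels
    return CohortTable(frame, kinds, catalog.outcome.name)


def inject_missingness(table: CohortTable, config: CohortConfig) -> CohortTable:
    """Mask cells independently per variable at the configured MCAR rates.

    The outcome is never masked.  Uses an RNG stream decoupled from the
    sampling stream so turning missingness on does not change the values.
    """
    unknown = [v for v in config.missing_rates if v not in table.kinds]
    if unknown:
        raise ValueError(f"missing_rates name unknown variables: {unknown}")
    seed = None if config.seed is None else [config.seed, _MISSING_STREAM]
    rng = np.random.default_rng(seed)
    out = table.copy()
    for var, rate in config.missing_rates.items():
        if rate == 0.0:
            continue
        mask = rng.random(table.n) < rate
        col = out.frame[var]
        if col.dtype == "Int64":
            col = col.mask(mask)
        else:
            col = col.where(~mask, np.nan)
        out.frame[var] = col
    return out
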