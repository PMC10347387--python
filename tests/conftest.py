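import numpy as np
import pandas as pd
import pytest

import glycobench as gb
from glycobench.cohort import CohortTable


@pytest.fixture(scope="session")
def catalog():
    return gb.load_variable_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """Complete 600-patient cohort (no missingness)."""
    cfg = gb.CohortConfig(n=600, seed=11, missing_rates={})
    return gb.sample_cohort(catalog, cfg)


@pytest.fixture(scope="session")
def masked_cohort(catalog):
    """600-patient cohort with default FBG/waistline missingness injected."""
    cfg = gb.CohortConfig(n=600, seed=11)
    return gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)


def toy_table(data: dict, kinds: dict, labels=None) -> CohortTable:
    """Small hand-built CohortTable; labels default to alternating 0/1."""
    frame = pd.DataFrame(data)
    n = len(frame)
    frame["y"] = labels if labels is not None else np.arange(n) % 2
    for var, kind in kinds.items():
        if kind == "categorical":
            frame[var] = frame[var].astype("Int64")
    return CohortTable(frame, dict(kinds), "y")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
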