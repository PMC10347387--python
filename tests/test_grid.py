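"""Partitioning, dataset enumeration, grid-search training."""

import numpy as np
import pandas as pd
import pytest

import glycobench as gb
from glycobench.grid import enumerate_datasets, train_model
from tests.conftest import toy_table

FAST_IMPUTE = {"RF": {"n_estimators": 10, "max_sweeps": 2}}
FAST_SELECT = {
    "BOR": {"n_estimators": 30, "max_iter": 10},
    "EN": {"l1_ratios": [0.5]},
}


class TestPartition:
    def test_980_gives_784_train_196_test(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=980, seed=1))
        split = gb.partition_data(table, 0.8, seed=1)
        assert len(split.train) == 784 and len(split.test) == 196

    def test_tiny_split(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=10, seed=1))
        split = gb.partition_data(table, 0.8, seed=1)
        assert len(split.train) == 8 and len(split.test) == 2

    def test_stratification_within_one_patient(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=980, seed=2))
        split = gb.partition_data(table, 0.8, seed=2)
        labels = table.labels
        overall = labels.mean()
        train_rate = labels[list(split.train)].mean()
        assert abs(train_rate - overall) * len(split.train) <= 1.0

    def test_deterministic_under_seed(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=200, seed=3))
        a = gb.partition_data(table, 0.8, seed=9)
        b = gb.partition_data(table, 0.8, seed=9)
        assert a.train == b.train and a.test == b.test

    def test_disjoint_and_exhaustive(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=101, seed=4))
        split = gb.partition_data(table, 0.8, seed=0)
        assert set(split.train) | set(split.test) == set(range(101))
        assert not set(split.train) & set(split.test)

    def test_degenerate_inputs_rejected(self, catalog):
        table = gb.sample_cohort(catalog, gb.CohortConfig(n=1, seed=0))
        with pytest.raises(ValueError):
            gb.partition_data(table, 0.8, seed=0)
        big = gb.sample_cohort(catalog, gb.CohortConfig(n=10, seed=0))
        with pytest.raises(ValueError):
            gb.partition_data(big, 1.2, seed=0)


@pytest.fixture(scope="module")
def screened_cohort():
    catalog = gb.load_variable_catalog()
    cfg = gb.CohortConfig(n=300, seed=21)
    table = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
    screened, _ = gb.apply_prescreen(table)
    return screened


class TestEnumerateDatasets:
    def test_single_cell(self, screened_cohort):
        split = gb.partition_data(screened_cohort, 0.8, seed=0)
        variants = enumerate_datasets(
            screened_cohort, split, imputers=("SI",), selectors=("RD",), seed=0
        )
        assert len(variants) == 1
        v = variants[0]
        assert v.error is None
        assert v.imputer == "SI" and v.selector == "RD"
        assert 0 < v.variable_count <= len(screened_cohort.candidate_columns)
        assert v.train_count == len(split.train)
        assert set(v.X_test.columns) == set(v.selected)

    def test_both_flags_double_the_variants(self, screened_cohort):
        split = gb.partition_data(screened_cohort, 0.8, seed=0)
        variants = enumerate_datasets(
            screened_cohort,
            split,
            imputers=("SI", "OD"),
            selectors=("RD",),
            include_fbg_flags=(True, False),
            seed=0,
        )
        assert len(variants) == 4
        assert [v.include_fbg for v in variants] == [True, True, False, False]
        for v in variants:
            if not v.include_fbg:
                assert "X55" not in v.selected

    def test_numbering_follows_alphabetical_order(self, screened_cohort):
        split = gb.partition_data(screened_cohort, 0.8, seed=0)
        variants = enumerate_datasets(
            screened_cohort,
            split,
            imputers=("SI", "KNN"),
            selectors=("RD", "LA"),
            seed=0,
            select_params=FAST_SELECT,
        )
        order = [(v.imputer, v.selector) for v in variants]
        assert order == [
            ("KNN", "LA"), ("KNN", "RD"), ("SI", "LA"), ("SI", "RD")
        ]
        assert [v.number for v in variants] == [1, 2, 3, 4]


class TestTrainModel:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        n = 120
        y = np.repeat([0, 1], n // 2)
        x0 = y * 10.0 + rng.normal(0, 0.1, n)
        x1 = rng.normal(size=n)
        table = toy_table(
            {"A": x0, "B": x1},
            {"A": "continuous", "B": "continuous"},
            labels=y,
        )
        split = gb.partition_data(table, 0.8, seed=0)
        (variant,) = enumerate_datasets(
            table, split, imputers=("SI",), selectors=("RD",), seed=0
        )
        model = train_model(
            variant, gb.ModelSpec("RF", {"clf__n_estimators": [20]}), folds=3, seed=0
        )
        preds = model.estimator.predict(variant.X_train)
        assert (preds == variant.y_train).mean() == 1.0

    def test_grid_choice_deterministic_under_seed(self, screened_cohort):
        split = gb.partition_data(screened_cohort, 0.8, seed=1)
        (variant,) = enumerate_datasets(
            screened_cohort, split, imputers=("SI",), selectors=("RD",), seed=1
        )
        spec = gb.ModelSpec("LGBM", {"clf__max_depth": [1, 3], "clf__subsample": [1.0]})
        a = train_model(variant, spec, folds=3, seed=5)
        b = train_model(variant, spec, folds=3, seed=5)
        assert a.best_params == b.best_params
        assert a.cv_auc == b.cv_auc

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            gb.ModelSpec("RF", {})

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            gb.ModelSpec("SVM", {"C": [1]})


@pytest.fixture(scope="module")
def mini_run():
    catalog = gb.load_variable_catalog()
    cfg = gb.CohortConfig(n=260, seed=31)
    table = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
    screened, _ = gb.apply_prescreen(table)
    config = gb.ExperimentConfig(
        seed=31,
        imputers=("SI", "OD"),
        selectors=("RD",),
        algorithms=("LGBM", "LR"),
        include_fbg_flags=(True,),
        folds=3,
        grids=gb.fast_grids(),
        impute_params=FAST_IMPUTE,
        select_params=FAST_SELECT,
    )
    return gb.run_factorial(screened, config)


class TestFactorial:
    def test_record_count_and_completeness(self, mini_run):
        records, man = mini_run
        assert len(records) == 2 * 1 * 2  # imputers x selectors x algorithms
        assert len(man) == 2
        for r in records:
            assert (r.metrics is not None) != (r.error is not None)

    def test_metrics_are_finite(self, mini_run):
        records, _ = mini_run
        for r in records:
            assert r.error is None
            for value in r.metrics.values():
                assert np.isfinite(value)

    def test_empty_algorithm_list_warns_and_returns_datasets_only(
        self, screened_cohort
    ):
        config = gb.ExperimentConfig(
            seed=0,
            imputers=("SI",),
            selectors=("RD",),
            algorithms=(),
            include_fbg_flags=(True,),
            grids=gb.fast_grids(),
        )
        with pytest.warns(UserWarning, match="empty algorithm"):
            records, man = gb.run_factorial(screened_cohort, config)
        assert records == [] and len(man) == 1

    def test_leakage_guard_test_rows_do_not_influence_training(self):
        """Mutating test-partition rows changes nothing about the trained
        model (imputer statistics, selection, hyperparameters, or
        predictions on fixed probe data)."""
        catalog = gb.load_variable_catalog()
        cfg = gb.CohortConfig(n=240, seed=41)
        table = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
        screened, _ = gb.apply_prescreen(table)
        split = gb.partition_data(screened, 0.8, seed=41)

        mutated = screened.copy()
        test_rows = list(split.test)
        for var in mutated.candidate_columns:
            if mutated.kinds[var] == "continuous":
                mutated.frame.loc[
                    mutated.frame.index[test_rows], var
                ] *= 3.7

        def fit(tab):
            (variant,) = enumerate_datasets(
                tab, split, imputers=("SI",), selectors=("RD",), seed=41
            )
            model = train_model(
                variant,
                gb.ModelSpec("LGBM", {"clf__max_depth": [1, 3]}),
                folds=3,
                seed=41,
            )
            return variant, model

        v1, m1 = fit(screened)
        v2, m2 = fit(mutated)
        assert v1.selected == v2.selected
        assert m1.best_params == m2.best_params
        probe = v1.X_train.iloc[:20]
        assert np.allclose(
            m1.estimator.predict_proba(probe), m2.estimator.predict_proba(probe)
        )
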