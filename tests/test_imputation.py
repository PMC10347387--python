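"""The four missing-data methods and the optimal-deletion oracle."""

import numpy as np
import pandas as pd
import pytest

import glycobench as gb
from glycobench.cohort import CohortTable
from tests.conftest import toy_table


def random_masked_table(rng, n_rows=6, n_cols=6, rate=0.2):
    mask = rng.random((n_rows, n_cols)) < rate
    data = np.where(mask, np.nan, rng.normal(size=(n_rows, n_cols)))
    cols = [f"C{j}" for j in range(n_cols)]
    frame = pd.DataFrame(data, columns=cols)
    frame["y"] = rng.integers(0, 2, n_rows)
    return CohortTable(frame, {c: "continuous" for c in cols}, "y")


class TestSimpleImputing:
    def test_continuous_filled_with_column_mean(self):
        table = toy_table(
            {"A": [1.0, 2.0, np.nan, 3.0], "B": [0.0, 1.0, 2.0, 3.0]},
            {"A": "continuous", "B": "continuous"},
        )
        result = gb.impute(table, "SI")
        assert result.table.frame["A"].iloc[2] == pytest.approx(2.0)
        assert result.cells_filled == 1

    def test_categorical_filled_with_observed_median_code(self):
        table = toy_table(
            {"A": [0, 0, 1, 2, None, 2], "B": [1.0] * 6},
            {"A": "categorical", "B": "continuous"},
        )
        result = gb.impute(table, "SI")
        # observed codes [0, 0, 1, 2, 2] -> median 1, an observed code
        assert result.table.frame["A"].iloc[4] == 1

    def test_complete_table_is_identity(self, small_cohort):
        for method in ("SI", "KNN", "OD"):
            result = gb.impute(small_cohort, method)
            assert result.cells_filled == 0
            assert result.table.frame.equals(small_cohort.frame)

    def test_fully_missing_column_rejected(self):
        table = toy_table(
            {"A": [np.nan] * 4, "B": [1.0, 2.0, 3.0, 4.0]},
            {"A": "continuous", "B": "continuous"},
        )
        with pytest.raises(ValueError, match="pre-screening"):
            gb.impute(table, "SI")

    def test_unknown_method_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown imputation"):
            gb.impute(small_cohort, "MICE")


class TestKNNImputing:
    def test_k1_duplicate_row_copies_value(self):
        # row 3 duplicates row 0 in all observed features
        table = toy_table(
            {
                "A": [1.0, 5.0, 9.0, 1.0],
                "B": [2.0, 6.0, 10.0, 2.0],
                "C": [3.0, 7.0, 11.0, np.nan],
            },
            {"A": "continuous", "B": "continuous", "C": "continuous"},
        )
        result = gb.impute(table, "KNN", {"k": 1})
        assert result.table.frame["C"].iloc[3] == pytest.approx(3.0)

    def test_categorical_filled_with_neighbor_mode(self, rng):
        n = 60
        group = rng.integers(0, 2, n)
        x = group * 10.0 + rng.normal(0, 0.1, n)
        codes = [None] + [int(g) for g in group[1:]]
        table = toy_table(
            {"A": x, "B": codes},
            {"A": "continuous", "B": "categorical"},
            labels=group,
        )
        result = gb.impute(table, "KNN", {"k": 5})
        assert result.table.frame["B"].iloc[0] == group[0]


class TestMethodInvariants:
    @pytest.mark.parametrize("method", ["SI", "KNN", "RF"])
    def test_observed_cells_unchanged_and_output_complete(self, method, catalog):
        cfg = gb.CohortConfig(
            n=150, seed=4, missing_rates={"X55": 0.15, "X4": 0.1, "X36": 0.1}
        )
        table = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
        params = {"RF": {"n_estimators": 15, "max_sweeps": 2}}.get(method)
        result = gb.impute(table, method, params)
        assert result.table.is_complete()
        observed = table.mask
        for var in table.candidate_columns:
            obs = observed[var]
            before = table.frame.loc[obs, var]
            after = result.table.frame.loc[obs, var]
            assert (before == after).all(), (method, var)

    def test_od_never_alters_retained_cells(self, catalog):
        cfg = gb.CohortConfig(n=150, seed=4)
        table = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
        result = gb.impute(table, "OD")
        out = result.table
        for var in out.candidate_columns:
            assert (out.frame[var] == table.frame.loc[out.frame.index, var]).all()

    def test_predictive_beats_mean_fill_on_class_structured_data(self, rng):
        """Masked cells with class-dependent means and an informative
        companion variable: KNN/RF recover class structure that a constant
        mean fill cannot."""
        n = 2000
        cls = rng.integers(0, 2, n)
        proxy = cls * 3.0 + rng.normal(0, 1, n)
        target = cls * 3.0 + rng.normal(0, 1, n)
        noise = rng.normal(0, 1, (n, 3))
        hidden = rng.random(n) < 0.1
        masked_target = np.where(hidden, np.nan, target)
        data = {"P": proxy, "T": masked_target}
        data.update({f"N{j}": noise[:, j] for j in range(3)})
        kinds = {c: "continuous" for c in data}
        complete_truth = target[hidden]
        table = toy_table(data, kinds, labels=cls)

        def rmse(method, params=None):
            filled = gb.impute(table, method, params).table
            est = filled.frame.loc[hidden, "T"].to_numpy(float)
            return float(np.sqrt(np.mean((est - complete_truth) ** 2)))

        si = rmse("SI")
        assert rmse("KNN") < si
        assert rmse("RF", {"n_estimators": 30, "max_sweeps": 2}) < si

    def test_imputer_fit_is_frozen_for_transform(self, catalog):
        """Transforming new data reuses training statistics (no refitting)."""
        cfg = gb.CohortConfig(n=300, seed=6)
        train = gb.inject_missingness(gb.sample_cohort(catalog, cfg), cfg)
        cfg2 = gb.CohortConfig(n=100, seed=60)
        test = gb.inject_missingness(gb.sample_cohort(catalog, cfg2), cfg2)
        imputer = gb.get_imputer("SI")
        imputer.fit(train)
        out = imputer.transform(test)
        train_mean = train.frame["X55"].dropna().mean()
        filled = out.frame.loc[test.frame["X55"].isna(), "X55"]
        assert np.allclose(filled, train_mean)


class TestOptimalDeletion:
    def test_complete_table_empty_plan(self, small_cohort):
        plan = gb.optimal_deletion(small_cohort)
        assert plan.rows_removed == () and plan.cols_removed == ()
        assert plan.objective_value == small_cohort.n * len(
            small_cohort.candidate_columns
        )

    def test_missing_confined_to_one_column_deletes_it(self):
        table = toy_table(
            {
                "A": [1.0, np.nan, np.nan, 4.0],
                "B": [1.0, 2.0, 3.0, 4.0],
                "C": [1.0, 2.0, 3.0, 4.0],
            },
            {"A": "continuous", "B": "continuous", "C": "continuous"},
        )
        plan = gb.optimal_deletion(table)
        assert plan.cols_removed == ("A",)
        assert plan.rows_removed == ()
        assert plan.objective_value == 8

    def test_single_missing_cell_table(self):
        table = toy_table({"A": [np.nan]}, {"A": "continuous"})
        with pytest.warns(UserWarning):
            plan = gb.optimal_deletion(table)
        assert plan.objective_value == 0

    def test_brute_force_single_missing_column(self):
        table = toy_table(
            {"A": [np.nan] * 3, "B": [1.0, 2.0, 3.0], "C": [4.0, 5.0, 6.0]},
            {"A": "continuous", "B": "continuous", "C": "continuous"},
        )
        plan = gb.brute_force_deletion(table)
        assert plan.cols_removed == ("A",)
        assert plan.retained_rows == 3

    def test_brute_force_dimension_cap(self, rng):
        table = random_masked_table(rng, n_rows=14, n_cols=3)
        with pytest.raises(ValueError, match="cap"):
            gb.brute_force_deletion(table, max_dim=12)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(30):
            table = random_masked_table(rng, rate=float(rng.uniform(0.1, 0.3)))
            fast = gb.optimal_deletion(table)
            brute = gb.brute_force_deletion(table)
            assert fast.objective_value == brute.objective_value
            assert (
                fast.objective_value == fast.retained_rows * fast.retained_cols
            )

    def test_greedy_fallback_never_beats_exact(self, rng):
        for _ in range(20):
            table = random_masked_table(rng, rate=0.2)
            greedy = gb.optimal_deletion(table, exact_limit=0)
            exact = gb.optimal_deletion(table)
            assert greedy.objective_value <= exact.objective_value

    def test_plan_yields_complete_submatrix(self, rng):
        table = random_masked_table(rng, n_rows=8, n_cols=5, rate=0.25)
        plan = gb.optimal_deletion(table)
        keep_rows = [i for i in range(8) if i not in plan.rows_removed]
        keep_cols = [c for c in table.candidate_columns if c not in plan.cols_removed]
        assert not table.frame.loc[keep_rows, keep_cols].isna().any().any()
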