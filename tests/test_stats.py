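"""Reliability statistics: ICC forms, absolute differences, observer study."""

import numpy as np
import pandas as pd
import pytest

from jawmotion.stats import (
    MeasurementTable, anova_mean_squares, icc, absolute_differences, observer_study,
)


def brute_force_icc(values: np.ndarray, model: str) -> float:
    """Independent oracle: explicit double-loop ANOVA sums over the grid."""
    n, k = values.shape
    grand = sum(values[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(values[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(values[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((values[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if model == "two_way_random_absolute":
        return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_perfect_agreement_is_exactly_one(self):
        t = MeasurementTable(np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]))
        assert icc(t, "two_way_random_absolute") == 1.0
        assert icc(t, "two_way_mixed_consistency") == 1.0

    def test_constant_offset_separates_the_two_forms(self):
        base = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        t = MeasurementTable(np.column_stack([base, base + 3.0]))
        assert icc(t, "two_way_mixed_consistency") == pytest.approx(1.0, abs=1e-12)
        assert icc(t, "two_way_random_absolute") < 1.0

    @pytest.mark.parametrize("model", ["two_way_random_absolute",
                                       "two_way_mixed_consistency"])
    def test_matches_brute_force_anova_on_random_tables(self, model):
        rng = np.random.default_rng(7)
        for _ in range(100):
            values = rng.normal(0, 2, size=(25, 2)) + rng.normal(0, 3, size=(25, 1))
            ours = icc(MeasurementTable(values), model)
            assert ours == pytest.approx(brute_force_icc(values, model), abs=1e-10)

    @pytest.mark.parametrize("model", ["two_way_random_absolute",
                                       "two_way_mixed_consistency"])
    def test_matches_pingouin(self, model):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        values = rng.normal(0, 1, size=(20, 3)) + rng.normal(0, 2, size=(20, 1))
        n, k = values.shape
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": values.ravel(),
        })
        res = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        typ = "ICC(A,1)" if model == "two_way_random_absolute" else "ICC(C,1)"
        ref = float(res.loc[res.Type == typ, "ICC"].iloc[0])
        assert icc(MeasurementTable(values), model) == pytest.approx(ref, abs=1e-8)

    def test_invariances(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, size=(15, 2)) + rng.normal(0, 2, size=(15, 1))
        for model in ("two_way_random_absolute", "two_way_mixed_consistency"):
            ref = icc(MeasurementTable(values), model)
            # shift all cells, rescale all cells
            assert icc(MeasurementTable(values + 7.0), model) == pytest.approx(ref, abs=1e-10)
            assert icc(MeasurementTable(values * 3.5), model) == pytest.approx(ref, abs=1e-10)
            assert ref <= 1.0
        # consistency form only: shift a single rater
        shifted = values.copy()
        shifted[:, 1] += 4.0
        assert icc(MeasurementTable(shifted), "two_way_mixed_consistency") == pytest.approx(
            icc(MeasurementTable(values), "two_way_mixed_consistency"), abs=1e-10)

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(MeasurementTable(np.full((5, 2), 3.0)), "two_way_random_absolute")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="model"):
            icc(MeasurementTable(np.eye(3)), "one_way")

    def test_table_shape_validation(self):
        with pytest.raises(ValueError):
            MeasurementTable(np.zeros((1, 2)))
        with pytest.raises(ValueError):
            MeasurementTable(np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestAbsoluteDifferences:
    def test_identical_raters(self):
        t = MeasurementTable(np.column_stack([[1.0, 2, 3], [1.0, 2, 3]]))
        assert absolute_differences(t) == (0.0, 0.0)

    def test_constant_difference(self):
        t = MeasurementTable(np.column_stack([[1.0, 2, 3], [2.0, 3, 4]]))
        mean, sd = absolute_differences(t)
        assert mean == pytest.approx(1.0) and sd == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        values = rng.normal(size=(30, 2))
        mean, sd = absolute_differences(MeasurementTable(values))
        d = np.abs(values[:, 0] - values[:, 1])
        assert mean == pytest.approx(d.mean(), abs=1e-12)
        assert sd == pytest.approx(d.std(ddof=1), abs=1e-12)

    def test_three_raters_rejected(self):
        with pytest.raises(ValueError, match="2 raters"):
            absolute_differences(MeasurementTable(np.zeros((4, 3)) + np.arange(4)[:, None]))


def _long(values, raters=("a", "b"), segment="maxilla", parameter="t_ap"):
    rows = []
    for i, row in enumerate(values):
        for r, v in zip(raters, row):
            rows.append({"case": f"c{i}", "rater": r, "segment": segment,
                         "parameter": parameter, "value": v})
    return pd.DataFrame(rows)


class TestObserverStudy:
    def test_identical_report_sets_give_icc_one_and_zero_differences(self, rng):
        base = rng.normal(0, 2, size=10)
        df = _long(np.column_stack([base, base]))
        out = observer_study(df)
        assert (out.icc == 1.0).all()
        assert (out.mean_abs_diff == 0.0).all()

    def test_single_rater_rejected(self, rng):
        df = _long(np.column_stack([rng.normal(size=5)]), raters=("a",))
        with pytest.raises(ValueError, match="2 raters"):
            observer_study(df)

    def test_mismatched_case_lists_rejected(self, rng):
        df = _long(np.column_stack([rng.normal(size=5), rng.normal(size=5)]))
        df = df.drop(df[(df.rater == "b") & (df.case == "c0")].index)
        df = pd.concat([df, pd.DataFrame([{"case": "c9", "rater": "b",
                                           "segment": "maxilla", "parameter": "t_ap",
                                           "value": 0.0}])])
        with pytest.raises(ValueError, match="different case lists"):
            observer_study(df)

    def test_one_row_per_segment_parameter(self, rng):
        df = pd.concat([
            _long(rng.normal(size=(6, 2)), segment="maxilla", parameter="t_ap"),
            _long(rng.normal(size=(6, 2)), segment="chin", parameter="pitch"),
        ])
        out = observer_study(df)
        assert len(out) == 2
        assert set(zip(out.segment, out.parameter)) == {("maxilla", "t_ap"),
                                                        ("chin", "pitch")}
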