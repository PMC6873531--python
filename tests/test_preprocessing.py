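"""Preprocessing: orientation, outlier rules, nonparanormal transform,
pairwise correlations and PSD repair."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from symptomnet import RatingMatrix
from symptomnet.preprocessing import (
    clean_scores,
    multivariate_outlier_removal,
    nearest_correlation_repair,
    nonparanormal_transform,
    orient_scores,
    pairwise_correlations,
    univariate_outlier_to_missing,
)
from symptomnet.preprocessing import nonparanormal_delta

from conftest import make_rating


class TestOrientScores:
    def test_reflection_with_bounds(self):
        data = make_rating(np.array([[5.0, 1.0], [np.nan, 2.0]]),
                           names=["rev", "ok"],
                           orientation={"rev": False, "ok": True},
                           bounds={"rev": (0, 21), "ok": (0, 10)})
        out = orient_scores(data)
        assert out.values.loc[0, "rev"] == 16.0
        assert np.isnan(out.values.loc[1, "rev"])  # missing stays missing
        assert out.values["ok"].tolist() == [1.0, 2.0]  # untouched
        assert out.orientation.all()

    def test_negation_without_bounds(self):
        data = make_rating(np.array([[3.0], [4.0]]), names=["rev"],
                           orientation={"rev": False})
        out = orient_scores(data)
        assert out.values["rev"].tolist() == [-3.0, -4.0]


class TestUnivariateOutliers:
    def test_single_extreme_value_replaced(self):
        col = np.zeros(100)
        col[-1] = 100.0
        other = np.linspace(0, 1, 100)
        data = make_rating(np.column_stack([col, other]))
        out, count = univariate_outlier_to_missing(data)
        assert count == 1
        assert np.isnan(out.values.iloc[-1, 0])

    def test_no_outliers(self):
        rng = np.random.default_rng(0)
        data = make_rating(rng.uniform(0, 1, size=(50, 3)))
        _, count = univariate_outlier_to_missing(data)
        assert count == 0

    def test_injected_outliers_recovered(self, default_cohort):
        _, _, data, record = default_cohort
        oriented = orient_scores(data)
        out, count = univariate_outlier_to_missing(oriented)
        assert count == len(record.univariate_outlier_cells)
        flagged = {(i, out.variable_names.index(name))
                   for entry in out.log if entry["step"] == "univariate_outliers"
                   for i, name in entry["cells"]}
        assert flagged == set(record.univariate_outlier_cells)

    def test_zero_sd_variable_warns(self):
        data = make_rating(np.column_stack([np.ones(20), np.arange(20.0)]))
        with pytest.warns(UserWarning, match="zero SD"):
            _, count = univariate_outlier_to_missing(data)
        assert count == 0


class TestMultivariateOutliers:
    def test_constructed_row_removed(self):
        rng = np.random.default_rng(1)
        p = 4
        X = rng.standard_normal((300, p))
        cutoff = stats.chi2.ppf(0.999, df=p)
        X[0] = np.sqrt(2 * cutoff / p)  # D^2 ~ 2*cutoff on identity covariance
        data = make_rating(X)
        _, removed = multivariate_outlier_removal(data, alpha=0.001)
        assert 0 in removed

    def test_alpha_zero_removes_nothing(self):
        rng = np.random.default_rng(2)
        data = make_rating(rng.standard_normal((100, 3)))
        out, removed = multivariate_outlier_removal(data, alpha=0.0)
        assert removed == []
        assert out.n == 100

    def test_injected_rows_among_removals(self, default_cohort):
        _, _, data, record = default_cohort
        oriented = orient_scores(data)
        step, _ = univariate_outlier_to_missing(oriented)
        _, removed = multivariate_outlier_removal(step, alpha=0.001)
        assert set(record.multivariate_outlier_rows) <= set(map(int, removed))


class TestNonparanormal:
    def test_delta_formula(self):
        # m = 714 gives the winsorisation level of the study-sized sample
        assert nonparanormal_delta(714) == pytest.approx(0.010648, abs=5e-5)

    def test_gaussian_data_nearly_unchanged(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(2000)
        data = make_rating(x[:, None])
        out = nonparanormal_transform(data)
        assert np.corrcoef(x, out.values.iloc[:, 0])[0, 1] > 0.99

    def test_monotone_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, size=(200, 1))
        a = nonparanormal_transform(make_rating(x))
        b = nonparanormal_transform(make_rating(np.exp(x)))
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy(),
                                   atol=1e-12)

    def test_monotone_in_ranks_and_missing_preserved(self):
        x = np.array([3.0, 1.0, np.nan, 2.0, 2.0, 10.0,
                      4.0, 5.0, 6.0, 7.0, 8.0, 9.0])[:, None]
        out = nonparanormal_transform(make_rating(np.repeat(x, 2, axis=1)))
        col = out.values.iloc[:, 0]
        assert np.isnan(col[2])
        assert col[1] < col[3] == col[4] < col[0] < col[5]

    def test_standardised(self):
        rng = np.random.default_rng(5)
        out = nonparanormal_transform(make_rating(rng.gamma(1.0, size=(500, 2))))
        assert out.values.mean().abs().max() < 1e-12
        assert np.allclose(out.values.std(ddof=1), 1.0)

    def test_constant_variable_errors(self):
        data = make_rating(np.column_stack([np.ones(30), np.arange(30.0)]),
                           names=["const", "ok"])
        with pytest.raises(ValueError, match="const"):
            nonparanormal_transform(data)


class TestPairwiseCorrelations:
    def test_hand_computed_with_missing_cell(self):
        vals = np.array([
            [1.0, 2.0, 1.5],
            [2.0, 1.0, 2.5],
            [3.0, 4.0, np.nan],
            [4.0, 3.0, 3.0],
            [5.0, 5.0, 4.0],
        ])
        data = make_rating(vals, names=["a", "b", "c"])
        est = pairwise_correlations(data, min_pairs=3)
        # oracle: plain Pearson on the complete pairs, computed directly
        def pearson(x, y):
            m = ~(np.isnan(x) | np.isnan(y))
            return np.corrcoef(x[m], y[m])[0, 1]
        for i, vi in enumerate(["a", "b", "c"]):
            for j, vj in enumerate(["a", "b", "c"]):
                assert est.corr.loc[vi, vj] == pytest.approx(
                    pearson(vals[:, i], vals[:, j]))
        assert est.pairwise_n.loc["a", "c"] == 4
        assert est.pairwise_n.loc["a", "b"] == 5
        assert est.effective_n == 5

    def test_pairwise_equals_listwise_without_missing(self):
        rng = np.random.default_rng(6)
        data = make_rating(rng.standard_normal((40, 4)))
        a = pairwise_correlations(data, method="pairwise")
        b = pairwise_correlations(data, method="listwise")
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_perfect_linear_relation(self):
        x = np.arange(20.0)
        data = make_rating(np.column_stack([x, 2 * x + 1]))
        est = pairwise_correlations(data)
        assert est.corr.iloc[0, 1] == pytest.approx(1.0)

    def test_too_few_pairs_errors(self):
        vals = np.full((12, 2), np.nan)
        vals[:, 0] = np.arange(12.0)
        vals[:5, 1] = np.arange(5.0)
        with pytest.raises(ValueError, match="complete observations"):
            pairwise_correlations(make_rating(vals))


class TestNearestCorrelationRepair:
    def test_psd_input_unchanged(self):
        A = np.array([[1.0, 0.5], [0.5, 1.0]])
        est = pairwise_correlations(make_rating(
            np.random.default_rng(0).standard_normal((30, 2))))
        est.corr = pd.DataFrame(A, index=est.corr.index, columns=est.corr.columns)
        out = nearest_correlation_repair(est)
        assert not out.repaired
        np.testing.assert_array_equal(out.matrix, A)

    def test_indefinite_repaired(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.9
        A[0, 2] = A[2, 0] = 0.9
        A[1, 2] = A[2, 1] = -0.9
        assert np.linalg.eigvalsh(A)[0] < 0
        est = pairwise_correlations(make_rating(
            np.random.default_rng(1).standard_normal((30, 3))))
        est.corr = pd.DataFrame(A, index=est.corr.index, columns=est.corr.columns)
        out = nearest_correlation_repair(est)
        assert out.repaired
        assert np.linalg.eigvalsh(out.matrix)[0] >= -1e-8
        np.testing.assert_allclose(np.diag(out.matrix), 1.0)
        # total movement bounded by |eigmin| * p
        bound = abs(np.linalg.eigvalsh(A)[0]) * 3
        assert out.max_repair_delta < bound


def test_pipeline_order_logged(default_cohort):
    _, _, data, _ = default_cohort
    clean = clean_scores(data)
    steps = [e["step"] for e in clean.log]
    assert steps == ["orient", "univariate_outliers", "multivariate_outliers"]


def test_transformed_correlations_approximate_latent(default_cohort):
    """Nonparanormal correlations of a 5000-person clean cohort track the
    latent correlation matrix."""
    from symptomnet import GeneratorConfig, build_block_precision, sample_cohort

    cfg = GeneratorConfig(seed=13, n_persons=5000, missing_rate=0.0,
                          n_univariate_outliers=0, n_multivariate_outliers=0,
                          age_effect=np.zeros(23), reverse_oriented=())
    model = build_block_precision(cfg)
    data = sample_cohort(model, cfg)
    out = nonparanormal_transform(data)
    emp = np.corrcoef(out.values.to_numpy(), rowvar=False)
    assert np.abs(emp - model.latent_correlation()).max() < 0.08
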