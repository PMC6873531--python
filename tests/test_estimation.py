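"""Network estimation: penalty path, glasso oracle equivalence, EBIC,
model selection, thresholding and covariate handling."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import pinvh

from symptomnet import (
    GeneratorConfig,
    PipelineConfig,
    RatingMatrix,
    build_block_precision,
    ebic_score,
    estimate_network,
    glasso_fit,
    lambda_path,
    sample_cohort,
    select_model,
    threshold_network,
)
from symptomnet.estimation import (
    NetworkModel,
    default_tau,
    drop_covariate_nodes,
    partial_corr_from_precision,
)
from symptomnet.preprocessing import CorrelationEstimate


def _corr_estimate(S, n=200):
    names = [f"V{i}" for i in range(S.shape[0])]
    df = pd.DataFrame(S, index=names, columns=names)
    pn = pd.DataFrame(np.full_like(S, n, dtype=int), index=names, columns=names)
    return CorrelationEstimate(corr=df, pairwise_n=pn, method="pairwise",
                               effective_n=n)


def _random_correlation(p, rng):
    A = rng.standard_normal((p, 2 * p))
    S = A @ A.T / (2 * p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestLambdaPath:
    def test_log_spacing(self):
        S = np.eye(2)
        S[0, 1] = S[1, 0] = 0.5
        path = lambda_path(S, n_lambda=3, min_ratio=0.01)
        np.testing.assert_allclose(path, [0.005, 0.05, 0.5])

    def test_identity_errors(self):
        with pytest.raises(ValueError):
            lambda_path(np.eye(4))

    def test_length_and_monotone(self):
        S = _random_correlation(6, np.random.default_rng(0))
        path = lambda_path(S, n_lambda=25)
        assert len(path) == 25
        assert np.all(np.diff(path) > 0)


class TestGlassoFit:
    def test_large_penalty_gives_empty_network(self):
        S = _random_correlation(5, np.random.default_rng(1))
        lam_max = lambda_path(S, n_lambda=2)[-1]
        prec = glasso_fit(S, lam_max * 1.001)
        off = prec - np.diag(np.diag(prec))
        assert np.abs(off).max() < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_zero_penalty_matches_inverse(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.integers(3, 11)
        S = _random_correlation(p, rng)
        prec = glasso_fit(S, 0.0)
        assert np.abs(prec - np.linalg.inv(S)).max() < 1e-5

    def test_tridiagonal_partial_correlations(self):
        theta = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        S = np.linalg.inv(theta)
        W = partial_corr_from_precision(glasso_fit(S, 0.0))
        assert W[0, 1] == pytest.approx(0.5, abs=1e-8)
        assert W[1, 2] == pytest.approx(0.5, abs=1e-8)
        assert W[0, 2] == pytest.approx(0.0, abs=1e-8)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(3), -0.1)


class TestEbicScore:
    def test_identity_case(self):
        assert ebic_score(np.eye(2), np.eye(2), n=100) == pytest.approx(200.0)

    def test_gamma_term_is_additive(self):
        rng = np.random.default_rng(2)
        S = _random_correlation(5, rng)
        prec = glasso_fit(S, 0.05)
        p = 5
        iu = np.triu_indices(p, k=1)
        E = np.count_nonzero(prec[iu])
        d = ebic_score(prec, S, n=300, gamma=0.5) - ebic_score(prec, S, n=300, gamma=0.0)
        assert d == pytest.approx(4 * E * 0.5 * np.log(p))

    def test_independent_likelihood_recomputation(self):
        rng = np.random.default_rng(3)
        S = _random_correlation(4, rng)
        prec = glasso_fit(S, 0.02)
        # oracle: eigenvalue-based log-likelihood, element-wise trace
        logdet = float(np.sum(np.log(np.linalg.eigvalsh(prec))))
        trace = float((S * prec).sum())
        E = np.count_nonzero(prec[np.triu_indices(4, k=1)])
        n, gamma = 250, 0.5
        expected = -n * (logdet - trace) + E * np.log(n) + 4 * E * gamma * np.log(4)
        assert ebic_score(prec, S, n=n, gamma=gamma) == pytest.approx(expected, abs=1e-8)

    def test_non_pd_precision_rejected(self):
        bad = np.diag([1.0, -1.0])
        with pytest.raises(ValueError):
            ebic_score(bad, np.eye(2), n=100)


class TestSelectModel:
    def test_single_lambda_path(self):
        S = _random_correlation(4, np.random.default_rng(4))
        est = _corr_estimate(S)
        model = select_model(est, path=[0.1])
        assert model.lambda_selected == pytest.approx(0.1)
        assert len(model.path) == 1

    def test_gamma_monotonicity(self):
        """A heavier EBIC penalty never selects a denser network."""
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(n_persons=300, block_sizes=(3, 3, 2), seed=5,
                              n_univariate_outliers=0, n_multivariate_outliers=0,
                              missing_rate=0.0, reverse_oriented=(),
                              age_effect=np.zeros(8))
        tm = build_block_precision(cfg)
        data = sample_cohort(tm, cfg)
        prev_edges = None
        for gamma in (0.0, 0.25, 0.5, 1.0):
            pc = PipelineConfig(gamma=gamma, threshold=False, include_age=False,
                                n_lambda=40, mahal_alpha=0.0)
            model = estimate_network(data, pc)
            if prev_edges is not None:
                assert model.edge_count <= prev_edges
            prev_edges = model.edge_count


class TestThreshold:
    def test_tau_formula(self):
        assert default_tau(24, 714) == pytest.approx(0.0887, abs=2e-4)

    def test_zero_tau_is_identity(self, toy_network):
        out = threshold_network(toy_network, tau=0.0)
        np.testing.assert_array_equal(out.adjacency, toy_network.adjacency)

    def test_small_edges_zeroed_large_retained(self, toy_network):
        out = threshold_network(toy_network, tau=0.15)
        assert out.weight("B", "C") == 0.0  # |0.1| < tau
        assert out.weight("A", "B") == pytest.approx(0.3)
        assert out.thresholded
        assert out.adjacency_unthresholded is not None


class TestCovariateDrop:
    def test_submodel_geometry(self):
        rng = np.random.default_rng(6)
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.2
        model = NetworkModel(nodes=list("ABCDE"), precision=np.eye(5) - W,
                             adjacency=W, lambda_selected=0.1, gamma=0.5,
                             covariate_nodes=["E"])
        sub = drop_covariate_nodes(model)
        assert sub.nodes == list("ABCD")
        assert sub.p == model.p - 1
        np.testing.assert_array_equal(sub.adjacency, W[:4, :4])

    def test_too_few_remaining_nodes(self):
        model = NetworkModel(nodes=list("ABC"), precision=np.eye(3),
                             adjacency=np.zeros((3, 3)), lambda_selected=0.1,
                             gamma=0.5, covariate_nodes=["C"])
        with pytest.raises(ValueError):
            drop_covariate_nodes(model)


class TestEstimateNetworkVariants:
    def test_unregularised_equals_pseudoinverse_partials(self, small_cohort):
        _, _, data = small_cohort
        pc = PipelineConfig(regularised=False, threshold=False)
        model, clean, transformed, est, full = estimate_network(
            data, pc, return_intermediates=True)
        expected = partial_corr_from_precision(pinvh(est.matrix))
        keep = [i for i, v in enumerate(est.nodes) if v != "age"]
        np.testing.assert_allclose(model.adjacency,
                                   expected[np.ix_(keep, keep)], atol=1e-10)

    def test_thresholded_edges_subset_of_unthresholded(self, small_cohort):
        _, _, data = small_cohort
        thr = estimate_network(data, PipelineConfig(threshold=True, n_lambda=40))
        raw = estimate_network(data, PipelineConfig(threshold=False, n_lambda=40))
        edges_thr = {(a, b) for a, b, _ in thr.edges()}
        edges_raw = {(a, b) for a, b, _ in raw.edges()}
        assert edges_thr <= edges_raw

    def test_age_absent_from_reported_network(self, fitted_small):
        assert "age" not in fitted_small.model.nodes
        assert "age" in fitted_small.full_model.nodes

    def test_tau_override_requires_threshold(self):
        with pytest.raises(ValueError):
            PipelineConfig(threshold=False, tau_override=0.1)
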