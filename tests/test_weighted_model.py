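"""Kernel weighting, weighted design, and penalized solvers."""

import numpy as np
import pytest

from conftest import make_weighting
from netgic import (
    DegenerateFitError,
    DegenerateWeightingError,
    InvalidBandwidthError,
    NetgicError,
)
from netgic.weighted_model import (
    CoefficientVector,
    ExpressionDataset,
    PenaltyConfig,
    build_weighted_design,
    estimate_noise_scale,
    fit_by_lqa,
    fit_weighted_elastic_net,
    gaussian_kernel_weights,
)


class TestGaussianKernelWeights:
    def test_zero_distance_gives_unit_weight(self):
        w = gaussian_kernel_weights([0.3, 0.7, 1.0], 0.3, h=0.5)
        assert w.raw_weights[0] == 1.0

    def test_unit_distance_unit_bandwidth(self):
        w = gaussian_kernel_weights([0.0, 1.0], 0.0, h=1.0)
        assert w.raw_weights[1] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_huge_bandwidth_reduces_to_uniform(self, rng):
        m = rng.uniform(-1, 1, 50)
        w = gaussian_kernel_weights(m, 0.0, h=1e6)
        assert np.allclose(w.raw_weights, 1.0, atol=1e-5)
        assert np.allclose(w.normalized_weights, 1.0, atol=1e-5)

    def test_normalized_weights_sum_to_retained_count(self, rng):
        m = rng.uniform(-3, 3, 40)
        w = gaussian_kernel_weights(m, float(m[4]), h=0.2)
        assert w.normalized_weights.sum() == pytest.approx(w.n_retained, abs=1e-9)

    @pytest.mark.parametrize("h", [0.0, -1.0, np.nan])
    def test_invalid_bandwidth_rejected(self, h):
        with pytest.raises(InvalidBandwidthError):
            gaussian_kernel_weights([0.0, 1.0], 0.0, h=h)

    def test_too_few_retained_samples(self):
        # everything except the target itself falls below the weight floor
        with pytest.raises(DegenerateWeightingError):
            gaussian_kernel_weights([0.0, 5.0, 6.0], 0.0, h=1e-3)


class TestBuildWeightedDesign:
    def test_unit_weights_are_identity(self, rng):
        y = rng.standard_normal(6)
        R = rng.standard_normal((6, 3))
        d = build_weighted_design(y, R, make_weighting(np.ones(6)))
        np.testing.assert_array_equal(d.y_star, y)
        np.testing.assert_array_equal(d.R_star, R)

    def test_quarter_weight_halves_row(self, rng):
        y = rng.standard_normal(4)
        R = rng.standard_normal((4, 2))
        weights = np.array([1.0, 0.25, 1.0, 1.0])
        d = build_weighted_design(y, R, make_weighting(weights))
        assert d.y_star[1] == pytest.approx(0.5 * y[1])
        np.testing.assert_allclose(d.R_star[1], 0.5 * R[1])

    def test_weighted_rss_identity_many_draws(self, rng):
        # (y*-R*b)'(y*-R*b) == sum_i w_i (y_i - r_i'b)^2 for random b, w
        n, p = 20, 4
        for _ in range(1000):
            y = rng.standard_normal(n)
            R = rng.standard_normal((n, p))
            w = rng.uniform(0.01, 2.0, n)
            beta = rng.standard_normal(p)
            d = build_weighted_design(y, R, make_weighting(w))
            lhs = np.sum((d.y_star - d.R_star @ beta) ** 2)
            rhs = np.sum(w * (y - R @ beta) ** 2)
            assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_shape_mismatch(self, rng):
        with pytest.raises(NetgicError):
            build_weighted_design(rng.standard_normal(5),
                                  rng.standard_normal((4, 2)),
                                  make_weighting(np.ones(5)))


class TestFitWeightedElasticNet:
    def test_lam_zero_equals_weighted_least_squares(self, instance_factory):
        y, R, w, d = instance_factory(n=40, p=5)
        fit = fit_weighted_elastic_net(d, PenaltyConfig(lam=0.0, pi=0.5))
        oracle = np.linalg.solve(d.R_star.T @ d.R_star, d.R_star.T @ d.y_star)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-8)

    def test_full_shrinkage_threshold(self, instance_factory):
        y, R, w, d = instance_factory()
        for pi in (0.3, 1.0):
            lam = np.max(np.abs(d.R_star.T @ d.y_star)) / pi
            fit = fit_weighted_elastic_net(d, PenaltyConfig(lam=lam * 1.0001, pi=pi))
            assert np.all(fit.beta == 0.0)

    def test_univariate_soft_threshold_closed_form(self, rng):
        # single predictor with ||r*||^2=1: b = sign(z) max(|z|-lam*pi,0)/(1+lam(1-pi))
        n = 25
        r = rng.standard_normal(n)
        r /= np.linalg.norm(r)
        y = 1.7 * r + 0.1 * rng.standard_normal(n)
        d = build_weighted_design(y, r[:, None], make_weighting(np.ones(n)))
        z = float(r @ d.y_star)
        for lam, pi in [(0.5, 1.0), (0.8, 0.4), (3.0, 0.9)]:
            fit = fit_weighted_elastic_net(d, PenaltyConfig(lam=lam, pi=pi))
            expect = np.sign(z) * max(abs(z) - lam * pi, 0.0) / (1.0 + lam * (1 - pi))
            assert fit.beta[0] == pytest.approx(expect, abs=1e-6)

    def test_monotone_shrinkage_along_lambda_grid(self, instance_factory):
        y, R, w, d = instance_factory(n=50, p=8)
        lam_max = np.max(np.abs(d.R_star.T @ d.y_star)) / 0.5
        lams = np.geomspace(lam_max, 1e-3 * lam_max, 30)
        dfs = [fit_weighted_elastic_net(d, PenaltyConfig(lam=l, pi=0.5)).df
               for l in lams]
        assert all(a <= b for a, b in zip(dfs, dfs[1:]))

    def test_huge_bandwidth_reduces_to_unweighted_fit(self, rng):
        n, p = 60, 6
        R = rng.standard_normal((n, p))
        y = R @ rng.standard_normal(p) + rng.standard_normal(n)
        m = rng.uniform(-1, 1, n)
        w = gaussian_kernel_weights(m, 0.0, h=1e9)
        d_w = build_weighted_design(y, R, w)
        d_u = build_weighted_design(y, R, make_weighting(np.ones(n)))
        pen = PenaltyConfig(lam=1.5, pi=0.7)
        np.testing.assert_allclose(fit_weighted_elastic_net(d_w, pen).beta,
                                   fit_weighted_elastic_net(d_u, pen).beta,
                                   atol=1e-6)


class TestFitByLQA:
    def test_agrees_with_coordinate_descent(self, rng):
        # independent solver cross-check on 50 random instances
        for k in range(50):
            n, p = 100, 10
            R = rng.standard_normal((n, p))
            beta_true = np.zeros(p)
            beta_true[:3] = rng.uniform(0.5, 2.0, 3)
            y = R @ beta_true + 0.3 * rng.standard_normal(n)
            d = build_weighted_design(y, R, make_weighting(np.ones(n)))
            pen = PenaltyConfig(lam=float(rng.uniform(0.5, 10.0)),
                                pi=float(rng.uniform(0.2, 1.0)))
            cd = fit_weighted_elastic_net(d, pen)
            init = CoefficientVector(
                beta=np.linalg.solve(d.R_star.T @ d.R_star + 1e-6 * np.eye(p),
                                     d.R_star.T @ d.y_star))
            lqa = fit_by_lqa(d, pen, init)
            np.testing.assert_allclose(lqa.beta, cd.beta, atol=1e-4)

    def test_pure_ridge_single_step(self, instance_factory):
        y, R, w, d = instance_factory(n=40, p=5)
        lam = 2.5
        init = CoefficientVector(beta=np.ones(5))
        fit = fit_by_lqa(d, PenaltyConfig(lam=lam, pi=0.0), init)
        oracle = np.linalg.solve(d.R_star.T @ d.R_star + lam * np.eye(5),
                                 d.R_star.T @ d.y_star)
        np.testing.assert_allclose(fit.beta, oracle, atol=1e-7)

    def test_zero_init_stays_zero(self, instance_factory):
        y, R, w, d = instance_factory()
        fit = fit_by_lqa(d, PenaltyConfig(lam=1.0, pi=0.5),
                         CoefficientVector(beta=np.zeros(5), active_set=np.array([], int)))
        assert np.all(fit.beta == 0.0)


class TestEstimateNoiseScale:
    def test_hand_computed_variance(self):
        # residuals (1,-1,1,-1,1,-1), 2 active coefficients, n'=6 -> 6/4
        R = np.column_stack([np.ones(6), np.arange(6.0)])
        beta = CoefficientVector(beta=np.array([0.5, 1.0]))
        resid = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = R @ beta.beta + resid
        d = build_weighted_design(y, R, make_weighting(np.ones(6)))
        s = estimate_noise_scale(d, beta)
        assert s.sigma2 == pytest.approx(1.5)
        np.testing.assert_allclose(s.per_sample, 1.5)

    def test_perfect_interpolation_is_degenerate(self):
        R = np.column_stack([np.ones(5), np.arange(5.0)])
        beta = CoefficientVector(beta=np.array([2.0, -1.0]))
        y = R @ beta.beta
        d = build_weighted_design(y, R, make_weighting(np.ones(5)))
        with pytest.raises(DegenerateFitError):
            estimate_noise_scale(d, beta)

    def test_no_residual_degrees_of_freedom(self, rng):
        R = rng.standard_normal((3, 3))
        y = rng.standard_normal(3)
        d = build_weighted_design(y, R, make_weighting(np.ones(3)))
        with pytest.raises(DegenerateFitError):
            estimate_noise_scale(d, CoefficientVector(beta=np.ones(3)))

    def test_scale_equivariance(self, instance_factory):
        y, R, w, d = instance_factory(n=30, p=4)
        beta = CoefficientVector(beta=np.zeros(4), active_set=np.array([], int))
        s1 = estimate_noise_scale(d, beta)
        d2 = type(d)(y_star=2.0 * d.y_star, R_star=2.0 * d.R_star, weights=d.weights)
        s2 = estimate_noise_scale(d2, beta)
        assert s2.sigma2 == pytest.approx(4.0 * s1.sigma2, rel=1e-12)


class TestExpressionDataset:
    def test_target_column_excluded_from_regulators(self, rng):
        vals = rng.standard_normal((10, 4))
        ds = ExpressionDataset(vals, list("ABCD"), [f"s{i}" for i in range(10)])
        y, R, reg_ids, _ = ds.regression_view("B")
        assert reg_ids == ["A", "C", "D"]
        assert R.shape == (10, 3)
        np.testing.assert_allclose(y, ds.values[:, 1])

    def test_rescale_recovers_original_scale_coefficients(self, rng):
        n = 200
        x = rng.standard_normal(n) * 3.0 + 1.0
        y = 2.0 * x + 0.01 * rng.standard_normal(n)
        filler = rng.standard_normal(n)
        ds = ExpressionDataset(np.column_stack([y, x, filler]),
                               ["y", "x", "z"], [f"s{i}" for i in range(n)])
        ys, Rs, _, rescale = ds.regression_view("y")
        beta_std, *_ = np.linalg.lstsq(Rs, ys, rcond=None)
        beta_orig = beta_std * rescale
        assert beta_orig[0] == pytest.approx(2.0, rel=1e-3)

    def test_duplicate_gene_ids_rejected(self, rng):
        with pytest.raises(NetgicError):
            ExpressionDataset(rng.standard_normal((5, 2)), ["A", "A"],
                              [f"s{i}" for i in range(5)])

    def test_missing_values_rejected(self, rng):
        vals = rng.standard_normal((5, 2))
        vals[2, 1] = np.nan
        with pytest.raises(NetgicError, match="s2"):
            ExpressionDataset(vals, ["A", "B"], [f"s{i}" for i in range(5)])
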