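"""Bayesian P-spline fit: decomposition correctness, λ posterior, prediction."""

import warnings

import numpy as np
import pytest

from plumespline.basis import BasisSpec, build_tensor_design
from plumespline.data import MonitoringDataset
from plumespline.model import (
    ModelSizeError,
    NIGPrior,
    default_lambda_grid,
    effective_df,
    fit,
    lambda_posterior,
    model_average_predict,
    precompute,
    predict,
    select_map,
)
from plumespline.penalty import build_difference_penalty

from conftest import (
    dense_log_posterior,
    dense_profile,
    make_data,
    mid_targets,
    small_problem,
    smooth_signal,
)


class TestFastPathEquivalence:
    @pytest.mark.parametrize("seed,order", [(0, 1), (1, 2), (2, 1)])
    def test_matches_dense_route(self, seed, order):
        data, spec, design, pen = small_problem(seed, order=order)
        ctx = precompute(design, pen, data.y)
        for lam in (0.01, 1.0, 100.0):
            alpha_d, rss_pen_d, rss_d, edf_d, _ = dense_profile(
                design, pen, data.y, lam
            )
            alpha_f = ctx.coefficients(lam)
            assert np.abs(alpha_f - alpha_d).max() <= 1e-8 * max(
                1.0, np.abs(alpha_d).max()
            )
            assert float(ctx.rss_penalized(np.asarray(lam))) == pytest.approx(
                rss_pen_d, rel=1e-8
            )
            assert float(ctx.rss(np.asarray(lam))) == pytest.approx(rss_d, rel=1e-8)
            assert float(ctx.edf(np.asarray(lam))) == pytest.approx(edf_d, rel=1e-8)

    def test_log_posterior_matches_dense_null_space_formulation(self):
        data, spec, design, pen = small_problem(7, sizes=(3, 3, 3), n=50)
        ctx = precompute(design, pen, data.y)
        prior = NIGPrior()
        lams = np.logspace(-4, 4, 9)
        fast = ctx.log_posterior(lams, prior)
        dense = dense_log_posterior(design, pen, data.y, prior, lams)
        # both defined up to one common additive constant
        assert np.abs((fast - fast[0]) - (dense - dense[0])).max() < 1e-8

    def test_logdet_matches_dense_up_to_constant(self):
        data, spec, design, pen = small_problem(11, sizes=(4, 3, 3), n=90, order=2)
        ctx = precompute(design, pen, data.y)
        lams = np.array([1e-3, 1.0, 1e3])
        fast = ctx.logdet_gen(lams)
        dense = np.array(
            [dense_profile(design, pen, data.y, l)[4] for l in lams]
        )
        assert np.abs((fast - fast[0]) - (dense - dense[0])).max() < 1e-8

    def test_profile_never_touches_dense_eig_after_precompute(self, monkeypatch):
        data, spec, design, pen = small_problem(3)
        ctx = precompute(design, pen, data.y)
        calls = {"n": 0}
        orig = np.linalg.eigh

        def counting(*a, **k):
            calls["n"] += 1
            return orig(*a, **k)

        monkeypatch.setattr(np.linalg, "eigh", counting)
        grid = np.logspace(-6, 8, 100)
        lambda_posterior(ctx, NIGPrior(), grid)
        ctx.edf(grid)
        ctx.rss(grid)
        assert calls["n"] == 0


class TestLimits:
    def test_edf_limits(self):
        data, spec, design, pen = small_problem(4)
        ctx = precompute(design, pen, data.y)
        assert effective_df(ctx, 1e14) == pytest.approx(pen.null_dim, abs=1e-6)
        assert effective_df(ctx, 0.0) == pytest.approx(ctx.rank_b, abs=1e-8)
        with pytest.raises(ValueError):
            effective_df(ctx, -1.0)

    def test_monotone_profiles(self):
        data, spec, design, pen = small_problem(5)
        ctx = precompute(design, pen, data.y)
        grid = np.logspace(-6, 8, 50)
        rss = ctx.rss(grid)
        edf = ctx.edf(grid)
        assert np.all(np.diff(rss) >= -1e-8 * rss[0] - 1e-12)
        assert np.all(np.diff(edf) <= 1e-10)

    def test_edf_decreasing_matches_dense_trace(self):
        data, spec, design, pen = small_problem(6, sizes=(4, 3, 3), n=100)
        ctx = precompute(design, pen, data.y)
        grid = np.logspace(-4, 6, 50)
        fast = ctx.edf(grid)
        dense = np.array(
            [dense_profile(design, pen, data.y, l)[3] for l in grid]
        )
        assert np.allclose(fast, dense, rtol=1e-8)
        assert np.all(np.diff(fast) < 0)

    def test_interpolation_limit_recovers_spline_truth(self):
        """Noise-free data from the span are reproduced as λ → 0."""
        rng = np.random.default_rng(8)
        data = make_data(rng, n=400)
        spec = BasisSpec.from_data(data, (4, 4, 3))
        design = build_tensor_design(data, spec)
        pen = build_difference_penalty(spec, order=1)
        alpha_true = rng.normal(size=design.m)
        y = design.B @ alpha_true
        ctx = precompute(design, pen, y)
        pred = design.B @ ctx.coefficients(0.0)
        assert np.abs(pred - y).max() < 1e-8

    def test_ridge_limit_converges_to_null_space_formulation(self):
        """A vanishing ridge on the prior precision recovers the rank-based kernel."""
        data, spec, design, pen = small_problem(9, sizes=(3, 3, 3), n=60)
        prior = NIGPrior()
        lams = np.logspace(-2, 4, 13)
        ctx = precompute(design, pen, data.y)
        ref = ctx.log_posterior(lams, prior)
        ref = ref - ref.max()

        B = design.B.toarray()
        P = pen.DtD.toarray()
        C = B.T @ B
        y = data.y
        p_eig = np.clip(np.linalg.eigvalsh(P), 0.0, None)
        p_eig[p_eig < 1e-10 * p_eig.max()] = 0.0  # exact null directions
        diffs = []
        for eps in (1e-2, 1e-4, 1e-6, 1e-10):
            vals = []
            for lam in lams:
                A = C + lam * P + eps * np.eye(pen.m)
                rss = float(y @ y - y @ B @ np.linalg.solve(A, B.T @ y))
                # |λP + εI| from the spectrum of P (exact, well conditioned)
                logdet_k = float(np.sum(np.log(lam * p_eig + eps)))
                vals.append(
                    0.5 * logdet_k
                    - 0.5 * np.linalg.slogdet(A)[1]
                    - (prior.a + 0.5 * len(y)) * np.log(2 * prior.b + rss)
                )
            vals = np.asarray(vals)
            vals = vals - vals.max()
            diffs.append(np.abs(vals - ref).max())
        assert all(a >= b for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < 1e-6


class TestGuardrailsAndErrors:
    def test_refuses_oversized_coefficient_space(self):
        rng = np.random.default_rng(10)
        data = make_data(rng, n=40)
        spec = BasisSpec.from_data(data, (25, 25, 25))
        design_m = spec.m
        assert design_m == 15_625
        design = build_tensor_design(data, spec)
        pen = build_difference_penalty(spec, order=1)
        with pytest.raises(ModelSizeError) as exc:
            precompute(design, pen, data.y)
        assert exc.value.m == 15_625
        assert "15625" in str(exc.value)

    def test_unidentified_null_space_errors(self):
        """Too few observations to pin the order-2 null space (dim 8)."""
        rng = np.random.default_rng(11)
        data = make_data(rng, n=5)
        spec = BasisSpec.from_data(data, (4, 4, 3))
        design = build_tensor_design(data, spec)
        pen = build_difference_penalty(spec, order=2)
        with pytest.raises(np.linalg.LinAlgError, match="direction"):
            precompute(design, pen, data.y)

    def test_posterior_finite_everywhere(self):
        data, spec, design, pen = small_problem(12, n=30)
        ctx = precompute(design, pen, data.y)
        lp = ctx.log_posterior(default_lambda_grid(), NIGPrior())
        assert np.all(np.isfinite(lp))

    def test_invalid_lambda_rejected(self):
        data, spec, design, pen = small_problem(13, n=30)
        ctx = precompute(design, pen, data.y)
        with pytest.raises(ValueError):
            ctx.log_posterior(np.array([0.0]), NIGPrior())


class TestSelection:
    def test_interior_map_on_unimodal_profile(self):
        data, spec, design, pen = small_problem(14)
        ctx = precompute(design, pen, data.y)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            lam, post = select_map(ctx, NIGPrior(), default_lambda_grid())
        assert 0 < post.map_index < len(post.grid) - 1
        assert post.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert post.log_posterior[post.map_index] == post.log_posterior.max()

    def test_single_point_grid_warns_boundary(self):
        data, spec, design, pen = small_problem(15, n=60)
        ctx = precompute(design, pen, data.y)
        with pytest.warns(UserWarning, match="boundary"):
            lam, _ = select_map(ctx, NIGPrior(), np.array([1.0]))
        assert lam == 1.0

    def test_map_within_central_mass(self):
        """The MAP sits inside the central 90% of the posterior mass."""
        data, spec, design, pen = small_problem(16, n=300)
        ctx = precompute(design, pen, data.y)
        post = lambda_posterior(ctx, NIGPrior(), default_lambda_grid())
        cdf = np.cumsum(post.weights)
        assert 0.05 < cdf[post.map_index] or post.weights[post.map_index] > 0.9
        assert cdf[post.map_index] - post.weights[post.map_index] < 0.95


class TestPrediction:
    def test_level_zero_degenerate_interval(self):
        data, spec, design, pen = small_problem(17)
        ctx = precompute(design, pen, data.y)
        pts = mid_targets(spec, 1)
        grid = predict(ctx, 1.0, pts, level=0.0)
        assert grid.lower[0] == grid.mean[0] == grid.upper[0]

    def test_bounds_bracket_mean(self):
        data, spec, design, pen = small_problem(18)
        ctx = precompute(design, pen, data.y)
        pts = mid_targets(spec, 15)
        grid = predict(ctx, 0.5, pts, level=0.95)
        assert np.all(grid.lower <= grid.mean + 1e-12)
        assert np.all(grid.mean <= grid.upper + 1e-12)

    def test_extrapolation_requires_flag(self):
        data, spec, design, pen = small_problem(19)
        ctx = precompute(design, pen, data.y)
        s1_out = spec.domain_s1[1] + 1.0
        mid = mid_targets(spec, 1)
        with pytest.raises(Exception, match="domain"):
            predict(ctx, 1.0, ([s1_out], mid[1], mid[2]))
        predict(ctx, 1.0, ([s1_out], mid[1], mid[2]), extrapolate=True)

    def test_degenerate_weight_grid_equals_single_lambda(self):
        data, spec, design, pen = small_problem(20)
        ctx = precompute(design, pen, data.y)
        pts = mid_targets(spec, 4)
        single = predict(ctx, 2.0, pts, level=0.9)
        avg = model_average_predict(ctx, NIGPrior(), np.array([2.0]), pts, level=0.9)
        assert np.allclose(avg.mean, single.mean, atol=1e-10)
        assert np.allclose(avg.lower, single.lower, atol=1e-6)
        assert np.allclose(avg.upper, single.upper, atol=1e-6)

    def test_mixture_interval_at_least_as_wide_as_map(self):
        """With a concentrated λ posterior, averaging over λ widens intervals."""
        data, spec, design, pen = small_problem(21, n=800)
        ctx = precompute(design, pen, data.y)
        prior = NIGPrior()
        grid = default_lambda_grid()
        post = lambda_posterior(ctx, prior, grid)
        pts = mid_targets(spec, 10)
        mix = model_average_predict(ctx, prior, grid, pts, level=0.95)
        single = predict(ctx, post.map_lambda, pts, level=0.95, prior=prior)
        width_mix = mix.upper - mix.lower
        width_map = single.upper - single.lower
        assert np.all(width_mix >= width_map * (1 - 1e-6))

    def test_back_transform_monotone(self):
        rng = np.random.default_rng(22)
        raw = rng.uniform(0.0, 30.0, 150)
        data = make_data(rng, n=150)
        data = MonitoringDataset.from_raw(
            well=data.well, s1=data.s1, s2=data.s2, t=data.t, raw=raw
        )
        res = fit(data, n_basis=(4, 4, 3), selector="map")
        pts = mid_targets(res.ctx.design.spec, 1)
        tr = res.predict(pts, level=0.9, back_transform=True)
        un = res.predict(pts, level=0.9, back_transform=False)
        assert tr.mean[0] == pytest.approx(np.expm1(un.mean[0]), rel=1e-10)
        assert tr.lower[0] <= tr.mean[0] <= tr.upper[0]


class TestFitResult:
    def test_posterior_parameter_invariants(self):
        rng = np.random.default_rng(23)
        data = make_data(rng, n=100)
        res = fit(data, n_basis=(4, 4, 3), selector="map")
        assert res.a_n == pytest.approx(res.prior.a + data.n / 2)
        assert res.b_n(res.selected_lambda) >= res.prior.b
        summary = res.summary()
        assert summary["selected_lambda"] == res.selected_lambda
        assert len(summary["log_posterior"]) == len(res.posterior.grid)

    def test_classical_selector_wiring(self):
        rng = np.random.default_rng(24)
        data = make_data(rng, n=150)
        res_map = fit(data, n_basis=(4, 4, 3), selector="map")
        res_aicc = fit(data, n_basis=(4, 4, 3), selector="aicc")
        assert res_aicc.selected_lambda in res_aicc.posterior.grid
        assert res_map.selector == "map" and res_aicc.selector == "aicc"
        with pytest.raises(ValueError):
            fit(data, n_basis=(4, 4, 3), selector="nope")
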