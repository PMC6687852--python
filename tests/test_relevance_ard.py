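"""Tests of the linear-kernel GP relevance machinery."""

import numpy as np
import pytest

from bvrlf.relevance_ard import (
    RelevanceDataset, ablation_relevance, contribution_signs, fit_ard, _nlml,
)


def make_linear_problem(weights, n=200, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 2.0, size=(n, len(weights)))
    y = x @ np.asarray(weights, dtype=float) + rng.normal(0, noise, n)
    return RelevanceDataset.from_raw(x, y)


class TestFitArd:
    def test_single_relevant_feature_concentrates(self):
        # centering removes the intercept the bias-free linear kernel
        # cannot represent, isolating the machinery's recovery behaviour
        data = make_linear_problem([3, 0, 0, 0, 0, 0, 0, 0], noise=0.1)
        fit = fit_ard(data, seed=1, center=True)
        assert fit.relevance[0] > 0.9
        assert abs(fit.relevance.sum() - 1.0) < 1e-9
        assert fit.signs[0] == 1

    def test_pure_noise_does_not_concentrate(self):
        # without signal the per-feature explained share (noise variance in
        # the denominator) must stay small and the noise term must dominate
        concentrated = 0
        noise_dominated = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 2, size=(200, 8))
            y = rng.normal(0, 1, 200)
            fit = fit_ard(RelevanceDataset.from_raw(x, y), seed=seed)
            if fit.explained_share.max() >= 0.5:
                concentrated += 1
            var_contrib = np.sum(fit.sigma2_d * np.var(x, axis=0))
            if fit.sigma2_r > var_contrib:
                noise_dominated += 1
        assert concentrated == 0
        assert noise_dominated >= 4

    def test_row_duplication_leaves_relevance_unchanged(self):
        data = make_linear_problem([2, -1, 0, 0], n=120, seed=3)
        doubled = RelevanceDataset(np.vstack([data.x, data.x]),
                                   np.concatenate([data.y, data.y]))
        a = fit_ard(data, seed=2)
        b = fit_ard(doubled, seed=2)
        assert np.allclose(a.relevance, b.relevance, atol=1e-3)

    def test_requires_more_samples_than_features(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 2, size=(6, 8))
        with pytest.raises(ValueError):
            fit_ard(RelevanceDataset.from_raw(x, rng.normal(size=6)))

    def test_rank_order_follows_effect_size(self):
        # |w_i| * SD(x_i) orders the true influence; check recovery across
        # seeded replicates
        weights = [3.0, -2.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        hits = 0
        for seed in range(10):
            data = make_linear_problem(weights, noise=0.3, seed=seed)
            fit = fit_ard(data, seed=seed)
            top3 = np.argsort(fit.relevance)[::-1][:3]
            hits += list(top3) == [0, 1, 2]
        assert hits >= 9


class TestSigns:
    def test_signs_match_ols_oracle(self):
        data = make_linear_problem([-1, 1, 0.5, -0.5], n=150, noise=0.05,
                                   seed=5)
        fit = fit_ard(data, seed=5)
        beta = np.linalg.lstsq(
            np.column_stack([data.x, np.ones(len(data.y))]), data.y,
            rcond=None)[0][:4]
        assert np.all(fit.signs[:2] == np.sign(beta)[:2].astype(int))
        assert fit.signs[0] == -1
        assert fit.signs[1] == 1

    def test_flipping_output_flips_every_sign(self):
        data = make_linear_problem([2, -1, 0.5, -0.25], n=120, seed=6)
        flipped = RelevanceDataset(data.x, -data.y)
        a = fit_ard(data, seed=1)
        b = fit_ard(flipped, seed=1)
        nonzero = a.signs != 0
        assert np.all(a.signs[nonzero] == -b.signs[nonzero])


class TestRidgeEquivalence:
    def test_gp_predictive_mean_equals_ridge_regression(self):
        # linear-kernel GP mean f = X S X^T (X S X^T + s2 I)^-1 y equals
        # ridge with per-feature penalty s2 S^-1 (Woodbury identity)
        rng = np.random.default_rng(7)
        x = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        s_diag = np.array([0.5, 1.0, 2.0, 0.1])
        s2 = 0.3
        k = (x * s_diag) @ x.T
        gp_mean = k @ np.linalg.solve(k + s2 * np.eye(30), y)
        w_ridge = np.linalg.solve(x.T @ x + s2 * np.diag(1.0 / s_diag),
                                  x.T @ y)
        assert np.allclose(gp_mean, x @ w_ridge, atol=1e-6)

    def test_nlml_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        h0 = np.array([0.2, -0.3, 0.1, -0.5])
        f0, g = _nlml(h0, x, y)
        for i in range(4):
            e = np.zeros(4)
            e[i] = 1e-6
            f1, _ = _nlml(h0 + e, x, y)
            assert (f1 - f0) / 1e-6 == pytest.approx(g[i], rel=1e-3, abs=1e-6)


class TestAblation:
    def test_shapes_and_normalization(self):
        data = make_linear_problem([2, -1, 0, 0, 0.5], n=120, seed=9)
        tables = ablation_relevance(data, n_folds=5, seed=2)
        assert set(tables) == set(range(5))
        for i, res in tables.items():
            assert res.relevance.shape == (4,)
            assert res.relevance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_removing_inert_feature_preserves_relevances(self):
        data = make_linear_problem([3, -2, 0, 0], n=200, noise=0.2, seed=10)
        full = fit_ard(data, n_folds=5, seed=3, center=True)
        tables = ablation_relevance(data, n_folds=5, seed=3, center=True)
        reduced = tables[3].relevance  # feature 3 is inert
        renorm = full.relevance[:3] / full.relevance[:3].sum()
        assert np.allclose(reduced, renorm, atol=0.05)

    def test_removing_the_sole_relevant_feature_inflates_noise(self):
        data = make_linear_problem([3, 0, 0, 0], n=150, noise=0.1, seed=11)
        full = fit_ard(data, n_folds=5, seed=4, center=True)
        tables = ablation_relevance(data, n_folds=5, seed=4, center=True)
        assert tables[0].sigma2_r > 5 * full.sigma2_r
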