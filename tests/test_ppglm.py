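"""Design assembly, likelihood/gradient, fitting, and phase introspection."""

import numpy as np
import pytest

from spikefield import (
    FeatureBlock,
    FeatureMatrix,
    PPGLMModel,
    assemble_design,
    conditional_intensity,
    fit_ppglm,
    penalized_nll_and_gradient,
    preferred_phase,
)
from spikefield import _solver
from spikefield.core import DELTA_S


def random_instance(seed, T=400, p=3, rate_hz=40.0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, p))
    y = (rng.random(T) < rate_hz * DELTA_S).astype(float)
    return X, y


class TestAssembleDesign:
    def test_self_scored_columns_standardized(self):
        rng = np.random.default_rng(0)
        blk = FeatureBlock(rng.normal(5, 3, size=(500, 4)),
                           [f"c{i}" for i in range(4)], "kin")
        fm = assemble_design([blk])
        assert np.allclose(fm.X.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(fm.X.std(axis=0), 1.0, atol=1e-9)

    def test_constant_column_excluded(self, caplog):
        blk = FeatureBlock(np.ones((100, 1)), ["const"], "kin")
        fm = assemble_design([blk])
        assert fm.p == 0

    def test_training_stats_applied_to_test_block(self):
        rng = np.random.default_rng(1)
        train = FeatureBlock(rng.normal(0, 1, (400, 2)), ["a", "b"], "kin")
        test = FeatureBlock(rng.normal(2, 3, (300, 2)), ["a", "b"], "kin")
        fm_train = assemble_design([train])
        fm_test = assemble_design([test], stats_from=fm_train)
        fm_test_own = assemble_design([test])
        # shifted/rescaled test data: training-stats scoring must differ
        assert not np.allclose(fm_test.X, fm_test_own.X, atol=1e-3)
        assert abs(fm_test.X.mean()) > 0.3


class TestConditionalIntensity:
    def test_closed_forms(self):
        X = FeatureMatrix(np.zeros((10, 0)), [], [])
        m0 = PPGLMModel(mu=0.0, A=np.empty(0), alpha=0.0)
        assert np.allclose(conditional_intensity(m0, X), 1.0)
        m10 = PPGLMModel(mu=np.log(10.0), A=np.empty(0), alpha=0.0)
        assert np.allclose(conditional_intensity(m10, X), 10.0)

    def test_row_loop_oracle(self):
        rng = np.random.default_rng(2)
        Xv = rng.standard_normal((50, 3))
        fm = FeatureMatrix(Xv, ["a", "b", "c"], ["kin"] * 3,
                           np.zeros(3), np.ones(3))
        model = PPGLMModel(mu=-0.5, A=np.array([0.2, -0.1, 0.4]), alpha=0.0,
                           labels=["a", "b", "c"], groups=["kin"] * 3)
        lam = conditional_intensity(model, fm)
        for t in range(50):
            expected = np.exp(-0.5 + model.A @ Xv[t])
            assert abs(lam[t] - expected) < 1e-12 * max(1, expected)


class TestLikelihood:
    def test_no_spikes_closed_form(self):
        X, _ = random_instance(0, T=100, p=2)
        y = np.zeros(100)
        mu = -1.3
        nll, grad = penalized_nll_and_gradient(mu, np.zeros(2), X, y, 0.0)
        assert abs(nll - np.exp(mu) * DELTA_S) < 1e-12
        assert abs(grad[0] - np.exp(mu) * DELTA_S) < 1e-12

    def test_zero_weights_zero_penalty(self):
        X, y = random_instance(1)
        n0, _ = penalized_nll_and_gradient(0.0, np.zeros(3), X, y, 0.0)
        n1, _ = penalized_nll_and_gradient(0.0, np.zeros(3), X, y, 100.0)
        assert n0 == n1

    def test_gradient_matches_finite_differences(self):
        for seed in range(5):
            X, y = random_instance(seed, T=300, p=4)
            rng = np.random.default_rng(100 + seed)
            mu = rng.normal(0, 0.5)
            A = rng.normal(0, 0.3, 4)
            alpha = rng.uniform(0, 1)
            _, g = penalized_nll_and_gradient(mu, A, X, y, alpha)
            eps = 1e-6
            for i in range(5):
                def f(du, dA_i=None):
                    A2 = A.copy()
                    if dA_i is not None:
                        A2[dA_i[0]] += dA_i[1]
                    v, _ = penalized_nll_and_gradient(mu + du, A2, X, y, alpha)
                    return v
                if i == 0:
                    num = (f(eps) - f(-eps)) / (2 * eps)
                else:
                    num = (f(0, (i - 1, eps)) - f(0, (i - 1, -eps))) / (2 * eps)
                assert abs(num - g[i]) <= 1e-6 * max(1.0, abs(g[i]))

    def test_overflow_reports_bin(self):
        X = np.zeros((10, 1))
        X[7, 0] = 1.0
        with pytest.raises(FloatingPointError, match="bin 7"):
            penalized_nll_and_gradient(0.0, np.array([1000.0]), X,
                                       np.zeros(10), 0.0)


class TestFitting:
    def test_covariate_free_closed_form(self):
        rng = np.random.default_rng(3)
        y = (rng.random(50000) < 0.015).astype(float)
        m = fit_ppglm(None, y, 0.0)
        assert abs(m.mu - np.log(y.mean() / DELTA_S)) < 1e-8

    def test_huge_penalty_shrinks_weights_not_mu(self):
        X, y = random_instance(4, T=20000, p=3)
        fm = assemble_design([FeatureBlock(X, ["a", "b", "c"], "kin")])
        m = fit_ppglm(fm, y, 1e6)
        assert np.linalg.norm(m.A) <= 1e-3
        assert abs(m.mu - np.log(y.mean() / DELTA_S)) < 1e-3

    def test_multistart_agreement_convexity(self):
        X, y = random_instance(5, T=5000, p=5, rate_hz=50)
        fm = assemble_design(
            [FeatureBlock(X, [f"c{i}" for i in range(5)], "kin")]
        )
        rng = np.random.default_rng(7)
        fits = []
        for _ in range(5):
            w0 = np.r_[rng.normal(-6, 1), rng.normal(0, 0.5, 5)]
            w0[0] = rng.normal(np.log(y.mean() / DELTA_S), 1.0)
            m = fit_ppglm(fm, y, 0.01, w0=w0)
            nll, _ = penalized_nll_and_gradient(m.mu, m.A, fm, y, 0.01)
            fits.append((nll, np.r_[m.mu, m.A]))
        objs = [f[0] for f in fits]
        assert max(objs) - min(objs) < 1e-8 * (abs(objs[0]) + 1)
        for _, w in fits[1:]:
            assert np.allclose(w, fits[0][1], atol=1e-4)

    def test_monotone_shrinkage_in_alpha(self):
        X, y = random_instance(6, T=8000, p=4, rate_hz=60)
        fm = assemble_design(
            [FeatureBlock(X, [f"c{i}" for i in range(4)], "kin")]
        )
        norms = [
            np.linalg.norm(fit_ppglm(fm, y, a).A)
            for a in (0.0, 1e-4, 1e-2, 1.0, 100.0)
        ]
        assert all(b <= a + 1e-9 for a, b in zip(norms, norms[1:]))

    def test_tiny_instance_matches_grid_search(self):
        X, y = random_instance(8, T=200, p=1, rate_hz=80)
        fm = assemble_design([FeatureBlock(X, ["a"], "kin")])
        m = fit_ppglm(fm, y, 0.0)
        mus = np.linspace(m.mu - 1, m.mu + 1, 201)
        ws = np.linspace(m.A[0] - 1, m.A[0] + 1, 201)
        best = (np.inf, None, None)
        for mu in mus:
            for w in ws:
                nll, _ = penalized_nll_and_gradient(
                    mu, np.array([w]), fm, y, 0.0
                )
                if nll < best[0]:
                    best = (nll, mu, w)
        assert abs(best[1] - m.mu) < 5e-3 + 1e-9
        assert abs(best[2] - m.A[0]) < 5e-3 + 1e-9

    def test_path_solver_matches_exact_newton(self):
        X, y = random_instance(9, T=3000, p=6, rate_hz=50)
        fm = assemble_design(
            [FeatureBlock(X, [f"c{i}" for i in range(6)], "kin")]
        )
        X1 = np.column_stack([np.ones(3000), fm.X])
        alphas = np.array([0.0, 1e-4, 1e-2, 1.0])
        W, info = _solver.fit_path(X1, y, alphas, gfac=1e-9)
        assert info["converged"].all()
        for k, a in enumerate(alphas):
            w_ref, _ = _solver.exact_newton(X1, y, a)
            assert np.allclose(W[:, k], w_ref, atol=1e-5)


class TestPreferredPhase:
    def _model(self, wc, ws, sd=None):
        labels = ["delta_cosph", "delta_sinph"]
        return PPGLMModel(
            mu=0.0, A=np.array([wc, ws]), alpha=0.0, labels=labels,
            groups=["lfp", "lfp"],
            zscore_mean=None if sd is None else np.zeros(2),
            zscore_sd=None if sd is None else np.asarray(sd),
        )

    def test_axis_cases(self):
        th, depth = preferred_phase(self._model(1.0, 0.0), "delta")
        assert th == 0.0 and abs(depth - 1.0) < 1e-12
        th, depth = preferred_phase(self._model(0.0, 1.0), "delta")
        assert abs(th - np.pi / 2) < 1e-12 and abs(depth - 1.0) < 1e-12

    def test_zscore_scale_undone(self):
        th, depth = preferred_phase(self._model(0.5, 0.5, sd=[0.5, 1.0]),
                                    "delta")
        assert abs(th - np.arctan2(0.5, 1.0)) < 1e-12

    def test_broad_band_rejected(self):
        m = PPGLMModel(mu=0.0, A=np.array([1.0]), alpha=0.0,
                       labels=["gamma1_amp"], groups=["lfp"])
        with pytest.raises(ValueError, match="phase"):
            preferred_phase(m, "gamma1")


class TestSerialization:
    def test_json_roundtrip(self):
        m = PPGLMModel(
            mu=-1.0, A=np.array([0.1, -0.2]), alpha=1e-3,
            labels=["a", "b"], groups=["kin", "lfp"],
            zscore_mean=np.array([1.0, 2.0]), zscore_sd=np.array([3.0, 4.0]),
        )
        m2 = PPGLMModel.from_json(m.to_json())
        assert m2.mu == m.mu and m2.alpha == m.alpha
        assert np.allclose(m2.A, m.A)
        assert np.allclose(m2.zscore_sd, m.zscore_sd)
        assert m2.labels == m.labels
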