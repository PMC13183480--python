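"""Block relaxation: designs, updates, fitting, and prediction."""

import numpy as np
import pytest

from tensorqr import (
    Dataset,
    FitConfig,
    QRModel,
    SimulationSpec,
    TensorQuantileRegressor,
    TuckerFactorization,
    check_loss,
    evaluate,
    fit,
    kron_chain,
    linear_predictor,
    predict_quantile,
    simulate,
    vec,
)
from tensorqr.estimator import _FitState, block_design, block_update
from conftest import assert_monotone_within_nu, random_factorization


def brute_force_quantile_line(x, y, tau):
    """Exact simple quantile regression by enumerating interpolating pairs."""
    best = (np.inf, None)
    n = len(y)
    for i in range(n):
        for k in range(n):
            if i == k or x[i] == x[k]:
                continue
            b = (y[i] - y[k]) / (x[i] - x[k])
            a = y[i] - b * x[i]
            loss = float(np.sum(check_loss(y - a - b * x, tau)))
            if loss < best[0] - 1e-12:
                best = (loss, (a, b))
    return best[1]


def _toy_model(rng, dims=(3, 4), rank=(2, 2), p0=2, tau=0.5):
    return QRModel(0.4, rng.standard_normal(p0), random_factorization(rng, dims, rank), tau)


def _toy_dataset(rng, n=40, dims=(3, 4), p0=2):
    return Dataset(
        rng.standard_normal(n),
        rng.standard_normal((n, p0)),
        rng.standard_normal((n,) + dims),
    )


class TestDataset:
    def test_alignment_error(self, rng):
        with pytest.raises(ValueError, match="alignment"):
            Dataset(np.zeros(5), np.zeros((4, 2)), np.zeros((5, 2, 2)))

    def test_nonfinite_rejected(self):
        y = np.array([1.0, np.nan])
        with pytest.raises(ValueError, match="invalid data"):
            Dataset(y, np.zeros((2, 0)), np.zeros((2, 2, 2)))

    def test_subset(self, rng):
        ds = _toy_dataset(rng)
        sub = ds.subset([0, 3, 5])
        assert sub.n == 3 and sub.dims == ds.dims


class TestLinearPredictor:
    def test_constant_model(self, rng):
        m = QRModel(1.0, np.zeros(2), TuckerFactorization(np.zeros((1, 1)), [np.ones((3, 1)), np.ones((4, 1))]))
        ds = _toy_dataset(rng)
        assert np.allclose(linear_predictor(m, ds.X, np.zeros_like(ds.Z)), 1.0)

    def test_matches_kron_route(self, rng):
        m = _toy_model(rng)
        ds = _toy_dataset(rng)
        eta = linear_predictor(m, ds.X, ds.Z)
        gk = kron_chain(m.effect) @ vec(m.effect.core)
        manual = m.alpha + ds.X @ m.beta + np.array([vec(z) @ gk for z in ds.Z])
        assert np.allclose(eta, manual, rtol=1e-10)

    def test_shape_mismatch(self, rng):
        m = _toy_model(rng)
        ds = _toy_dataset(rng, dims=(3, 5))
        with pytest.raises(ValueError, match="shape mismatch"):
            linear_predictor(m, ds.X, ds.Z)

    def test_intercept_shift(self, rng):
        m = _toy_model(rng)
        ds = _toy_dataset(rng)
        shifted = QRModel(m.alpha + 2.5, m.beta, m.effect, m.tau)
        assert np.allclose(
            predict_quantile(shifted, ds.X, ds.Z),
            predict_quantile(m, ds.X, ds.Z) + 2.5,
        )


class TestBlockDesign:
    def test_column_counts(self, rng):
        m = _toy_model(rng)
        ds = _toy_dataset(rng)
        assert block_design(ds, m, "scalars").shape == (ds.n, 3)
        assert block_design(ds, m, "core").shape == (ds.n, 4)
        assert block_design(ds, m, 0).shape == (ds.n, 6)
        assert block_design(ds, m, 1).shape == (ds.n, 8)

    def test_rank_one_unit_factor_core_column(self, rng):
        e1 = np.zeros((3, 1))
        e1[0, 0] = 1.0
        e2 = np.zeros((4, 1))
        e2[0, 0] = 1.0
        m = QRModel(0.0, np.zeros(0), TuckerFactorization(np.ones((1, 1)), [e1, e2]))
        ds = _toy_dataset(rng, p0=0)
        d = block_design(ds, m, "core")
        assert np.allclose(d[:, 0], ds.Z[:, 0, 0])

    def test_design_reproduces_block_contribution(self, rng):
        m = _toy_model(rng)
        ds = _toy_dataset(rng)
        eta = linear_predictor(m, ds.X, ds.Z)
        base = np.array([0.0])
        # core: eta = scalars + design_core @ vec(core)
        sc = block_design(ds, m, "scalars") @ np.concatenate([[m.alpha], m.beta])
        core_part = block_design(ds, m, "core") @ vec(m.effect.core)
        assert np.allclose(eta, sc + core_part, rtol=1e-9)
        for j in range(2):
            fac_part = block_design(ds, m, j) @ vec(m.effect.factors[j])
            assert np.allclose(eta, sc + fac_part, rtol=1e-9)

    def test_invalid_block(self, rng):
        with pytest.raises(ValueError, match="invalid block"):
            block_design(_toy_dataset(rng), _toy_model(rng), "banana")


class TestBlockUpdate:
    def test_descent_on_random_states(self, rng):
        ds = _toy_dataset(rng, n=30)
        cfg = FitConfig(rank=(2, 2), seed=0, n_restarts=1)
        for trial in range(20):
            state = _FitState(ds, cfg)
            state.alpha = float(rng.standard_normal())
            state.beta = rng.standard_normal(2)
            state.fact = random_factorization(rng, ds.dims, (2, 2))
            for block in ["scalars", "core", 0, 1]:
                before = state.objective(0.1)
                after = block_update(state, block, 0.1)
                assert after <= before + 1e-12

    def test_scalars_update_reaches_median(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ds = Dataset(y, np.zeros((5, 0)), np.zeros((5, 2, 2)))
        res = fit(ds, FitConfig(rank=(1, 1), tau=0.5, seed=0, n_restarts=1))
        assert abs(res.model.alpha - 3.0) < 1e-3

    def test_squared_loss_matches_ols(self, rng):
        n = 60
        X = rng.standard_normal((n, 3))
        y = 0.5 + X @ [1.0, -2.0, 0.3] + 0.2 * rng.standard_normal(n)
        ds = Dataset(y, X, np.zeros((n, 1, 1)))
        res = fit(ds, FitConfig(rank=(1, 1), loss_family="squared", seed=0, n_restarts=1))
        ref = np.linalg.lstsq(np.hstack([np.ones((n, 1)), X]), y, rcond=None)[0]
        assert np.allclose([res.model.alpha, *res.model.beta], ref, atol=1e-6)


class TestFit:
    def test_recovery_beats_zero_baseline(self):
        tr, te, truth = simulate(SimulationSpec(signal="square", p=16, n_train=200, n_test=100, seed=7))
        res = fit(tr, FitConfig(rank=(1, 1), seed=0, n_restarts=1))
        rep = evaluate(res.model, truth, te)
        zero_rmse = float(np.sqrt(np.mean(truth.tensor_effect**2)))
        assert rep.gamma_rmse < zero_rmse

    def test_quantile_close_to_squared_under_normal_error(self):
        # the efficiency loss of the median fit under normal errors is bounded
        # near sqrt(pi/2); compare medians over seeds to damp replicate noise
        ratios = []
        for seed in (11, 12, 13):
            tr, te, truth = simulate(SimulationSpec(signal="square", p=16, n_train=400, n_test=100, seed=seed))
            rq = fit(tr, FitConfig(rank=(1, 1), seed=2, n_restarts=1))
            rs = fit(tr, FitConfig(rank=(1, 1), seed=2, n_restarts=1, loss_family="squared"))
            gq = evaluate(rq.model, truth, te).gamma_rmse
            gs = evaluate(rs.model, truth, te).gamma_rmse
            ratios.append(gq / gs)
        assert np.median(ratios) <= 1.25

    def test_loss_path_monotone_within_nu(self):
        tr, _, _ = simulate(SimulationSpec(signal="square", p=16, n_train=150, n_test=10, seed=3))
        res = fit(tr, FitConfig(rank=(2, 2), seed=1, n_restarts=1))
        assert_monotone_within_nu(res.loss_path)

    def test_rank_exceeding_dims_names_mode(self):
        ds = Dataset(np.arange(5.0), np.zeros((5, 0)), np.zeros((5, 2, 3)))
        with pytest.raises(ValueError, match="mode 2"):
            fit(ds, FitConfig(rank=(2, 4), seed=0))

    def test_constant_response_warns(self):
        ds = Dataset(np.ones(10), np.zeros((10, 0)), np.zeros((10, 2, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            fit(ds, FitConfig(rank=(1, 1), seed=0, n_restarts=1, max_sweeps=2))

    def test_deterministic_given_seed(self):
        tr, _, _ = simulate(SimulationSpec(signal="square", p=16, n_train=100, n_test=10, seed=5))
        cfg = FitConfig(rank=(1, 1), seed=42, n_restarts=2, max_sweeps=5)
        r1, r2 = fit(tr, cfg), fit(tr, cfg)
        assert np.array_equal(r1.model.tensor_effect, r2.model.tensor_effect)
        assert r1.model.alpha == r2.model.alpha

    def test_median_residual_coverage(self):
        tr, _, _ = simulate(SimulationSpec(signal="square", p=16, n_train=400, n_test=10, seed=9))
        res = fit(tr, FitConfig(rank=(1, 1), tau=0.5, seed=0, n_restarts=1))
        resid = tr.y - predict_quantile(res.model, tr.X, tr.Z)
        frac_neg = np.mean(resid < 0)
        assert abs(frac_neg - 0.5) < 2.0 / np.sqrt(tr.n)

    def test_exact_quantile_oracle_small_n(self, rng):
        x = rng.standard_normal(10)
        y = 1.0 + 2.0 * x + rng.standard_normal(10)
        ds = Dataset(y, x[:, None], np.zeros((10, 1, 1)))
        for tau in (0.3, 0.5, 0.7):
            a, b = brute_force_quantile_line(x, y, tau)
            res = fit(ds, FitConfig(rank=(1, 1), tau=tau, seed=0, n_restarts=1))
            assert abs(res.model.alpha - a) < 5e-3
            assert abs(res.model.beta[0] - b) < 5e-3


class TestSklearnInterface:
    def test_fit_predict_tensor_input(self):
        tr, te, _ = simulate(SimulationSpec(signal="square", p=16, n_train=150, n_test=50, p0=0, seed=2))
        est = TensorQuantileRegressor(rank=(1, 1), n_restarts=1, random_state=0)
        est.fit(tr.Z, tr.y)
        assert est.tensor_effect_.shape == (16, 16)
        pred = est.predict(te.Z)
        assert pred.shape == (50,)

    def test_2d_input_with_dims_roundtrip(self, rng):
        tr, _, _ = simulate(SimulationSpec(signal="square", p=16, n_train=120, n_test=10, seed=2))
        est = TensorQuantileRegressor(rank=(1, 1), dims=(16, 16), n_restarts=1, random_state=0)
        flat = np.hstack([tr.X, np.array([vec(z) for z in tr.Z])])
        ds = est._as_dataset(flat, tr.y)
        assert np.allclose(ds.Z, tr.Z)
        assert np.allclose(ds.X, tr.X)

    def test_get_set_params_clone(self):
        from sklearn.base import clone

        est = TensorQuantileRegressor(rank=(2, 2), tau=0.25, lam=0.1, penalty="lasso")
        c = clone(est)
        assert c.get_params()["tau"] == 0.25 and c.get_params()["rank"] == (2, 2)

    def test_score_is_negative_check_loss(self):
        tr, te, _ = simulate(SimulationSpec(signal="square", p=16, n_train=150, n_test=50, seed=4))
        est = TensorQuantileRegressor(rank=(1, 1), n_restarts=1, random_state=0).fit(tr, tr.y)
        s = est.score(te, te.y)
        pred = est.predict(te)
        assert np.isclose(s, -np.mean(check_loss(te.y - pred, 0.5)))
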