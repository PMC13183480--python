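"""scikit-learn estimator interface for tensor quantile regression."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .estimator import Dataset, FitConfig, fit as _fit, linear_predictor
from .penalties import AdjacencyGraph, PenaltySpec
from .smoothing import SmoothingSchedule, check_loss

__all__ = ["TensorQuantileRegressor"]


class TensorQuantileRegressor(RegressorMixin, BaseEstimator):
    """Quantile regression with a low-rank tensor covariate effect.

    Fits ``Q_tau(Y | x, Z) = alpha + x'beta + <Z, Gamma>`` with a Tucker
    decomposition of rank ``rank`` on Gamma, by smoothed-loss cyclic block
    relaxation.  Composes with sklearn model selection when the covariates are
    passed as a 2-D array (see ``fit``).

    Parameters
    ----------
    rank : tuple of int
        Tucker rank (R1, ..., Rq) of the tensor effect.
    tau : float
        Quantile level in (0, 1).
    loss : {"quantile", "squared"}
        "squared" gives the mean-regression baseline with identical structure.
    penalty : {"none", "lasso", "fused_lasso"}
        Penalty family applied through the composed tensor effect.
    lam : float
        Penalty weight λ ≥ 0.
    adjacency : AdjacencyGraph, optional
        Cell adjacency for the fused lasso.
    dims : tuple of int, optional
        Tensor dimensions; required when ``X`` is passed 2-D.
    nu0, nu_decay, nu_min : float
        Geometric smoothing schedule; ``nu0=None`` starts at
        max(1, IQR of initial residuals).
    rel_tol : float
        Per-stage relative-change stopping rule (default 1e-4, i.e. 0.01%).
    n_restarts : int
        Independent random restarts; the best final objective is kept.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p0,)
        Scalar-covariate effects.
    tensor_effect_ : ndarray
        The composed coefficient tensor Γ̂.
    core_, factors_ : Tucker components of Γ̂ (canonicalized).
    result_ : FitResult with the per-block loss path and diagnostics.
    """

    def __init__(
        self,
        rank=(1, 1),
        tau=0.5,
        loss="quantile",
        penalty="none",
        lam=0.0,
        adjacency=None,
        dims=None,
        nu0=None,
        nu_decay=0.1,
        nu_min=1e-4,
        smooth_penalty_with_nu=True,
        rel_tol=1e-4,
        max_sweeps=50,
        inner_max_iter=200,
        n_restarts=3,
        random_state=None,
    ):
        self.rank = rank
        self.tau = tau
        self.loss = loss
        self.penalty = penalty
        self.lam = lam
        self.adjacency = adjacency
        self.dims = dims
        self.nu0 = nu0
        self.nu_decay = nu_decay
        self.nu_min = nu_min
        self.smooth_penalty_with_nu = smooth_penalty_with_nu
        self.rel_tol = rel_tol
        self.max_sweeps = max_sweeps
        self.inner_max_iter = inner_max_iter
        self.n_restarts = n_restarts
        self.random_state = random_state

    # -- input plumbing -----------------------------------------------------

    def _as_dataset(self, X, y=None) -> Dataset:
        if isinstance(X, Dataset):
            return X
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        y = np.zeros(n) if y is None else np.asarray(y, dtype=float)
        if X.ndim >= 3:
            return Dataset(y, np.zeros((n, 0)), X)
        if X.ndim == 2:
            if self.dims is None:
                raise ValueError("2-D covariate input requires the `dims` parameter")
            dims = tuple(self.dims)
            P = int(np.prod(dims))
            p0 = X.shape[1] - P
            if p0 < 0:
                raise ValueError(f"X has {X.shape[1]} columns < prod(dims) = {P}")
            Zc = X[:, p0:]
            Z = Zc.reshape((n,) + dims[::-1]).transpose(
                (0,) + tuple(range(len(dims), 0, -1))
            )
            return Dataset(y, X[:, :p0], Z)
        raise ValueError("covariate input must be a Dataset, tensor stack, or 2-D array")

    def _config(self) -> FitConfig:
        schedule = None
        if self.nu0 is not None:
            schedule = SmoothingSchedule(self.nu0, self.nu_decay, self.nu_min)
        adjacency = self.adjacency
        if adjacency is not None and not isinstance(adjacency, AdjacencyGraph):
            adjacency = AdjacencyGraph.from_edge_list(self.dims, adjacency)
        pen = PenaltySpec(
            family=self.penalty,
            lam=self.lam,
            adjacency=adjacency,
            smooth_with_nu=self.smooth_penalty_with_nu,
        )
        seed = self.random_state
        return FitConfig(
            rank=tuple(self.rank),
            tau=self.tau,
            schedule=schedule,
            nu_decay=self.nu_decay,
            nu_min=self.nu_min,
            penalty=pen,
            rel_tol=self.rel_tol,
            max_sweeps=self.max_sweeps,
            inner_max_iter=self.inner_max_iter,
            seed=seed,
            n_restarts=self.n_restarts,
            loss_family=self.loss,
        )

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y=None):
        ds = self._as_dataset(X, y)
        result = _fit(ds, self._config())
        self.result_ = result
        self.model_ = result.model
        self.intercept_ = result.model.alpha
        self.coef_ = result.model.beta
        self.core_ = result.model.effect.core
        self.factors_ = result.model.effect.factors
        self.tensor_effect_ = result.model.tensor_effect
        self.loss_path_ = result.loss_path
        self.converged_ = result.converged
        self.n_sweeps_ = result.sweeps_used
        self.n_features_in_ = ds.p0 + int(np.prod(ds.dims))
        return self

    def predict(self, X):
        ds = self._as_dataset(X)
        return linear_predictor(self.model_, ds.X, ds.Z)

    def score(self, X, y):
        """Negative mean check loss at tau (higher is better)."""
        pred = self.predict(X)
        return -float(np.mean(check_loss(np.asarray(y, dtype=float) - pred, self.tau)))
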