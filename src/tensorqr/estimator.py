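"""Tensor quantile regression by smoothed-loss cyclic block relaxation.

Model: the conditional τ-quantile of a scalar response is

    Q_τ(Y | x, Z) = α + xᵀβ + ⟨Z, Γ⟩,

with scalar covariates x and a tensor covariate Z whose effect Γ carries a
low-rank Tucker decomposition Γ = [Λ | Γ(1), ..., Γ(q)].  The (smoothed,
optionally penalized) objective

    l_ν(θ) = n⁻¹ Σ_i H_{τ,ν}(y_i − η_i) + λ J_ν(Γ)

is nonconvex jointly but *linear in each parameter block* (scalars, core,
each factor matrix) once the others are fixed, so each block subproblem is
smooth and convex.  Fitting cycles through the blocks, minimizing each with
gradient descent using Barzilai–Borwein step sizes safeguarded by Armijo
backtracking, while the smoothing width ν anneals to zero along a geometric
schedule, warm-starting each stage from the last.

Every block update is accepted only if it does not increase the objective, so
the recorded loss path is non-increasing within each ν stage by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .penalties import PenaltySpec, penalty_value_and_grad
from .smoothing import SmoothingSchedule, check_loss, gen_huber
from .tensor_core import (
    TuckerFactorization,
    canonicalize,
    kron_chain,
    matricize,
    tucker_compose,
    unmatricize,
    unvec,
    vec,
)

__all__ = [
    "Dataset",
    "QRModel",
    "FitConfig",
    "FitResult",
    "linear_predictor",
    "predict_quantile",
    "block_design",
    "block_update",
    "fit",
    "score",
    "information",
    "is_locally_identifiable",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Dataset:
    """Aligned response / scalar-covariate / tensor-covariate triplets.

    ``y`` has length n, ``X`` is n × p0 (p0 may be zero), and ``Z`` stacks the
    n tensor covariates along axis 0.
    """

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.size
        X = np.asarray(self.X, dtype=float)
        if X.size == 0:
            X = np.zeros((X.shape[0] if X.ndim >= 1 and X.shape[0] else n, 0))
        elif X.ndim == 1:
            X = X.reshape(-1, 1)
        self.X = X
        self.Z = np.asarray(self.Z, dtype=float)
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError(
                f"alignment error: y has {n} rows, X has {self.X.shape[0]}, "
                f"Z has {self.Z.shape[0]}"
            )
        for name, arr in (("y", self.y), ("X", self.X), ("Z", self.Z)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"invalid data: non-finite values in {name}")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p0(self) -> int:
        return self.X.shape[1]

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(self.Z.shape[1:])

    def subset(self, idx) -> "Dataset":
        return Dataset(self.y[idx], self.X[idx], self.Z[idx])


@dataclass
class QRModel:
    """Everything needed to predict a conditional quantile."""

    alpha: float
    beta: np.ndarray
    effect: TuckerFactorization
    tau: float = 0.5

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")

    @property
    def tensor_effect(self) -> np.ndarray:
        return tucker_compose(self.effect)


@dataclass
class FitConfig:
    """Hyperparameters and numerical controls for a fit.

    ``rel_tol`` is the 0.01% relative-change stopping rule, applied per ν
    stage to the penalized smoothed objective.  ``loss_family`` "squared"
    swaps the smoothed check loss for half the squared error, giving the
    mean-regression baseline with the identical block structure.
    """

    rank: tuple[int, ...] = (1, 1)
    tau: float = 0.5
    schedule: SmoothingSchedule | None = None
    nu_decay: float = 0.1
    nu_min: float = 1e-4
    penalty: PenaltySpec = field(default_factory=PenaltySpec)
    rel_tol: float = 1e-4
    max_sweeps: int = 50
    inner_max_iter: int = 200
    seed: int | None = None
    n_restarts: int = 3
    loss_family: str = "quantile"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        if self.loss_family not in ("quantile", "squared"):
            raise ValueError(f"unknown loss_family: {self.loss_family!r}")


@dataclass
class FitResult:
    """Fitted model plus the audit trail of the optimization."""

    model: QRModel
    loss_path: list  # rows (nu_index, sweep, block, objective)
    converged: bool
    sweeps_used: int
    config: FitConfig
    final_objective: float = np.nan

    def loss_path_array(self) -> np.ndarray:
        return np.array([row[3] for row in self.loss_path])


# ---------------------------------------------------------------------------
# linear predictor and block designs


def _flatten_rows(Z: np.ndarray) -> np.ndarray:
    """Rows are vec(Z_i) in mode-1-fastest order."""
    n = Z.shape[0]
    axes = (0,) + tuple(range(Z.ndim - 1, 0, -1))
    return np.ascontiguousarray(Z.transpose(axes).reshape(n, -1))


def _unfold_rows(Z: np.ndarray, mode: int) -> np.ndarray:
    """(n, pj, rest) stack of mode-``mode`` unfoldings of each Z_i."""
    B = np.moveaxis(Z, mode + 1, 1)
    axes = (0, 1) + tuple(range(B.ndim - 1, 1, -1))
    return np.ascontiguousarray(B.transpose(axes).reshape(Z.shape[0], Z.shape[mode + 1], -1))


def linear_predictor(model: QRModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """η_i = α + x_iᵀβ + ⟨Z_i, Γ⟩."""
    n = Z.shape[0]
    X = np.asarray(X, dtype=float).reshape(n, -1) if np.size(X) else np.zeros((n, 0))
    if X.shape[1] != model.beta.size:
        raise ValueError(f"shape mismatch: X has {X.shape[1]} columns, beta has {model.beta.size}")
    if tuple(Z.shape[1:]) != model.effect.dims:
        raise ValueError(f"shape mismatch: Z dims {Z.shape[1:]} vs effect dims {model.effect.dims}")
    g = vec(tucker_compose(model.effect))
    return model.alpha + X @ model.beta + _flatten_rows(Z) @ g


def predict_quantile(model: QRModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """The fitted conditional τ-quantile; identical to the linear predictor."""
    return linear_predictor(model, X, Z)


def _factor_design(Zunf_j: np.ndarray, f: TuckerFactorization, j: int) -> np.ndarray:
    """Rows vec( Z_i(j) · Γj⊗ · Λ(j)ᵀ )ᵀ — the factor-j block design."""
    Bj = kron_chain(f, skip=j) @ matricize(f.core, j).T  # (rest, Rj)
    D = np.einsum("npr,rk->nkp", Zunf_j, Bj)
    return D.reshape(Zunf_j.shape[0], -1)


def block_design(dataset: Dataset, model: QRModel, block) -> np.ndarray:
    """Design matrix of the chosen block ("scalars", "core", or factor index).

    The model being linear in each block, the block's contribution to η is
    ``design @ vec(block)``.
    """
    n = dataset.n
    if block == "scalars":
        return np.hstack([np.ones((n, 1)), dataset.X])
    if block == "core":
        return _flatten_rows(dataset.Z) @ kron_chain(model.effect)
    if isinstance(block, int) and 0 <= block < model.effect.order:
        return _factor_design(_unfold_rows(dataset.Z, block), model.effect, block)
    raise ValueError(f"invalid block: {block!r}")


# ---------------------------------------------------------------------------
# inner solver


def _loss_terms(r: np.ndarray, tau: float, nu: float, family: str):
    """Mean loss and the per-observation derivative ρ'(r)."""
    if family == "quantile":
        val, der = gen_huber(r, tau, nu)
        return float(val.mean()), der
    return float(0.5 * np.mean(r * r)), r


def _bb_descent(w0, value_and_grad, max_iter: int, gtol: float):
    """Monotone gradient descent with alternating BB1/BB2 steps.

    Each step is safeguarded by Armijo backtracking, so the objective never
    increases; a nonpositive or nonfinite BB step falls back to the last
    accepted step length.
    """
    w = np.asarray(w0, dtype=float).copy()
    f, g = value_and_grad(w)
    if not np.isfinite(f):
        raise FloatingPointError("diverged block update: non-finite objective")
    t = 1.0 / (np.linalg.norm(g) + 1e-12)
    for it in range(max_iter):
        gn2 = float(g @ g)
        if np.sqrt(gn2) <= gtol:
            break
        tt, accepted = t, False
        for _ in range(60):
            w_new = w - tt * g
            f_new, g_new = value_and_grad(w_new)
            if np.isfinite(f_new) and f_new <= f - 1e-4 * tt * gn2:
                accepted = True
                break
            tt *= 0.5
        if not accepted:
            break
        s = w_new - w
        dg = g_new - g
        sy = float(s @ dg)
        if it % 2 == 0:
            t_bb = float(s @ s) / sy if sy > 0 else np.nan
        else:
            yy = float(dg @ dg)
            t_bb = sy / yy if yy > 0 and sy > 0 else np.nan
        t = t_bb if np.isfinite(t_bb) and t_bb > 0 else tt
        stop = abs(f - f_new) <= 1e-12 * max(1.0, abs(f))
        w, f, g = w_new, f_new, g_new
        if stop:
            break
    return w, f


class _FitState:
    """Mutable optimization state with cached flattened covariates."""

    def __init__(self, dataset: Dataset, config: FitConfig):
        self.ds = dataset
        self.cfg = config
        self.Zmat = _flatten_rows(dataset.Z)
        self.Zunf = [_unfold_rows(dataset.Z, j) for j in range(len(dataset.dims))]
        self.X1 = np.hstack([np.ones((dataset.n, 1)), dataset.X])
        self.alpha = 0.0
        self.beta = np.zeros(dataset.p0)
        self.fact: TuckerFactorization | None = None

    @property
    def effect_vec(self) -> np.ndarray:
        return kron_chain(self.fact) @ vec(self.fact.core)

    def eta(self) -> np.ndarray:
        return self.alpha + self.ds.X @ self.beta + self.Zmat @ self.effect_vec

    def objective(self, nu: float) -> float:
        """Canonical penalized smoothed objective; the loss-path entry."""
        r = self.ds.y - self.eta()
        loss, _ = _loss_terms(r, self.cfg.tau, nu, self.cfg.loss_family)
        g = tucker_compose(self.fact)
        pen, _ = penalty_value_and_grad(g, self.cfg.penalty, nu)
        return loss + pen


def block_update(state: _FitState, block, nu: float) -> float:
    """Minimize the objective in one block, holding the others fixed.

    Returns the canonical objective after the update.  The update is reverted
    if it would increase the objective (guaranteeing monotone descent even
    under floating-point reordering).
    """
    ds, cfg = state.ds, state.cfg
    n = ds.n
    spec = cfg.penalty
    penalized = spec.family != "none" and spec.lam > 0

    if block == "scalars":
        A = state.X1
        w0 = np.concatenate([[state.alpha], state.beta])
        eta_rest = state.Zmat @ state.effect_vec
        to_G = None
    elif block == "core":
        Gkron = kron_chain(state.fact)
        A = state.Zmat @ Gkron
        w0 = vec(state.fact.core)
        eta_rest = state.alpha + ds.X @ state.beta
        to_G = lambda w: unvec(Gkron @ w, state.fact.dims)
        back = lambda dJdG: Gkron.T @ vec(dJdG)
    else:
        j = block
        Bj = kron_chain(state.fact, skip=j) @ matricize(state.fact.core, j).T
        A = np.einsum("npr,rk->nkp", state.Zunf[j], Bj).reshape(n, -1)
        w0 = vec(state.fact.factors[j])
        eta_rest = state.alpha + ds.X @ state.beta
        pj = ds.dims[j]
        to_G = lambda w: _compose_with_factor(state.fact, j, w.reshape(pj, -1, order="F"))
        back = lambda dJdG: vec(matricize(dJdG, j) @ Bj)

    y = ds.y

    def value_and_grad(w):
        r = y - eta_rest - A @ w
        f, der = _loss_terms(r, cfg.tau, nu, cfg.loss_family)
        grad = -(A.T @ der) / n
        if penalized and to_G is not None:
            pv, pg = penalty_value_and_grad(to_G(w), spec, nu)
            f += pv
            grad += back(pg)
        return f, grad

    before = state.objective(nu)
    if cfg.loss_family == "squared" and not (penalized and to_G is not None):
        w, _ = np.linalg.lstsq(A, y - eta_rest, rcond=None)[:2]
    else:
        gtol = 1e-8 * w0.size
        w, _ = _bb_descent(w0, value_and_grad, cfg.inner_max_iter, gtol)

    saved = (state.alpha, state.beta.copy(), state.fact)
    _write_block(state, block, w)
    after = state.objective(nu)
    if not np.isfinite(after) or after > before:
        state.alpha, state.beta, state.fact = saved
        return before
    return after


def _compose_with_factor(f: TuckerFactorization, j: int, Wj: np.ndarray) -> np.ndarray:
    factors = list(f.factors)
    factors[j] = Wj
    return tucker_compose(TuckerFactorization(f.core, factors))


def _write_block(state: _FitState, block, w: np.ndarray) -> None:
    if block == "scalars":
        state.alpha = float(w[0])
        state.beta = w[1:].copy()
    elif block == "core":
        state.fact = TuckerFactorization(
            unvec(w, state.fact.rank), [g.copy() for g in state.fact.factors]
        )
    else:
        factors = [g.copy() for g in state.fact.factors]
        factors[block] = w.reshape(state.ds.dims[block], -1, order="F")
        state.fact = TuckerFactorization(state.fact.core.copy(), factors)


# ---------------------------------------------------------------------------
# outer loop


def _initial_state(dataset: Dataset, config: FitConfig, rng: np.random.Generator) -> _FitState:
    state = _FitState(dataset, config)
    rank = tuple(config.rank)
    dims = dataset.dims
    if len(rank) != len(dims):
        raise ValueError(f"rank {rank} does not match tensor order {len(dims)}")
    for j, (r, p) in enumerate(zip(rank, dims)):
        if not 1 <= r <= p:
            raise ValueError(f"rank exceeds dims in mode {j + 1}: R={r}, p={p}")
    state.alpha = float(np.quantile(dataset.y, config.tau))
    factors = [rng.standard_normal((p, r)) / np.sqrt(p) for p, r in zip(dims, rank)]
    state.fact = TuckerFactorization(np.zeros(rank), factors)
    return state


def _auto_schedule(dataset: Dataset, state: _FitState, config: FitConfig) -> SmoothingSchedule:
    if config.schedule is not None:
        return config.schedule
    resid = dataset.y - state.alpha - dataset.X @ state.beta
    iqr = abs(float(np.subtract(*np.percentile(resid, [75, 25]))))
    return SmoothingSchedule(nu0=max(1.0, iqr), decay=config.nu_decay, nu_min=config.nu_min)


def fit(dataset: Dataset, config: FitConfig) -> FitResult:
    """Cyclic block relaxation across the vanishing-smoothing schedule.

    For each ν the blocks (scalars, core, factor 1..q) are updated in a fixed
    cyclic order until the penalized smoothed objective changes by less than
    ``rel_tol`` (relative) between sweeps, or ``max_sweeps`` is reached; the
    next ν stage warm-starts from the current estimates.  ``n_restarts``
    independent random initializations are run and the best final objective
    kept — a guard against the local minima the nonconvex problem admits.
    The returned model is canonicalized (unit-norm, sign-fixed factor columns).
    """
    if np.ptp(dataset.y) == 0:
        warnings.warn("degenerate fit: response is constant", stacklevel=2)
    master = np.random.SeedSequence(config.seed)
    best = None
    for child in master.spawn(max(1, config.n_restarts)):
        rng = np.random.default_rng(child)
        state = _initial_state(dataset, config, rng)
        schedule = _auto_schedule(dataset, state, config)
        if config.loss_family == "squared" and (
            config.penalty.family == "none" or config.penalty.lam == 0
        ):
            nus = [schedule.nu_min]
        else:
            nus = list(schedule.values())

        blocks = ["scalars", "core"] + list(range(len(dataset.dims)))
        loss_path = []
        converged = True
        sweeps_used = 0
        # one core update before the first sweep seats the random factors
        block_update(state, "core", nus[0])
        for ni, nu in enumerate(nus):
            prev = state.objective(nu)
            conv = False
            for sweep in range(config.max_sweeps):
                obj = prev
                for block in blocks:
                    obj = block_update(state, block, nu)
                    loss_path.append((ni, sweep, block, obj))
                sweeps_used += 1
                if abs(prev - obj) <= config.rel_tol * max(1e-12, abs(prev)):
                    conv = True
                    break
                prev = obj
            converged = converged and conv
        final = state.objective(nus[-1])
        if best is None or final < best[0]:
            best = (final, state, loss_path, converged, sweeps_used, nus)

    final, state, loss_path, converged, sweeps_used, nus = best
    effect = state.fact
    try:
        effect = canonicalize(effect)
    except ValueError:
        pass  # an exactly-zero factor column (degenerate data); leave as-is
    model = QRModel(state.alpha, state.beta, effect, config.tau)
    return FitResult(model, loss_path, converged, sweeps_used, config, final)


# ---------------------------------------------------------------------------
# score, information, identifiability


def _theta_design(model: QRModel, dataset: Dataset, include_scalars: bool = True) -> np.ndarray:
    """Per-observation gradient d_i = ∂η_i/∂θ, θ = (vecΛ, vecΓ(1..q)[, α, β])."""
    f = model.effect
    cols = [_flatten_rows(dataset.Z) @ kron_chain(f)]
    for j in range(f.order):
        cols.append(_factor_design(_unfold_rows(dataset.Z, j), f, j))
    if include_scalars:
        cols.append(np.hstack([np.ones((dataset.n, 1)), dataset.X]))
    return np.hstack(cols)


def score(model: QRModel, dataset: Dataset, nu: float) -> np.ndarray:
    """Gradient of the total smoothed check loss Σ_i H_{τ,ν}(y_i − η_i).

    Ordered as (vecΛ, vecΓ(1), ..., vecΓ(q), α, β); equals
    −Σ_i ρ'_{τ,ν}(y_i − η_i) d_i with d_i the per-observation η-gradient.
    """
    r = dataset.y - linear_predictor(model, dataset.X, dataset.Z)
    _, der = gen_huber(r, model.tau, nu)
    return -(_theta_design(model, dataset).T @ der)


def information(model: QRModel, dataset: Dataset, nu: float) -> np.ndarray:
    """Empirical plug-in Fisher information n⁻¹ Σ_i ρ'(y_i−η_i)² d_i d_iᵀ."""
    r = dataset.y - linear_predictor(model, dataset.X, dataset.Z)
    _, der = gen_huber(r, model.tau, nu)
    D = _theta_design(model, dataset)
    return (D * (der**2)[:, None]).T @ D / dataset.n


def _gauge_basis(f: TuckerFactorization, p0: int) -> np.ndarray:
    """Tangent directions of the Tucker gauge orbit (η unchanged).

    For every mode j and Rj×Rj generator E, perturbing Γ(j) by Γ(j)E while
    the core's mode-j unfolding absorbs −E leaves the composed tensor fixed
    to first order; these Σ Rj² directions are intrinsic null directions of
    the information matrix.
    """
    rank = f.rank
    sizes = [int(np.prod(rank))] + [p * r for p, r in zip(f.dims, rank)] + [1 + p0]
    offsets = np.cumsum([0] + sizes)
    total = offsets[-1]
    cols = []
    for j, rj in enumerate(rank):
        lam_j = matricize(f.core, j)  # (Rj, rest)
        for r in range(rj):
            for s in range(rj):
                v = np.zeros(total)
                E = np.zeros((rj, rj))
                E[r, s] = 1.0
                dlam = unmatricize(-E @ lam_j, rank, j)
                v[offsets[0] : offsets[1]] = vec(dlam)
                dfac = f.factors[j] @ E
                v[offsets[1 + j] : offsets[2 + j]] = vec(dfac)
                cols.append(v)
    return np.column_stack(cols)


def is_locally_identifiable(
    model: QRModel, dataset: Dataset, nu: float, tol: float = 1e-8
) -> bool:
    """Local identifiability ⇔ nonsingular information on the reduced space.

    The raw information matrix is always singular along the Tucker gauge orbit
    (scale/rotation indeterminacy); identifiability is judged by the smallest
    eigenvalue of the information restricted to the orthogonal complement of
    those known gauge directions — the canonicalized parameter space.
    """
    I = information(model, dataset, nu)
    N = _gauge_basis(model.effect, dataset.p0)
    # orthonormal basis of the complement of span(N)
    U, s, _ = np.linalg.svd(N, full_matrices=True)
    rank_n = int(np.sum(s > 1e-10 * max(1.0, s[0] if s.size else 0.0)))
    C = U[:, rank_n:] if rank_n < U.shape[1] else np.zeros((I.shape[0], 0))
    if C.shape[1] == 0:
        return False
    M = C.T @ I @ C
    ev = np.linalg.eigvalsh(M)
    return bool(ev[0] > tol * max(1.0, ev[-1]))
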