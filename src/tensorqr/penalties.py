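"""Penalties applied through the composed tensor effect.

Regularization acts on the composed effect Γ = [Λ | Γ(1), ..., Γ(q)] rather
than on the decomposition components, so the penalty has direct meaning on the
coefficient map (sparsity of cells, smoothness between spatially adjacent
cells).  The absolute value is smoothed as ``|u| ≈ 2 H_{0.5,ν}(u)`` — twice the
generalized Huber function at τ = 1/2 — so the penalized objective stays
differentiable and converges uniformly to the exact penalty as ν → 0.

Gradients with respect to the core and factor parameters follow by the chain
rule through the Tucker composition:

    ∇_vecΛ J   = Γ⊗ᵀ vec(∂J/∂Γ)
    ∇_vecΓ(j) J = vec( (∂J/∂Γ)_(j) · Γj⊗ · Λ_(j)ᵀ )

where Γ⊗ (resp. Γj⊗) is the descending Kronecker chain of all factors (resp.
all factors but mode j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .smoothing import gen_huber
from .tensor_core import TuckerFactorization, kron_chain, matricize, vec

__all__ = [
    "PenaltySpec",
    "AdjacencyGraph",
    "lasso",
    "fused_lasso",
    "build_grid_adjacency",
    "grad_wrt_core",
    "grad_wrt_factor",
    "penalty_value_and_grad",
]


@dataclass
class AdjacencyGraph:
    """Cell adjacency over a tensor grid, for fused-lasso penalties.

    ``terms`` lists the (a, b) pairs of flat cell indices exactly as the
    penalty sum enumerates them — duplicates are kept when a wraparound term
    revisits a pair, so the penalty value reproduces the literal sum.
    ``edges`` is the deduplicated set of undirected edges.
    """

    dims: tuple[int, ...]
    terms: np.ndarray  # (m, 2) int array, one row per penalty term

    def __post_init__(self) -> None:
        self.terms = np.asarray(self.terms, dtype=np.intp).reshape(-1, 2)
        n = int(np.prod(self.dims))
        if self.terms.size and (self.terms.min() < 0 or self.terms.max() >= n):
            raise ValueError("adjacency edge references a cell outside dims")
        if np.any(self.terms[:, 0] == self.terms[:, 1]):
            raise ValueError("adjacency contains a self-edge")

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {tuple(sorted(pair)) for pair in self.terms.tolist()}

    @classmethod
    def from_edge_list(cls, dims, edges) -> "AdjacencyGraph":
        return cls(tuple(dims), np.asarray(edges, dtype=np.intp))


@dataclass
class PenaltySpec:
    """Penalty family, weight, and smoothing linkage.

    ``smooth_with_nu=True`` ties the |·| smoothing width to the loss's current
    ν (keeping the whole objective uniformly convergent along the schedule);
    otherwise ``nu_pen`` is used throughout.
    """

    family: str = "none"
    lam: float = 0.0
    adjacency: AdjacencyGraph | None = None
    smooth_with_nu: bool = True
    nu_pen: float = 1e-4

    def __post_init__(self) -> None:
        if self.family not in ("none", "lasso", "fused_lasso"):
            raise ValueError(f"unknown penalty family: {self.family!r}")
        if self.lam < 0:
            raise ValueError("penalty weight must be nonnegative")
        if self.family == "fused_lasso" and self.lam > 0 and self.adjacency is None:
            raise ValueError("fused_lasso requires an adjacency graph")

    def effective_nu(self, nu: float) -> float:
        return nu if self.smooth_with_nu else self.nu_pen


def _smooth_abs(u: np.ndarray, nu: float):
    """Smoothed absolute value 2·H_{0.5,ν} and its derivative."""
    val, der = gen_huber(u, 0.5, nu)
    return 2.0 * val, 2.0 * der


def lasso(g: np.ndarray, nu: float):
    """Smoothed elementwise lasso on the composed effect.

    Returns ``(value, gradient)`` where the gradient is a tensor of the same
    shape as ``g``.  The value converges to Σ|g| as ν → 0.
    """
    val, der = _smooth_abs(np.asarray(g, dtype=float), nu)
    return float(val.sum()), der


def fused_lasso(g: np.ndarray, adj: AdjacencyGraph, nu: float):
    """Smoothed sum of absolute differences across adjacent cells.

    Evaluates ``Σ_terms 2 H_{0.5,ν}(g_a − g_b)`` over the graph's term list
    (with multiplicity) and accumulates the ±derivative into an elementwise
    gradient tensor of the same shape as ``g``.
    """
    g = np.asarray(g, dtype=float)
    if tuple(g.shape) != tuple(adj.dims):
        raise ValueError(f"dims mismatch: tensor {g.shape} vs adjacency {adj.dims}")
    gv = vec(g)
    a, b = adj.terms[:, 0], adj.terms[:, 1]
    val, der = _smooth_abs(gv[a] - gv[b], nu)
    grad = np.zeros_like(gv)
    np.add.at(grad, a, der)
    np.add.at(grad, b, -der)
    return float(val.sum()), grad.reshape(g.shape, order="F")


def build_grid_adjacency(
    dims: tuple[int, int, int],
    wrap_mode3: bool = True,
    block_mode1: bool = True,
) -> AdjacencyGraph:
    """Grid adjacency for an order-3 tensor (slice × rows × columns).

    For each mode-1 slice ``k``, penalty terms join vertical neighbours
    ``(i,j)–(i+1,j)`` for ``i < p2`` and horizontal neighbours ``(i,j)–(i,j+1)``
    for every row, with the last column wrapping back to the first when
    ``wrap_mode3`` (a cyclic surface parameterization).  ``block_mode1`` keeps
    slices disconnected — e.g. no penalty ties the left and right hippocampi.
    """
    if len(dims) != 3:
        raise ValueError("grid adjacency requires order-3 dims")
    p1, p2, p3 = dims

    def flat(k, i, j):
        return k + p1 * i + p1 * p2 * j

    terms = []
    for k in range(p1):
        for j in range(p3):
            for i in range(p2 - 1):
                terms.append((flat(k, i, j), flat(k, i + 1, j)))
            jmax = p3 if wrap_mode3 else p3 - 1
            if j < jmax:
                for i in range(p2):
                    terms.append((flat(k, i, j), flat(k, i, (j + 1) % p3)))
        if not block_mode1 and k < p1 - 1:
            for j in range(p3):
                for i in range(p2):
                    terms.append((flat(k, i, j), flat(k + 1, i, j)))
    return AdjacencyGraph(tuple(dims), np.asarray(terms, dtype=np.intp))


def grad_wrt_core(djdg: np.ndarray, f: TuckerFactorization) -> np.ndarray:
    """Chain-rule penalty gradient w.r.t. vec(core): Γ⊗ᵀ vec(∂J/∂Γ)."""
    djdg = np.asarray(djdg, dtype=float)
    if tuple(djdg.shape) != f.dims:
        raise ValueError(f"dims mismatch: {djdg.shape} vs {f.dims}")
    return kron_chain(f).T @ vec(djdg)


def grad_wrt_factor(djdg: np.ndarray, f: TuckerFactorization, j: int) -> np.ndarray:
    """Chain-rule penalty gradient w.r.t. vec(factor j).

    Returns ``vec( (∂J/∂Γ)_(j) · Γj⊗ · Λ_(j)ᵀ )``, length pj·Rj.
    """
    djdg = np.asarray(djdg, dtype=float)
    if tuple(djdg.shape) != f.dims:
        raise ValueError(f"dims mismatch: {djdg.shape} vs {f.dims}")
    if not 0 <= j < f.order:
        raise ValueError(f"mode out of range: {j}")
    m = matricize(djdg, j) @ kron_chain(f, skip=j) @ matricize(f.core, j).T
    return vec(m)


def penalty_value_and_grad(g: np.ndarray, spec: PenaltySpec, nu: float):
    """Weighted penalty λ·J(Γ) and its elementwise gradient λ·∂J/∂Γ."""
    if spec.family == "none" or spec.lam == 0.0:
        return 0.0, None
    nu_eff = spec.effective_nu(nu)
    if spec.family == "lasso":
        val, grad = lasso(g, nu_eff)
    else:
        val, grad = fused_lasso(g, spec.adjacency, nu_eff)
    return spec.lam * val, spec.lam * grad
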