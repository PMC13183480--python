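"""Dense tensor algebra for low-rank Tucker effects.

Conventions
-----------
Tensors are plain ``numpy`` arrays with shape ``(p1, ..., pq)``.  Vectorization
is *mode-1-fastest* (the column-major / Fortran analogue): index ``(i1, ..., iq)``
maps to position ``i1 + p1*i2 + p1*p2*i3 + ...``.  Mode-``j`` matricization
follows the Kolda–Bader convention: rows index mode ``j`` and columns run over
the remaining modes with lower modes varying fastest.  Under these conventions

    vec([L | G1, ..., Gq]) = (Gq ⊗ ... ⊗ G1) vec(L),

i.e. the Kronecker chain runs over modes in *descending* order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

__all__ = [
    "TuckerFactorization",
    "vec",
    "unvec",
    "matricize",
    "unmatricize",
    "mode_permutation",
    "tucker_compose",
    "kron_chain",
    "inner",
    "canonicalize",
]


def vec(a: np.ndarray) -> np.ndarray:
    """Vectorize a tensor with mode 1 varying fastest."""
    return np.asarray(a).reshape(-1, order="F")


def unvec(v: np.ndarray, dims: tuple[int, ...]) -> np.ndarray:
    """Inverse of :func:`vec` for the given dimensions."""
    v = np.asarray(v)
    if v.size != int(np.prod(dims)):
        raise ValueError(f"cannot reshape {v.size} values into dims {dims}")
    return v.reshape(dims, order="F")


def matricize(a: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization A_(j) of shape (pj, prod of other dims).

    ``mode`` is 0-based.  Columns run over the remaining modes with lower
    modes varying fastest (Kolda–Bader unfolding).
    """
    a = np.asarray(a)
    if not 0 <= mode < a.ndim:
        raise ValueError(f"mode out of range: {mode} for order-{a.ndim} tensor")
    return np.moveaxis(a, mode, 0).reshape(a.shape[mode], -1, order="F")


def unmatricize(m: np.ndarray, dims: tuple[int, ...], mode: int) -> np.ndarray:
    """Inverse of :func:`matricize`."""
    if not 0 <= mode < len(dims):
        raise ValueError(f"mode out of range: {mode} for dims {dims}")
    rest = tuple(d for k, d in enumerate(dims) if k != mode)
    a = np.asarray(m).reshape((dims[mode],) + rest, order="F")
    return np.moveaxis(a, 0, mode)


def mode_permutation(dims: tuple[int, ...], mode: int) -> np.ndarray:
    """Index map ``perm`` with ``vec(A) = vec(A_(mode))[perm]``.

    Realizes the row-permutation operator tying a tensor's vectorization to the
    vectorization of its mode-``mode`` unfolding, as an index array rather than
    a dense permutation matrix.  The inverse map is ``np.argsort(perm)``.
    """
    n = int(np.prod(dims))
    idx = unmatricize(np.arange(n).reshape(dims[mode], -1, order="F"), dims, mode)
    return vec(idx)


@dataclass
class TuckerFactorization:
    """Low-rank Tucker representation ``[core | factors[0], ..., factors[q-1]]``.

    Parameters
    ----------
    core : ndarray of shape (R1, ..., Rq)
        Core tensor holding the interaction weights.
    factors : list of ndarray
        Factor matrices; the j-th has shape (pj, Rj).
    """

    core: np.ndarray
    factors: list[np.ndarray]

    def __post_init__(self) -> None:
        self.core = np.asarray(self.core, dtype=float)
        self.factors = [np.atleast_2d(np.asarray(f, dtype=float)) for f in self.factors]
        if self.core.ndim != len(self.factors):
            raise ValueError(
                "inconsistent factorization: core order "
                f"{self.core.ndim} != number of factors {len(self.factors)}"
            )
        for j, (r, f) in enumerate(zip(self.core.shape, self.factors)):
            if f.shape[1] != r:
                raise ValueError(
                    f"inconsistent factorization: factor {j} has {f.shape[1]} "
                    f"columns but core dim {j} is {r}"
                )
            if f.shape[1] > f.shape[0]:
                raise ValueError(
                    f"inconsistent factorization: rank {f.shape[1]} exceeds "
                    f"dimension {f.shape[0]} in mode {j}"
                )

    @property
    def rank(self) -> tuple[int, ...]:
        return self.core.shape

    @property
    def dims(self) -> tuple[int, ...]:
        return tuple(f.shape[0] for f in self.factors)

    @property
    def order(self) -> int:
        return self.core.ndim

    def copy(self) -> "TuckerFactorization":
        return TuckerFactorization(self.core.copy(), [f.copy() for f in self.factors])


def tucker_compose(f: TuckerFactorization) -> np.ndarray:
    """Compose the full tensor from its Tucker factorization.

    Equals the sum over all core entries ``λ_{r1..rq}`` of the scaled outer
    products of the corresponding factor columns.
    """
    out = f.core
    for j, g in enumerate(f.factors):
        out = np.moveaxis(np.tensordot(g, out, axes=(1, j)), 0, j)
    return out


def kron_chain(f: TuckerFactorization, skip: int | None = None) -> np.ndarray:
    """Kronecker product of the factors in descending mode order.

    With ``skip=None`` returns ``Gq ⊗ ... ⊗ G1`` (shape ∏pj × ∏Rj), which
    satisfies ``vec(tucker_compose(f)) = kron_chain(f) @ vec(core)``.  With
    ``skip=j`` mode ``j`` is omitted from the chain.
    """
    mats = [g for k, g in enumerate(f.factors) if k != skip]
    if skip is not None and not 0 <= skip < f.order:
        raise ValueError(f"mode out of range: {skip}")
    if not mats:
        return np.eye(1)
    return reduce(np.kron, mats[::-1])


def inner(z: np.ndarray, g: np.ndarray) -> float:
    """Tensor inner product ⟨Z, G⟩ = vec(Z)ᵀ vec(G)."""
    z = np.asarray(z)
    g = np.asarray(g)
    if z.shape != g.shape:
        raise ValueError(f"dims mismatch: {z.shape} vs {g.shape}")
    return float(np.dot(z.ravel(), g.ravel()))


def canonicalize(f: TuckerFactorization) -> TuckerFactorization:
    """Resolve scale/sign indeterminacy of the factorization.

    Every factor column is rescaled to unit Euclidean norm with its
    largest-magnitude entry made positive; the absorbed scales and signs move
    into the core, leaving the composed tensor unchanged.
    """
    core = f.core.copy()
    factors = []
    for j, g in enumerate(f.factors):
        g = g.copy()
        norms = np.linalg.norm(g, axis=0)
        if np.any(norms == 0):
            raise ValueError(f"degenerate factor: zero column in mode {j}")
        signs = np.array([np.sign(col[np.argmax(np.abs(col))]) for col in g.T])
        scale = norms * signs
        g /= scale
        # absorb scales into the core along mode j
        shape = [1] * core.ndim
        shape[j] = -1
        core = core * scale.reshape(shape)
        factors.append(g)
    return TuckerFactorization(core, factors)
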