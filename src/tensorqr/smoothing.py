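"""Check loss, its generalized-Huber smoothing, and smoothing schedules.

The check (quantile) loss ``ρ_τ(u) = [τ − 1(u<0)] u`` is not differentiable at
zero, which rules out plain gradient methods.  We replace it by the generalized
Huber function ``H_{τ,ν}``: linear tails matching the check loss up to a
constant, with a quadratic middle piece of width ``ν`` on ``[(τ−1)ν, τν]``:

    H_{τ,ν}(u) = u(τ−1) − (τ−1)²ν/2   for u < (τ−1)ν
               = u²/(2ν)              for (τ−1)ν ≤ u < τν
               = uτ − τ²ν/2           for u ≥ τν

``H_{τ,ν}`` is convex, continuously differentiable, and converges uniformly to
``ρ_τ`` as ν → 0 (the gap is at most ``ν max(τ, 1−τ)²/2``), so minimizers of
the smoothed problem track those of the exact quantile problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "check_loss",
    "gen_huber",
    "smoothing_gap_bound",
    "SmoothingSchedule",
]


def check_loss(u, tau: float):
    """Quantile (check) loss ρ_τ(u), elementwise."""
    u = np.asarray(u, dtype=float)
    return (tau - (u < 0)) * u


def gen_huber(u, tau: float, nu: float):
    """Generalized Huber value and derivative, elementwise.

    Returns ``(value, derivative)``.  The derivative is continuous, lies in
    ``[τ−1, τ]``, and equals ``u/ν`` on the quadratic middle piece.
    """
    if nu <= 0:
        raise ValueError(f"invalid smoothing: nu must be positive, got {nu}")
    u = np.asarray(u, dtype=float)
    lo, hi = (tau - 1.0) * nu, tau * nu
    value = np.where(
        u < lo,
        u * (tau - 1.0) - (tau - 1.0) ** 2 * nu / 2.0,
        np.where(u >= hi, u * tau - tau**2 * nu / 2.0, u**2 / (2.0 * nu)),
    )
    deriv = np.clip(u / nu, tau - 1.0, tau)
    return value, deriv


def smoothing_gap_bound(tau: float, nu: float) -> float:
    """Uniform bound on |H_{τ,ν} − ρ_τ|: ``ν max(τ, 1−τ)² / 2``."""
    return nu * max(tau, 1.0 - tau) ** 2 / 2.0


@dataclass
class SmoothingSchedule:
    """Geometric, zero-convergent sequence of smoothing parameters.

    ``nu0`` is the starting width, shrunk by ``decay`` each stage and truncated
    at ``nu_min``.  The final stage is exactly ``nu_min``.
    """

    nu0: float = 1.0
    decay: float = 0.1
    nu_min: float = 1e-4

    def __post_init__(self) -> None:
        if self.nu0 <= 0 or self.nu_min <= 0:
            raise ValueError("smoothing parameters must be positive")
        if not 0 < self.decay < 1:
            raise ValueError("decay must lie in (0, 1)")
        if self.nu_min > self.nu0:
            raise ValueError("nu_min must not exceed nu0")

    def values(self) -> np.ndarray:
        """The sequence ν_0, ν_0·decay, ..., truncated at ``nu_min``."""
        out = []
        nu = self.nu0
        while nu > self.nu_min and not np.isclose(nu, self.nu_min):
            out.append(nu)
            nu *= self.decay
        out.append(self.nu_min)
        return np.array(out)
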