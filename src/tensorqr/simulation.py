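"""Seeded simulation designs and evaluation metrics.

The generator emulates the standard scalar-on-tensor benchmark: binary {0,1}
2-D signal tensors, covariate entries iid standard normal, responses
``y = η + ε`` with ``η = xᵀβ + ⟨Z, Γ⟩`` and errors drawn from normal, t,
Cauchy, or χ² families scaled to a target signal-to-noise ratio.  SNR is
defined as sd(η)/sd(ε); for the Cauchy, whose variance does not exist, the
sd is replaced by an IQR-matched robust spread (IQR divided by the normal's
IQR-to-sd ratio).  t and χ² errors are median-centered so the τ = 0.5
conditional quantile equals η exactly.

An order-3 "surface" fixture emulates grid-parameterized paired-surface data
(two disconnected blocks, wraparound adjacency in the last mode) with a
piecewise-constant true effect suited to the fused lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage.draw import polygon as _sk_polygon

from .estimator import Dataset, QRModel, predict_quantile
from .tensor_core import TuckerFactorization

__all__ = [
    "SimulationSpec",
    "EvalReport",
    "make_signal",
    "noise_scale",
    "simulate",
    "evaluate",
    "make_surface_fixture",
    "SIGNALS",
]

SIGNALS = ("square", "cross", "disk", "triangle", "star")

# ratio of a standard normal's IQR to its standard deviation
_NORMAL_IQR = float(stats.norm.ppf(0.75) - stats.norm.ppf(0.25))


def make_signal(name: str, p: int) -> np.ndarray:
    """Deterministic binary p×p signal mask, centered in the grid.

    ``square`` is the central p/2 × p/2 block (an exactly rank-1 mask) and
    ``cross`` the union of a horizontal and a vertical bar (exactly rank 2).
    ``star`` rasterizes a five-pointed polygon.  All shapes cover between 5%
    and 40% of the grid.
    """
    if p < 16:
        raise ValueError("signal grids need p >= 16")
    g = np.zeros((p, p))
    c = (p - 1) / 2.0
    if name == "square":
        lo, hi = p // 4, p // 4 + p // 2
        g[lo:hi, lo:hi] = 1.0
    elif name == "cross":
        w = max(2, p // 6)
        lo = (p - w) // 2
        g[lo : lo + w, :] = 1.0
        g[:, lo : lo + w] = 1.0
    elif name == "disk":
        ii, jj = np.indices((p, p))
        g[(ii - c) ** 2 + (jj - c) ** 2 <= (p / 4.0) ** 2] = 1.0
    elif name == "triangle":
        # isoceles triangle, apex up, height and base p/2
        for k, i in enumerate(range(p // 4, p // 4 + p // 2)):
            half = max(1, (k * (p // 2)) // (2 * (p // 2)))
            g[i, int(c) - half : int(c) + half + 1] = 1.0
    elif name == "star":
        outer, inner = 0.44 * p, 0.18 * p
        ang = -np.pi / 2 + np.arange(10) * np.pi / 5
        rad = np.where(np.arange(10) % 2 == 0, outer, inner)
        rr, cc = _sk_polygon(c + rad * np.sin(ang), c + rad * np.cos(ang), shape=(p, p))
        g[rr, cc] = 1.0
    else:
        raise ValueError(f"unknown signal name: {name!r}")
    return g


def noise_scale(eta: np.ndarray, family: str, df: float | None, snr: float) -> float:
    """Error scale s with sd(η) / (s · unit-spread) = snr.

    The unit-spread is the family's standard deviation at unit scale — 1 for
    the normal, sqrt(df/(df−2)) for t (df > 2), sqrt(2·df) for centered χ² —
    or, for the Cauchy, its IQR divided by the normal IQR-to-sd ratio.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if family == "normal":
        spread = 1.0
    elif family == "t":
        if df is None or df <= 2:
            raise ValueError("infinite variance; use robust spread (t needs df > 2)")
        spread = np.sqrt(df / (df - 2.0))
    elif family == "chisq":
        spread = np.sqrt(2.0 * df)
    elif family == "cauchy":
        spread = 2.0 / _NORMAL_IQR  # IQR of standard Cauchy is 2
    else:
        raise ValueError(f"unknown error family: {family!r}")
    return float(np.std(eta) / (snr * spread))


def _draw_errors(rng, family: str, df: float | None, size: int) -> np.ndarray:
    """Unit-scale errors, median-centered."""
    if family == "normal":
        return rng.standard_normal(size)
    if family == "t":
        return rng.standard_t(df, size)
    if family == "cauchy":
        return rng.standard_cauchy(size)
    if family == "chisq":
        return rng.chisquare(df, size) - stats.chi2.median(df)
    raise ValueError(f"unknown error family: {family!r}")


def _family_quantile(family: str, df: float | None, tau: float) -> float:
    """τ-quantile of the centered unit-scale error."""
    if family == "normal":
        return float(stats.norm.ppf(tau))
    if family == "t":
        return float(stats.t.ppf(tau, df))
    if family == "cauchy":
        return float(stats.cauchy.ppf(tau))
    if family == "chisq":
        return float(stats.chi2.ppf(tau, df) - stats.chi2.median(df))
    raise ValueError(f"unknown error family: {family!r}")


@dataclass
class SimulationSpec:
    """One replicate of the 2-D benchmark design."""

    signal: str = "square"
    p: int = 64
    n_train: int = 500
    n_test: int = 500
    p0: int = 5
    beta_true: np.ndarray | None = None  # defaults to (1, 2, ..., p0)
    error_family: str = "normal"
    error_df: float | None = 3.0
    snr: float = 3.0
    tau: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0 or self.n_test <= 0:
            raise ValueError("sample sizes must be positive")
        if self.beta_true is None:
            self.beta_true = np.arange(1.0, self.p0 + 1.0)
        self.beta_true = np.asarray(self.beta_true, dtype=float)


@dataclass
class EvalReport:
    """Held-out predictive error and coefficient recovery error."""

    test_mae: float
    gamma_rmse: float

    def __post_init__(self) -> None:
        if self.test_mae < 0 or self.gamma_rmse < 0:
            raise ValueError("metrics must be nonnegative")


def simulate(spec: SimulationSpec):
    """Generate (train Dataset, test Dataset, truth QRModel).

    The truth's intercept is the τ-quantile of the scaled error, so
    ``predict_quantile(truth, ·)`` is the exact conditional τ-quantile.
    """
    rng = np.random.default_rng(spec.seed)
    gamma = make_signal(spec.signal, spec.p)
    n_all = spec.n_train + spec.n_test
    X = rng.standard_normal((n_all, spec.p0))
    Z = rng.standard_normal((n_all, spec.p, spec.p))
    eta = X @ spec.beta_true + Z.reshape(n_all, -1) @ gamma.ravel()
    s = noise_scale(eta, spec.error_family, spec.error_df, spec.snr)
    eps = s * _draw_errors(rng, spec.error_family, spec.error_df, n_all)
    y = eta + eps
    tr = slice(0, spec.n_train)
    te = slice(spec.n_train, n_all)
    train = Dataset(y[tr], X[tr], Z[tr])
    test = Dataset(y[te], X[te], Z[te])
    alpha_true = s * _family_quantile(spec.error_family, spec.error_df, spec.tau)
    u, sv, vt = np.linalg.svd(gamma)
    r = max(1, int(np.sum(sv > 1e-10 * sv[0])))
    truth = QRModel(
        alpha_true,
        spec.beta_true,
        TuckerFactorization(np.diag(sv[:r]), [u[:, :r], vt[:r].T]),
        spec.tau,
    )
    return train, test, truth


def evaluate(fitted: QRModel, truth: QRModel | np.ndarray, test: Dataset) -> EvalReport:
    """Test MAE of the fitted quantile and RMSE of the coefficient tensor."""
    pred = predict_quantile(fitted, test.X, test.Z)
    gamma_true = truth.tensor_effect if isinstance(truth, QRModel) else np.asarray(truth)
    gamma_hat = fitted.tensor_effect
    if gamma_hat.shape != gamma_true.shape:
        raise ValueError("dims mismatch between fitted and true tensor effects")
    return EvalReport(
        test_mae=float(np.mean(np.abs(test.y - pred))),
        gamma_rmse=float(np.sqrt(np.mean((gamma_hat - gamma_true) ** 2))),
    )


def gamma_rmse(gamma_hat: np.ndarray, gamma_true: np.ndarray) -> float:
    """Root mean squared error between coefficient tensors, cellwise."""
    return float(np.sqrt(np.mean((np.asarray(gamma_hat) - np.asarray(gamma_true)) ** 2)))


def make_surface_fixture(
    p2: int = 75,
    p3: int = 50,
    seed: int = 0,
    n: int = 200,
    snr: float = 3.0,
):
    """Synthetic order-3 paired-surface dataset (2 × p2 × p3) and true effect.

    Each of the two mode-1 blocks carries a few contiguous constant-valued
    patches (one wrapping around the mode-3 seam), giving a piecewise-constant
    truth with wraparound continuity that the fused lasso is designed for.
    Returns ``(Dataset, gamma_true)``.
    """
    if p2 < 8 or p3 < 8:
        raise ValueError("surface fixture needs p2, p3 >= 8")
    rng = np.random.default_rng(seed)
    gamma = np.zeros((2, p2, p3))
    for k, sign in enumerate((1.0, -1.0)):
        # one interior patch
        gamma[k, p2 // 6 : p2 // 6 + p2 // 4, p3 // 5 : p3 // 5 + p3 // 4] = sign
        # one patch wrapping the mode-3 seam
        rows = slice(p2 // 2, p2 // 2 + p2 // 4)
        w = p3 // 6
        gamma[k, rows, p3 - w :] = -sign
        gamma[k, rows, :w] = -sign
    Z = rng.standard_normal((n, 2, p2, p3))
    eta = Z.reshape(n, -1) @ gamma.ravel()
    s = noise_scale(eta, "normal", None, snr)
    y = eta + s * rng.standard_normal(n)
    return Dataset(y, np.zeros((n, 0)), Z), gamma
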