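"""Rank selection by BIC and penalty-weight selection by cross-validation.

The Tucker rank is tuned on unpenalized fits with a BIC whose effective
degrees of freedom count the decomposition parameters net of rotational
indeterminacy: ``df = 1 + p0 + ∏Rj + Σ pj Rj − Σ Rj²``.  The penalty weight λ
is tuned by K-fold cross-validation on the held-out check loss at τ — the
quantity the model actually optimizes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .estimator import Dataset, FitConfig, FitResult, fit, predict_quantile
from .penalties import PenaltySpec
from .smoothing import check_loss

__all__ = ["bic", "select_rank", "cv_lambda", "tucker_df"]


def tucker_df(rank, dims, p0: int = 0) -> int:
    """Effective parameter count 1 + p0 + ∏Rj + Σ pj·Rj − Σ Rj²."""
    rank = tuple(rank)
    dims = tuple(dims)
    return int(
        1
        + p0
        + np.prod(rank)
        + sum(p * r for p, r in zip(dims, rank))
        - sum(r * r for r in rank)
    )


def bic(result: FitResult, dataset: Dataset) -> float:
    """BIC = 2n·L̄ + df·log n with L̄ the mean check loss at the estimate.

    The loss is evaluated with the exact (unsmoothed) check loss, i.e. the
    ν → 0 objective; intended for unpenalized or fixed-λ fits.
    """
    model = result.model
    pred = predict_quantile(model, dataset.X, dataset.Z)
    lbar = float(np.mean(check_loss(dataset.y - pred, model.tau)))
    df = tucker_df(model.effect.rank, model.effect.dims, dataset.p0)
    n = dataset.n
    return 2.0 * n * lbar + df * np.log(n)


def select_rank(dataset: Dataset, candidates, config: FitConfig):
    """Fit each candidate rank (shared seed) and return the BIC argmin.

    Returns ``(best_rank, grid)`` where ``grid`` is a DataFrame with one row
    per candidate (rank, bic, final objective, converged).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty rank candidate list")
    rows = []
    best = None
    for rank in candidates:
        rank = tuple(rank) if np.iterable(rank) else (rank,) * len(dataset.dims)
        res = fit(dataset, replace(config, rank=rank))
        b = bic(res, dataset)
        rows.append(
            {
                "rank": rank,
                "bic": b,
                "objective": res.final_objective,
                "converged": res.converged,
            }
        )
        if best is None or b < best[0]:
            best = (b, rank, res)
    grid = pd.DataFrame(rows)
    return best[1], grid


def cv_lambda(dataset: Dataset, lambdas, K: int, config: FitConfig):
    """K-fold cross-validation over the penalty weight λ.

    Folds are a seeded partition of the data; each observation is held out
    exactly once.  The criterion is the mean held-out check loss at τ.
    Ties break toward the smaller λ.  Returns ``(best_lambda, grid)``.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty lambda grid")
    if K > dataset.n:
        raise ValueError(f"K = {K} exceeds n = {dataset.n}")
    if K < 2:
        raise ValueError("cross-validation needs K >= 2")
    kf = KFold(n_splits=K, shuffle=True, random_state=config.seed)
    folds = list(kf.split(np.arange(dataset.n)))
    rows = []
    for lam in sorted(lambdas):
        losses = []
        for fold_i, (tr, te) in enumerate(folds):
            cfg = replace(
                config,
                penalty=replace(config.penalty, lam=float(lam)),
                seed=None if config.seed is None else config.seed + 1000 * (fold_i + 1),
            )
            res = fit(dataset.subset(tr), cfg)
            held = dataset.subset(te)
            pred = predict_quantile(res.model, held.X, held.Z)
            losses.append(float(np.mean(check_loss(held.y - pred, config.tau))))
        rows.append({"lam": float(lam), "cv_loss": float(np.mean(losses))})
    grid = pd.DataFrame(rows)
    best_lam = float(grid.loc[grid["cv_loss"].idxmin(), "lam"])
    return best_lam, grid
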