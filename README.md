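# tensorqr

Regularized quantile regression with tensor-valued covariates.

Imaging studies routinely relate a scalar outcome (a cognitive score, a
clinical measurement) to covariates that are tensors — a 2-D coefficient map
over an image grid, or an order-3 array over a parameterized anatomical
surface — alongside ordinary scalar covariates.  Vectorizing the tensor and
running a huge linear regression ignores its structure and overfits; mean
regression is fragile when responses are skewed, heavy-tailed, or
heteroskedastic.  `tensorqr` addresses both problems at once: it models a
conditional **quantile** of the response with a **low-rank tensor effect**,

```
Q_τ(Y | x, Z) = α + xᵀβ + ⟨Z, Γ⟩,          Γ = [Λ | Γ⁽¹⁾, …, Γ⁽ᑫ⁾]  (Tucker, rank (R₁,…,R_q))
```

estimated by minimizing the check loss ρ_τ(u) = [τ − 1(u<0)]u.  Because ρ_τ
is non-differentiable, it is replaced by the generalized Huber surrogate
H_{τ,ν} (linear tails, quadratic middle of width ν), and ν is annealed to
zero along a geometric schedule.  The objective is nonconvex jointly but
linear in each parameter block — (α,β), the core Λ, and each factor matrix
Γ⁽ʲ⁾ — so estimation cycles through the blocks, solving each smooth convex
subproblem by gradient descent with Barzilai–Borwein steps, stopping at a
0.01% relative change in the loss.  Penalties (elementwise lasso; fused
lasso over a spatial adjacency graph, with optional wraparound and
disconnected components) are applied **through the composed effect Γ**, not
to the decomposition components, so sparsity and smoothness land directly on
the interpretable coefficient map.

The package also provides the score and empirical Fisher information of the
smoothed model (with a local-identifiability check on the canonicalized
parameter space), BIC rank selection, K-fold cross-validation for the
penalty weight, a seeded simulation suite (binary 2-D signals, four error
families at a target SNR, an order-3 surface fixture), and a CLI.

## Worked example

Median regression of a synthetic response on a 32×32 tensor covariate whose
true coefficient map is a binary cross (an exactly rank-2 matrix), with five
scalar covariates (β = 1,…,5) and **Cauchy** errors scaled to SNR 3:

```python
import numpy as np
from tensorqr import TensorQuantileRegressor, SimulationSpec, simulate, evaluate

spec = SimulationSpec(signal="cross", p=32, n_train=1000, n_test=500,
                      error_family="cauchy", snr=3.0, seed=0)
train, test, truth = simulate(spec)

est = TensorQuantileRegressor(rank=(2, 2), tau=0.5, n_restarts=1, random_state=1)
est.fit(train, train.y)
rep = evaluate(est.model_, truth, test)
print(f"beta       : {np.round(est.coef_, 2)}")
print(f"test MAE   : {rep.test_mae:.3f}")
print(f"Gamma RMSE : {rep.gamma_rmse:.3f}")
```

prints

```
beta       : [0.97 2.03 3.64 4.02 4.52]
test MAE   : 35.536
Gamma RMSE : 0.080
```

The scalar effects are recovered near (1,…,5) and the coefficient-map RMSE
is 0.080 — against a root-mean-square of 0.52 for the all-zero map.  The
large test MAE simply reflects Cauchy noise (its mean absolute deviation is
infinite).  Swapping `loss="squared"` (the mean-regression baseline with the
identical low-rank structure) on the same data gives Gamma RMSE 1.373:
the estimate is destroyed by the heavy tails, which is precisely the case
for quantile loss.

The same estimator is a scikit-learn regressor: `get_params`/`set_params`,
`clone`, and 2-D covariate input (`dims=(p1,…,pq)`, columns `[X | vec(Z)]`)
for use with sklearn model selection all work.  Equivalent shell commands
are available via `tensorqr simulate | fit | predict | evaluate | cv-lambda
| select-rank`.

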