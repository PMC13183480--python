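# Methods

## Model

For a scalar response Y, scalar covariates x ∈ ℝ^{p0}, and a tensor
covariate Z ∈ ℝ^{p1×…×pq}, the level-τ conditional quantile is modeled as

    Q_τ(Y | x, Z) = α + xᵀβ + ⟨Z, Γ⟩,     ⟨Z, Γ⟩ = vec(Z)ᵀ vec(Γ),

with the tensor effect constrained to a Tucker decomposition
Γ = [Λ | Γ⁽¹⁾, …, Γ⁽ᑫ⁾] of rank (R₁,…,R_q): a core tensor Λ ∈ ℝ^{R1×…×Rq}
multiplied along each mode by a factor matrix Γ⁽ʲ⁾ ∈ ℝ^{pj×Rj}.  This cuts
the tensor-effect parameter count from ∏pj to ∏Rj + Σ pjRj.  Estimation
minimizes the empirical check loss ρ_τ(u) = [τ − 1(u<0)]u of the residuals,
optionally plus a penalty λ·J(Γ) evaluated **through the composed effect**
rather than on Λ or the Γ⁽ʲ⁾ — so the penalty's meaning (cellwise sparsity,
spatial smoothness) attaches to the interpretable coefficient map.

Assumptions worth keeping in mind: the model is linear in vec(Z) given the
low-rank constraint; the quantile level τ is fixed a priori; responses are
independent across subjects; identifiability of the decomposition is up to
the usual scale/rotation gauge, which is resolved by canonicalization
(unit-norm factor columns, sign fixed by the largest-magnitude entry, scales
absorbed into the core).

## Layout conventions

Vectorization is mode-1-fastest (the column-major analogue); mode-j
matricization follows the Kolda–Bader unfolding.  Under these conventions
vec(Γ) = (Γ⁽ᑫ⁾ ⊗ … ⊗ Γ⁽¹⁾) vec(Λ) — the Kronecker chain in descending mode
order — and the block-linearity identity
⟨Z, Γ⟩ = ⟨Z₍ⱼ₎ Γⱼ⊗ Λ₍ⱼ₎ᵀ, Γ⁽ʲ⁾⟩ holds, where Γⱼ⊗ omits mode j from the
chain.  Both identities are enforced by tests at 1e-10 relative tolerance;
every Jacobian used by the score/information code is derived from this
convention and validated against finite differences, rather than transcribed
from any printed ordering.  Mode permutations are realized as index maps,
never as dense ∏pj × ∏pj matrices.

## Smoothing

The check loss is replaced by the generalized Huber function H_{τ,ν}
(linear–quadratic–linear with knots at (τ−1)ν and τν), which is convex, C¹,
and satisfies sup|H_{τ,ν} − ρ_τ| ≤ ν·max(τ,1−τ)²/2.  The smoothing width
follows a geometric schedule ν_{k+1} = decay·ν_k truncated at ν_min, with

- ν₀ = max(1, IQR of the initial residuals) — scales with the data,
- decay = 0.1,
- ν_min = 1e-4 — the final optimization is effectively at the exact loss.

These defaults are a design choice of this package (residual-dependent
update rules are a known alternative); the geometric schedule is
deterministic and keeps the per-stage warm starts close.  The absolute value
inside lasso-type penalties is smoothed the same way, as 2·H_{0.5,ν}, by
default sharing the loss's current ν so the whole penalized objective
converges uniformly as ν → 0; a fixed ν_pen is available instead.

## Optimization

With all blocks but one held fixed, the linear predictor is linear in the
free block, so each block subproblem (smoothed loss + smoothed convex
penalty) is smooth and convex.  A fit cycles deterministically through the
blocks in the order (scalars, core, factor 1..q), solving each by gradient
descent with alternating Barzilai–Borwein (BB1/BB2) step sizes under an
Armijo backtracking safeguard (inner cap 200 iterations, gradient tolerance
1e-8 × block dimension).  A block result is accepted only if the globally
recomputed objective did not increase, so the recorded loss path is
non-increasing within every ν stage *by construction*; the test suite
asserts this on every fit it runs.  Per ν stage, sweeps stop at a 0.01%
relative change of the penalized smoothed objective (the penalty is included
so the monotonicity statement stays well-defined).  For the squared-loss
baseline without a penalty, block updates use exact least squares and a
single ν stage (the loss does not depend on ν).

Initialization: α starts at the sample τ-quantile of y, β at zero, factors
iid N(0,1)/√pj, core at zero, followed by one core update before the first
sweep.  Because the joint problem is nonconvex, `n_restarts` (default 3)
independent initializations are run and the best final objective kept; most
tests use one restart, which suffices at the problem sizes exercised.

## Score, information, identifiability

For the smoothed model the per-observation η-gradient is
d_i = [Γ⊗ | J₁ | … | J_q]ᵀ vec(Z_i) with the scalar block [1, x_i] appended;
the score is −Σ ρ′_{τ,ν}(y_i−η_i) d_i and the empirical plug-in information
is I_N = n⁻¹ Σ ρ′² d_i d_iᵀ.  I_N is always singular along the Tucker gauge
orbit (perturbing Γ⁽ʲ⁾ by Γ⁽ʲ⁾E while the core's mode-j unfolding absorbs
−E leaves Γ unchanged to first order — Σ Rj² directions).  The
identifiability check therefore builds that gauge basis explicitly, projects
I_N onto its orthogonal complement (the tangent space of the canonicalized
parameter space), and declares the model locally identifiable when the
smallest remaining eigenvalue exceeds tol × the largest (tol = 1e-8).
Duplicate factor columns, for instance, create degeneracy beyond the gauge
and are flagged.

## Penalties

- `lasso`: Σ_cells 2·H_{0.5,ν}(Γ_cell) → Σ|Γ_cell| as ν → 0.
- `fused_lasso`: Σ over adjacency terms 2·H_{0.5,ν}(Γ_a − Γ_b).  The
  order-3 grid builder emits, per mode-1 slice, vertical terms
  (i,j)–(i+1,j) for i < p2 and horizontal terms (i,j)–(i,j+1) for **all**
  rows with j wrapping p3 → 1 (a cyclic surface parameterization); mode-1
  slices can be kept disconnected (paired structures such as left/right
  anatomy).  When p3 = 2 the wrap revisits each horizontal pair; the term
  list keeps both terms so the penalty value reproduces the literal double
  sum, while the deduplicated edge set is exposed separately.
- Chain-rule gradients: ∇_vecΛ = Γ⊗ᵀ vec(∂J/∂Γ) and
  ∇_vecΓ⁽ʲ⁾ = vec((∂J/∂Γ)₍ⱼ₎ Γⱼ⊗ Λ₍ⱼ₎ᵀ), both finite-difference tested.

Penalties act only on the tensor effect, never on α or β.  BIC (below) is
applied to unpenalized fits only; λ is always chosen by cross-validation.

## Model selection

BIC = 2n·L̄ + df·log n, with L̄ the mean *exact* check loss at the estimate
and df = 1 + p0 + ∏Rj + Σ pjRj − Σ Rj² (Tucker parameters net of rotational
indeterminacy).  λ is selected by K-fold CV (default K = 5; smaller K is
used in some tests for speed) on held-out mean check loss at τ, ties going
to the smaller λ.

## Synthetic data

The 2-D benchmark draws Z and x entries iid N(0,1), sets β = (1,…,p0)
(default p0 = 5), forms η = xᵀβ + ⟨Z, Γ⟩ with a binary {0,1} signal mask Γ,
and adds errors from one of {normal, t, Cauchy, χ²}.  SNR is defined as
sd(η)/sd(ε) with sd(ε) the family's standard deviation at unit scale; since
the Cauchy has none, its "sd" is the IQR divided by the normal IQR-to-sd
ratio (≈1.349) — absolute metric values under Cauchy noise depend on this
convention.  t and χ² default to 3 degrees of freedom; all error families
are median-centered, so at τ = 0.5 the model is exactly correctly specified,
and the generated truth's intercept is the τ-quantile of the scaled error so
predictions from the truth are exact conditional quantiles at any τ.

Five canonical masks are provided — square (exactly rank 1), cross (exactly
rank 2: 1∘1 − (1−u)∘(1−v)), disk, triangle, star (a rasterized five-pointed
polygon) — all deterministic, binary, and covering 5–40% of the grid.  The
order-3 surface fixture (default 2×75×50; tests use smaller grids) places
constant-valued patches on each of two disconnected blocks, one patch
wrapping the mode-3 seam, with normal noise at SNR 3.

What the generator does **not** emulate: spatial correlation within Z
(entries are independent), non-binary or smooth true effects in the 2-D
designs, covariate measurement error, and dependence between subjects.
Passing recovery tests therefore demonstrates correctness of the estimator
under the stated design, not performance on correlated real imaging data.

## Problem sizes and numerical choices

Test and reproduction runs use desk-scale versions of the benchmark chosen
once: consistency on a 16×16 rank-1 truth over n ∈ {250, 500, 1000};
robustness and the quantile/squared comparison on a 32×32 cross with rank
(2,2) and n = 1000; the rank U-shape on a 16×16 cross at n = 300 (where the
R = 5 model's df ≈ 136 makes overfitting visible); lasso CV at SNR 1 with a
λ grid {0, 0.003, 0.012, 0.03}.  Degenerate inputs: a constant response
triggers a warning; a rank exceeding a mode's dimension raises with the
offending mode named; residuals exactly at a Huber knot use the linear-piece
derivative (a measure-zero event with matching one-sided values).

## Known limitations

- One tensor covariate per model; multiple tensor variables must be
  concatenated along mode 1 (the surface fixture illustrates the pattern).
- No standard-error or confidence-interval output; the asymptotic theory is
  exercised through recovery and score/information tests instead.
- Convex penalties only (none/lasso/fused lasso); the penalty interface is
  pluggable but nonconvex penalties are untested.
- Cyclic fixed block order only; no free-steering or ADMM/proximal variants.
- Dense tensors only; no CP-decomposition variant.
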