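# Methods

## Model

`bvsim` estimates a bivariate single-index mixed-effects model for
clustered continuous outcome pairs.  Subject *i* contributes `m_i` members
(e.g. teeth); member *j* yields `y_ij = (y_ij1, y_ij2)`:

    y_ijk = g_k(x_ijk' β_k) + z_ijk' b_ik + ε_ijk ,   k = 1, 2.

* `β_k` (unit norm, positive first component) are the index coefficients;
  `g_k` are unknown smooth links.
* `b_i = (b_i1, b_i2)` is a subject-level random effect with unstructured
  covariance `Ω` across both responses; `z_ijk` carries an intercept plus
  covariates.
* `ε_ij` is a bivariate error with scatter `Σ` and skewness `γ`.

The random terms follow multivariate shifted asymmetric Laplace (SALD)
laws built from a *single* exponential mixing variable per subject:

    y_i | b_i, V_i ~ N(μ̃_i + V_i (1_{m_i} ⊗ γ), V_i · I_{m_i} ⊗ Σ)
    b_i | V_i      ~ N(0, V_i Ω)
    V_i            ~ Exp(1).

Marginally `y_i ~ SALD_{2 m_i}(μ_i, G_i, 1_{m_i} ⊗ γ)` with
`G_i = Z_i' Ω Z_i + I_{m_i} ⊗ Σ`.  The shared `V_i` does two jobs: it
produces heavy tails jointly for a subject's responses, and it makes the
subject-level skew shift `V_i γ` identifiable (the links `g_k` absorb any
constant, so `γ` is identified through the distributional shape, not the
mean).  The SALD mean and covariance are `μ + γ` and `Σ + γγ'`.

## Numerics for the Laplace distribution

The SALD density and the E-step moments involve modified Bessel functions
`K_ν` at orders `ν = 1 − m_i` (down to −9 for ten-member clusters) and
arguments spanning many decades.  All evaluations run in log scale: the
order is reduced to its fractional part (where `scipy.special.kve` is
stable), then the three-term recurrence
`K_{o+1} = K_{o−1} + (2o/x) K_o` is applied upward with `logaddexp`, which
cannot overflow because every term is positive.  Ratios
`R_ν = K_{ν+1}/K_ν` are differences of log values; the GIG conditional
moments of `V_i` given `y_i` are

    E[V|y]   = sqrt(b/a) R_ν(√(ab)),
    E[1/V|y] = sqrt(a/b) R_ν(√(ab)) − 2ν/b,

with `a = 2 + γ*' G⁻¹ γ*` and `b = (y−μ)' G⁻¹ (y−μ)`.  `b` is floored at
1e−10; at the floor the expressions reproduce the small-argument limits
(`E[V|y] → 0`, `E[1/V|y] → ∞`) without special cases.  Scatter matrices
with condition number above 1e12 are rejected.

Per-subject quantities use the Woodbury identity
`G⁻¹ = Λ⁻¹ − Λ⁻¹Z'(Ω⁻¹ + ZΛ⁻¹Z')⁻¹ZΛ⁻¹`, so the largest factorization is
`(q1+q2+2)`-dimensional regardless of cluster size, and everything is
vectorized across subjects.

## Spline bases

Links are approximated by B-splines (cubic by default) on clamped knot
vectors, normalized so basis values at any point sum to the basis
dimension `K' + order`.  Interior knots sit at equally spaced quantiles of
the current index values (robust to skewed index distributions; an
experiment with equally spaced knots changed the index-coefficient error
by under 4%, so the choice is not load-bearing).  The support is the
observed index range and moves with `β`; evaluation outside the support is
clamped to the boundary.

The interior-knot count `K` (shared by both links) minimizes
`SIC(K) = −log L̂ + log(n) · 2K` over the integer grid from
`⌈0.5 n^{1/(2s+1)}⌉` to `⌊min(5 n^{1/(2s+1)}, √n)⌋` with smoothness `s = 2`
(at n=200 the grid is 2…14).  Selection happens once, on short pilot fits
(25 iterations each); re-selecting during the ECM iterations would break
the ascent property.

## ECM estimation

Starting values follow the convention `γ⁰ = 0`, `Σ⁰ = I₂`, with index
directions and `Ω⁰` from per-response linear mixed models (statsmodels
`MixedLM`; an OLS fallback with `Ω⁰ = I` is available and is the default
for large simulation studies, where the ECM refinement makes the cheaper
start equivalent) and spline coefficients from least squares on the
initial index.

Each iteration: an E-step computing `Δ_i = (Ω⁻¹ + ZΛ⁻¹Z')⁻¹`, the random
effect posterior pieces `R_i1, R_i2`, and the GIG moments `c_i, d_i`;
then five conditional-maximization steps — generalized least squares for
the spline coefficients `θ`, a closed form for `γ`, Newton–Raphson with
step-halving on the delete-one-component coordinates for `β` (the step is
accepted only if the expected complete-data objective Q1 does not
decrease; one Newton step per cycle by default, which measurably equals
ten steps in estimate and likelihood at half the cost), and closed forms
for `Σ` (the symmetrized quadratic-form sum divided by N) and `Ω` (the
mean of the posterior second-moment matrices).  Each update weakly
increases Q1/Q2 with the E-step posterior fixed, so the marginal
log-likelihood never decreases across iterations; this is asserted in the
test suite to 1e−8 on randomized datasets.

After the CM steps, if the new index values leave the current spline
support, knots are rebuilt and `θ` refit; the refreshed basis is kept only
when the marginal likelihood does not drop, preserving the monotone trace.

Convergence: maximum relative parameter change below `tol_param`
(1e−6 by default; 1e−5 in the Monte-Carlo harness, where the induced
estimate shift is below 1e−3 — two orders of magnitude under the
Monte-Carlo standard errors) or log-likelihood change below 1e−8, with a
500-iteration cap by default.

Two guards address genuine pathologies of the likelihood:

* **Degenerate subjects.**  The SALD marginal is unbounded along the ridge
  where one subject's Mahalanobis form `b_i → 0` (the subject is
  interpolated and `E[1/V_i|y] ~ 2|ν|/b_i` diverges).  When
  `min_i b_i < 1e−6` the fit stops and returns; the other parameters
  stabilize hundreds of iterations before this point.
* **Orientation boundary.**  `(β, g)` and `(−β, g(−·))` describe the same
  model; the positive-first-component convention picks one representative,
  but the delete-one-component parametrization cannot cross `β₁ = 0`.  A
  fit whose first component collapses to that boundary is restarted once
  from the tail-reflected orientation and the higher-likelihood fit is
  kept.

## Inference

Confidence intervals use the cluster bootstrap: subjects are resampled
with replacement (keeping all their members, which preserves within-cluster
dependence), the model is refit with the knot count of the base fit, and
percentile intervals are formed from the converged replicates (200
replicates, 95% by default).  Fitted values for observed subjects use the
posterior-mean random effects `E[b_i|y] = R_i1 − c_i R_i2`; predictions
for unseen subjects set the random effect to its prior mean zero and add
the error mean `γ̂` (a switch exposes the zero-mean variant).  AAFE/AAPE
are the average absolute fitted and prediction errors per response.

## Synthetic designs and what they show

The skewed design draws, per subject, `m_i ~ U{5,…,10}` members,
`x ~ U(0,1)³` index covariates per response, random-effect covariates
`(1, N(0,1))`, and the random terms from the hierarchical form above with
`g1(u) = 2 sin(πu)`, `g2(u) = 8u(1−u)`, `β1 = (1,−1,1)/√3`,
`β2 = (2,1,1)/√6`, `γ = (2, 1.5)`, `Σ = [[1, .6],[.6, 1]]`, and a fixed
4×4 `Ω`.  Four symmetric variants probe robustness: multivariate normal,
t with 5 degrees of freedom, symmetric Laplace (hierarchical, the regime
where the fitted model is exactly specified), and the scale mixture
`0.8 N(0,S) + 0.2 N(0,10S)` with independent mixing indicators per draw.

The generators share one mixing variable per subject for the Laplace
designs; they do not emulate covariate measurement error, missing members
(informative or otherwise), non-uniform covariate distributions, or
between-subject heterogeneity in `Σ`.  Passing recovery tests on these
designs therefore demonstrates correctness of the estimator under the
model's own assumptions (plus the three symmetric misspecifications), not
robustness to everything real dental data can do.

Replicates receive independent child seed-sequences spawned from one
master seed, so parallel and serial study runs produce identical tables.
The Monte-Carlo harness in `scripts/acceptance.py` uses 100 replications
per cell (reference summaries use 400) with the study-scale estimation
settings above; replicate failures are counted and reported, never
silently dropped.

## Known limitations

* The skewness pair converges along a very flat likelihood ridge (EM
  convergence rate near one); hundreds of iterations are normal, and the
  parameter-change criterion governs in practice.
* No standard errors from the information matrix; the bootstrap is the
  only supported inference.
* Two responses only; nested (not crossed) random effects; complete cases
  only.
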