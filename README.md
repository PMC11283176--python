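# bvsim — bivariate single-index mixed models with asymmetric Laplace random terms

`bvsim` fits a semiparametric joint model for **clustered bivariate
continuous outcomes** — the motivating case is periodontal research, where
probed pocket depth (PPD) and clinical attachment level (CAL) are measured
on every tooth of every study subject, and both outcomes are right-skewed
and heavy-tailed enough to break Gaussian mixed-model assumptions.

## The model

For member *j* of subject *i* the response pair is

```
y_ij = ( g1(x_ij1' β1) + z_ij1' b_i1 ,   g2(x_ij2' β2) + z_ij2' b_i2 )  +  ε_ij
```

* each response depends on its covariates only through a scalar **index**
  `u = x'β` transformed by an unknown smooth link `g_k`, approximated by
  normalized cubic B-splines (`‖β_k‖ = 1`, first component positive, for
  identifiability);
* the subject random effects `b_i ~ SAL(0, Ω, 0)` and the errors
  `ε_ij ~ SAL2(0, Σ, γ)` follow **multivariate (shifted) asymmetric Laplace
  distributions**, sharing one exponential mixing variable `V_i` per
  subject:

  ```
  y_i | b_i, V_i ~ N( μ_i + V_i (1 ⊗ γ), V_i Λ_i ),
  b_i | V_i     ~ N( 0, V_i Ω ),          V_i ~ Exp(1).
  ```

  The skewness vector `γ` captures asymmetry, the scatter `Σ` the residual
  dependence between the two outcomes, and `Ω` the within- and
  cross-outcome clustering.

Maximum likelihood runs through an **ECM algorithm**: the E-step computes
the conditional moments of the random effects and the generalized inverse
Gaussian moments `E[V_i|y]`, `E[1/V_i|y]` (ratios of modified Bessel
functions `K_ν`, evaluated in log scale), and five conditional-maximization
steps update the spline coefficients, the skewness, the index coefficients
(Newton–Raphson on the delete-one-component parametrization), `Σ`, and `Ω`
in closed form.  Interior-knot counts are chosen by a Schwarz information
criterion on the grid around `n^{1/(2s+1)}`.  Inference uses the cluster
bootstrap (resampling whole subjects).

## Worked example

```python
import numpy as np
import bvsim

# a synthetic study: 100 subjects, 5-10 members each, skewed SAL errors
data, truth = bvsim.generate_sim1(100, seed=2)

config = bvsim.FitConfig(n_interior=3, init="ols", newton_max=1,
                         tol_param=1e-5)
result = bvsim.fit(data, config)
print("beta1 ", np.round(result.params.beta1, 3))
print("beta2 ", np.round(result.params.beta2, 3))
print("gamma ", np.round(result.params.gamma, 3))
print("loglik", round(result.loglik, 2))
```

prints (truth: `beta1 = (1,-1,1)/√3 ≈ (0.577, -0.577, 0.577)`,
`beta2 = (2,1,1)/√6 ≈ (0.816, 0.408, 0.408)`, `gamma = (2, 1.5)`):

```
beta1  [ 0.587 -0.559  0.586]
beta2  [0.819 0.402 0.411]
gamma  [1.453 1.198]
loglik -2079.79
```

The index coefficients are recovered to a few percent at n=100; the
skewness pair is the hardest parameter (its Monte-Carlo standard error at
this sample size is ≈ 0.25 per component).  `result.predict_g(1, u_grid)`
evaluates the fitted link on a grid; `bvsim.bootstrap_ci(data, config,
B=200, seed=1)` gives percentile confidence intervals.

A command-line interface wraps the same calls:

```bash
bvsim simulate --design sim1 --n 50 --seed 1 --out sim_out
bvsim fit --data sim_out/data.csv --knots auto --seed 1 --out fit_out
bvsim replicate --config study.yaml
```

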